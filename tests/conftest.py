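import numpy as np
import pytest

from sostrack.fixtures import CrawlParams, render_worm, simulate_crawl


def make_capsule(bend_deg: float = 0.0, seed: int = 0, mpp: float = 0.05,
                 halfwidth: float = 0.25, body_length: float = 4.0,
                 heading_deg: float | None = None):
    """Render a single capsule posture and return (crop mask, info dict).

    The capsule is placed at a random sub-pixel offset and orientation so
    grid-aligned discretization ties do not distort pixel counts.
    """
    rng = np.random.default_rng(seed)
    params = CrawlParams(noise_sd=0, mm_per_pixel=mpp, body_halfwidth=halfwidth,
                         body_length=body_length)
    th0 = np.deg2rad(heading_deg) if heading_deg is not None else rng.uniform(0, 2 * np.pi)
    u = np.array([np.cos(th0), np.sin(th0)])
    a = th0 + np.deg2rad(bend_deg)
    w = np.array([np.cos(a), np.sin(a)])
    pivot = np.array([40.0, 40.0]) + rng.uniform(0, 0.1, 2)
    s_ant = np.linspace(body_length / 3, 0, 20)
    s_post = np.linspace(0, 2 * body_length / 3, 40)[1:]
    midline = np.vstack([pivot + np.outer(s_ant, w), pivot - np.outer(s_post, u)])
    _, truth = render_worm(midline, halfwidth, params)
    ys, xs = np.nonzero(truth.mask)
    pad = 3
    y0, x0 = ys.min() - pad, xs.min() - pad
    crop = truth.mask[y0:ys.max() + pad + 1, x0:xs.max() + pad + 1]
    offset = np.array([x0, y0], dtype=float)
    info = {
        "offset": offset,
        "head_px": midline[0] / mpp - offset,
        "tail_px": midline[-1] / mpp - offset,
        "apex_head_px": (midline[0] + halfwidth * w) / mpp - offset,
        "apex_tail_px": (midline[-1] - halfwidth * u) / mpp - offset,
        "midline_px": midline / mpp - offset,
        "mpp": mpp,
        "halfwidth_px": halfwidth / mpp,
        "length_px": body_length / mpp,
    }
    return crop, info


def circle_contour(radius: float, n: int | None = None,
                   center=(0.0, 0.0)) -> np.ndarray:
    n = n if n is not None else max(32, int(2 * np.pi * radius))
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


@pytest.fixture(scope="session")
def short_crawl():
    """A 21-frame noisy crawl with static clutter, shared across tests."""
    params = CrawlParams(duration=20, dt=1.0, speed=0.1, noise_sd=5,
                         contrast=100, seed=3, arena_size=(40.0, 40.0),
                         clutter=(((10.0, 10.0), 0.5, 120.0),),
                         start_xy=(12.0, 24.0))
    frames, truths = simulate_crawl(params)
    return params, frames, truths


@pytest.fixture(scope="session")
def clean_crawl():
    """A noise-free crawl for exactness checks (Jaccard, background)."""
    params = CrawlParams(duration=20, dt=1.0, speed=0.1, noise_sd=0,
                         contrast=100, seed=7, arena_size=(40.0, 40.0),
                         clutter=(((10.0, 10.0), 0.5, 120.0),),
                         start_xy=(12.0, 24.0))
    frames, truths = simulate_crawl(params)
    return params, frames, truths
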