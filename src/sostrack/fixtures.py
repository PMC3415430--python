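"""Synthetic frame sequences of a crawling worm-like animal with ground truth.

The generator renders a constant-halfwidth capsule (a midline polyline
dilated by a half-width, with semicircular caps) on a noisy background,
optionally with static circular clutter. Kinematics emulate the three
behavioural primitives of a crawling larva: runs (steady advance of the body
along its heading), head casts (the anterior third of the midline sweeping
sideways while the posterior body stays put) and turns (instantaneous
heading changes). Every frame comes with exact ground truth — midline,
head, tail, centroid, heading and the noiseless body mask — so each
downstream stage of the pipeline can be tested without any real video.

Defaults describe a third-instar fly larva in a typical tracking arena:
4 mm body crawling at 0.1 body lengths per second in an 80 mm field of view
imaged at 0.08 mm per pixel (50 pixels per body length) and 7 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from sostrack.errors import OutOfArenaError, SosError

#: Duration of one head-cast sweep, seconds. The bend angle follows half a
#: sine period over this window so the posture returns smoothly to straight.
CAST_WINDOW_S = 1.0


@dataclass(frozen=True)
class CrawlParams:
    """Geometry, kinematics and appearance of a synthetic crawl.

    Lengths are millimetres, times seconds, intensities 8-bit grey levels.
    ``speed`` is in body lengths per second; ``cast_amplitude`` is the peak
    bend angle of the anterior third in degrees; ``turn_times_and_angles``
    holds ``(time_s, signed_angle_deg)`` pairs.
    """

    body_length: float = 4.0
    body_halfwidth: float = 0.25
    speed: float = 0.1
    cast_amplitude: float = 60.0
    cast_times: tuple[float, ...] = ()
    turn_times_and_angles: tuple[tuple[float, float], ...] = ()
    duration: float = 7.0
    dt: float = 1.0 / 7.0
    arena_size: tuple[float, float] = (80.0, 80.0)
    mm_per_pixel: float = 0.08
    polarity: str = "dark_on_light"
    background_level: float = 200.0
    contrast: float = 100.0
    noise_sd: float = 5.0
    clutter: tuple[tuple[tuple[float, float], float, float], ...] = ()
    seed: int = 0
    start_xy: tuple[float, float] | None = None
    start_heading: float = 0.0
    soft_edge: bool = False
    allow_exit: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least dt")
        if self.body_length <= 2 * self.body_halfwidth:
            raise ValueError("body_length must exceed twice the halfwidth")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level outside [0, 255]")
        if self.polarity not in ("dark_on_light", "light_on_dark"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered frames."""
        w, h = self.arena_size
        return (int(round(h / self.mm_per_pixel)), int(round(w / self.mm_per_pixel)))


@dataclass
class GroundTruth:
    """Exact per-frame state of the synthetic animal (arena mm, y down)."""

    midline: np.ndarray          # (N, 2) head-first polyline, mm
    head: np.ndarray             # (2,), mm
    tail: np.ndarray             # (2,), mm
    centroid: np.ndarray         # (2,) mask centroid, mm
    mask: np.ndarray             # (H, W) bool, noiseless body capsule
    heading: float               # degrees, 0 = +x, y points down
    in_cast: bool = False

    def __post_init__(self):
        self.midline = np.asarray(self.midline, dtype=float)
        self.head = np.asarray(self.head, dtype=float)
        self.tail = np.asarray(self.tail, dtype=float)


def _polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Distance from each query point to a polyline (min over segments)."""
    a = polyline[:-1]                       # (S, 2)
    d = polyline[1:] - a                    # (S, 2)
    seg_len2 = np.maximum((d ** 2).sum(axis=1), 1e-30)
    # t = clamp(((p - a) . d) / |d|^2, 0, 1) for every (point, segment) pair
    diff = points[:, None, :] - a[None, :, :]           # (P, S, 2)
    t = np.clip((diff * d[None]).sum(-1) / seg_len2, 0.0, 1.0)
    proj = a[None] + t[..., None] * d[None]
    return np.sqrt(((points[:, None, :] - proj) ** 2).sum(-1)).min(axis=1)


def _capsule_mask(midline_mm: np.ndarray, halfwidth: float, params: CrawlParams,
                  soft: bool = False) -> np.ndarray:
    """Rasterize the capsule around a midline.

    Returns a float array in [0, 1]: binary for the hard mask, a 1-px linear
    edge ramp when ``soft``. Pixel (r, c) has its centre at mm
    (c * mm_per_pixel, r * mm_per_pixel).
    """
    shape = params.frame_shape
    mpp = params.mm_per_pixel
    out = np.zeros(shape, dtype=float)
    lo = (midline_mm.min(axis=0) - halfwidth) / mpp - 2
    hi = (midline_mm.max(axis=0) + halfwidth) / mpp + 2
    c0, r0 = max(int(np.floor(lo[0])), 0), max(int(np.floor(lo[1])), 0)
    c1 = min(int(np.ceil(hi[0])) + 1, shape[1])
    r1 = min(int(np.ceil(hi[1])) + 1, shape[0])
    if c1 <= c0 or r1 <= r0:
        return out
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    pts = np.column_stack([cc.ravel() * mpp, rr.ravel() * mpp])
    dist = _polyline_distance(pts, midline_mm).reshape(rr.shape)
    if soft:
        patch = np.clip((halfwidth - dist) / mpp + 0.5, 0.0, 1.0)
    else:
        patch = (dist <= halfwidth).astype(float)
    out[r0:r1, c0:c1] = patch
    return out


def render_worm(midline_mm: np.ndarray, halfwidth: float, params: CrawlParams,
                rng: np.random.Generator | None = None,
                heading: float = 0.0, in_cast: bool = False,
                ) -> tuple[np.ndarray, GroundTruth]:
    """Render one grayscale frame of a capsule body around ``midline_mm``.

    The capsule takes intensity ``background_level -/+ contrast`` according
    to polarity; i.i.d. Gaussian pixel noise of sd ``noise_sd`` is added and
    the result clipped to [0, 255]. The returned ground-truth mask is the
    noiseless capsule.

    Raises :class:`OutOfArenaError` when the capsule would leave the arena,
    unless ``params.allow_exit`` is set, in which case it is clipped at the
    frame border.
    """
    midline_mm = np.asarray(midline_mm, dtype=float)
    if midline_mm.ndim != 2 or len(midline_mm) < 2:
        raise ValueError("midline must be a polyline of at least 2 points")
    w, h = params.arena_size
    lo = midline_mm.min(axis=0) - halfwidth
    hi = midline_mm.max(axis=0) + halfwidth
    if not params.allow_exit and (lo[0] < 0 or lo[1] < 0 or hi[0] > w or hi[1] > h):
        raise OutOfArenaError("out_of_arena: body capsule extends beyond the arena")

    if rng is None:
        rng = np.random.default_rng(params.seed)
    sign = -1.0 if params.polarity == "dark_on_light" else 1.0

    img = np.full(params.frame_shape, params.background_level, dtype=float)
    for (cx, cy), radius, intensity in params.clutter:
        rr, cc = np.ogrid[:img.shape[0], :img.shape[1]]
        mpp = params.mm_per_pixel
        disk = (cc * mpp - cx) ** 2 + (rr * mpp - cy) ** 2 <= radius ** 2
        img[disk] = intensity

    alpha = _capsule_mask(midline_mm, halfwidth, params, soft=params.soft_edge)
    body_level = params.background_level + sign * params.contrast
    img = img * (1 - alpha) + body_level * alpha
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    frame = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    mask = alpha >= 0.5
    ys, xs = np.nonzero(mask)
    centroid = (np.array([xs.mean(), ys.mean()]) * params.mm_per_pixel
                if len(xs) else midline_mm.mean(axis=0))
    truth = GroundTruth(midline=midline_mm, head=midline_mm[0], tail=midline_mm[-1],
                        centroid=centroid, mask=mask, heading=heading, in_cast=in_cast)
    return frame, truth


def render_background(params: CrawlParams) -> np.ndarray:
    """Noiseless render of the scene without the animal (background level
    plus static clutter): the reference for background reconstruction."""
    img = np.full(params.frame_shape, params.background_level, dtype=float)
    mpp = params.mm_per_pixel
    for (cx, cy), radius, intensity in params.clutter:
        rr, cc = np.ogrid[:img.shape[0], :img.shape[1]]
        disk = (cc * mpp - cx) ** 2 + (rr * mpp - cy) ** 2 <= radius ** 2
        img[disk] = intensity
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _unit(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


def _midline(pivot: np.ndarray, heading: float, bend: float, params: CrawlParams,
             n_points: int = 65) -> np.ndarray:
    """Head-first midline: anterior third bent by ``bend`` deg at the pivot.

    The pivot sits one third of the body length behind the head; the
    posterior two thirds extend backwards along the heading.
    """
    L = params.body_length
    n_ant = max(2, n_points // 3)
    n_post = max(2, n_points - n_ant)
    u_post = _unit(heading)
    u_ant = _unit(heading + bend)
    s_ant = np.linspace(L / 3.0, 0.0, n_ant)          # head -> pivot
    s_post = np.linspace(0.0, 2.0 * L / 3.0, n_post + 1)[1:]   # pivot -> tail
    anterior = pivot[None, :] + s_ant[:, None] * u_ant[None, :]
    posterior = pivot[None, :] - s_post[:, None] * u_post[None, :]
    return np.vstack([anterior, posterior])


def simulate_crawl(params: CrawlParams) -> tuple[list[np.ndarray], list[GroundTruth]]:
    """Simulate a crawl and render it; returns (frames, ground truths).

    Frame count is ``floor(duration/dt) + 1`` (frame 0 at t = 0). Between
    events the pivot point advances along the heading at
    ``speed * body_length`` mm/s. During each 1 s cast window the pivot is
    frozen and the anterior third swings to ``cast_amplitude`` degrees and
    back (half-sine profile, alternating sides). Turns rotate the heading
    instantaneously at their stated times.
    """
    for t in params.cast_times:
        if not (0.0 <= t <= params.duration):
            raise SosError(f"cast time {t} outside [0, {params.duration}]")
    for t, _ in params.turn_times_and_angles:
        if not (0.0 <= t <= params.duration):
            raise SosError(f"turn time {t} outside [0, {params.duration}]")

    rng = np.random.default_rng(params.seed)
    n_frames = int(np.floor(params.duration / params.dt)) + 1
    v = params.speed * params.body_length          # mm/s

    w, h = params.arena_size
    if params.start_xy is None:
        pivot = np.array([w / 2.0, h / 2.0])
    else:
        pivot = np.array(params.start_xy, dtype=float)
    heading = float(params.start_heading)
    turns = sorted(params.turn_times_and_angles)
    turn_idx = 0
    casts = sorted(params.cast_times)

    frames: list[np.ndarray] = []
    truths: list[GroundTruth] = []
    for i in range(n_frames):
        t = i * params.dt
        while turn_idx < len(turns) and turns[turn_idx][0] <= t:
            heading += turns[turn_idx][1]
            turn_idx += 1
        bend = 0.0
        in_cast = False
        for k, t0 in enumerate(casts):
            if t0 <= t <= t0 + CAST_WINDOW_S:
                sgn = 1.0 if k % 2 == 0 else -1.0
                bend += sgn * params.cast_amplitude * np.sin(
                    np.pi * (t - t0) / CAST_WINDOW_S)
                in_cast = True
        midline = _midline(pivot, heading, bend, params)
        frame, truth = render_worm(midline, params.body_halfwidth, params,
                                   rng=rng, heading=heading, in_cast=in_cast)
        frames.append(frame)
        truths.append(truth)
        if not in_cast:
            pivot = pivot + v * params.dt * _unit(heading)
    return frames, truths


def write_sequence(frames: list[np.ndarray], truths: list[GroundTruth],
                   outdir: str | Path, params: CrawlParams | None = None,
                   fmt: str = "png") -> Path:
    """Write frames as zero-padded images plus a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(outdir / f"frame_{i:05d}.{fmt}", frame)
    sidecar = {
        "n_frames": len(frames),
        "frames": [
            {
                "midline": t.midline.tolist(),
                "head": t.head.tolist(),
                "tail": t.tail.tolist(),
                "centroid": t.centroid.tolist(),
                "heading": t.heading,
                "in_cast": t.in_cast,
            }
            for t in truths
        ],
    }
    if params is not None:
        sidecar["params"] = {
            k: v for k, v in params.__dict__.items()
            if isinstance(v, (int, float, str, bool, tuple, list))
        }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh)
    return outdir


def read_sequence(indir: str | Path) -> list[np.ndarray]:
    """Read a numbered image sequence (PNG/TIFF) from a directory."""
    indir = Path(indir)
    paths = sorted(p for p in indir.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not paths:
        raise SosError(f"no image frames found in {indir}")
    return [np.asarray(iio.imread(p)) for p in paths]
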