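"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most literal method available —
per-pixel loops, exhaustive search, finite differences — so that agreement
with the package's vectorized implementations is meaningful.
"""

import numpy as np


def thinning_oracle(mask: np.ndarray) -> np.ndarray:
    """Naive per-pixel implementation of the two-subiteration parallel
    thinning rule (Zhang-Suen): deletions within a subiteration are decided
    on a snapshot of the image."""
    img = np.asarray(mask, bool).copy()
    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            pad = np.pad(img, 1)
            to_delete = []
            for i in range(1, pad.shape[0] - 1):
                for j in range(1, pad.shape[1] - 1):
                    if not pad[i, j]:
                        continue
                    p = [pad[i - 1, j], pad[i - 1, j + 1], pad[i, j + 1],
                         pad[i + 1, j + 1], pad[i + 1, j], pad[i + 1, j - 1],
                         pad[i, j - 1], pad[i - 1, j - 1]]
                    b = sum(p)
                    if not 2 <= b <= 6:
                        continue
                    a = sum(1 for k in range(8) if not p[k] and p[(k + 1) % 8])
                    if a != 1:
                        continue
                    p2, p3, p4, p5, p6, p7, p8, p9 = p
                    if step == 0:
                        if (p2 and p4 and p6) or (p4 and p6 and p8):
                            continue
                    else:
                        if (p2 and p4 and p8) or (p2 and p6 and p8):
                            continue
                    to_delete.append((i - 1, j - 1))
            if to_delete:
                changed = True
                for i, j in to_delete:
                    img[i, j] = False
    return img


def otsu_oracle(pixels: np.ndarray) -> list[int]:
    """Exhaustive search over all 256 cut points for the thresholds
    maximizing between-class variance of the 8-bit histogram. Returns the
    full set of maximizing cut points (ties arise over empty bins)."""
    hist = np.bincount(np.asarray(pixels, dtype=np.uint8).ravel(), minlength=256)
    total = hist.sum()
    levels = np.arange(256)
    variances = np.full(256, -np.inf)
    for t in range(1, 256):
        w0 = hist[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[:t] * hist[:t]).sum() / w0
        mu1 = (levels[t:] * hist[t:]).sum() / w1
        variances[t] = w0 * w1 * (mu0 - mu1) ** 2
    return list(np.flatnonzero(variances == variances.max()))


def boundary_trace_oracle(mask: np.ndarray) -> float:
    """Perimeter by Moore boundary walking over pixel centres, using
    Euclidean step lengths."""
    mask = np.asarray(mask, bool)
    ys, xs = np.nonzero(mask)
    start = (ys[np.lexsort((xs, ys))][0], xs[np.lexsort((xs, ys))][0])
    # Moore neighbourhood clockwise starting west
    moore = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]

    def inside(p):
        return (0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1]
                and mask[p])

    boundary = [start]
    backtrack = (start[0], start[1] - 1)
    current = start
    while True:
        offs = [(n[0] - current[0], n[1] - current[1]) for n in [backtrack]][0]
        k = moore.index(offs)
        nxt = None
        for d in range(1, 9):
            cand_off = moore[(k + d) % 8]
            cand = (current[0] + cand_off[0], current[1] + cand_off[1])
            if inside(cand):
                nxt = cand
                backtrack = (current[0] + moore[(k + d - 1) % 8][0],
                             current[1] + moore[(k + d - 1) % 8][1])
                break
        if nxt is None:
            return 0.0          # isolated pixel
        boundary.append(nxt)
        current = nxt
        if current == start and len(boundary) > 2:
            break
    pts = np.array(boundary, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def finite_difference_gradient(landscape, p, h: float = 1e-4) -> np.ndarray:
    """Central-difference gradient of a landscape field."""
    x, y = p
    gx = (landscape.field_at((x + h, y)) - landscape.field_at((x - h, y))) / (2 * h)
    gy = (landscape.field_at((x, y + h)) - landscape.field_at((x, y - h))) / (2 * h)
    return np.array([gx, gy])
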