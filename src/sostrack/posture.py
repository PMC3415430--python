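"""Per-frame shape analysis: contour, curvature, skeleton and morphometrics.

From a segmented binary body mask, this stage extracts an ordered closed
contour, a single-pixel-wide skeleton by topology-preserving thinning, the
two skeleton endpoints (proxies for head and tail), curvature-based
head/tail candidates on the contour, and scalar morphometrics (area,
perimeter, skeleton length, centroid, skeleton midpoint).

Holes are filled before any contour or skeleton computation so segmentation
noise cannot change the body topology. Thinning can leave spurious short
branches ("spurs") yielding more than two endpoints; such frames are
flagged, not auto-repaired, and the fraction of flagged frames is tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes, convolve, distance_transform_edt
from skimage.morphology import closing as _closing, disk, opening as _opening
from skimage.measure import find_contours

from sostrack.errors import BranchedSkeletonError, NoObjectError, SosError

#: blob-like criterion: head-tail chord / skeleton length below this, or a
#: skeleton shorter than MIN_SKELETON_PX pixels.
BLOB_CHORD_RATIO = 0.3
MIN_SKELETON_PX = 5


@dataclass
class Posture:
    """Full shape description of one frame, in crop or arena coordinates."""

    contour: np.ndarray                 # (N, 2) closed ordered (x, y), cyclic
    skeleton: np.ndarray                # (M, 2) ordered (x, y), head-first
    head: np.ndarray
    tail: np.ndarray
    centroid: np.ndarray
    midpoint: np.ndarray
    area: float
    perimeter: float
    skeleton_length: float
    endpoints: list[np.ndarray] = field(default_factory=list)
    curvature: np.ndarray | None = None
    flags: set = field(default_factory=set)

    def with_head(self, head_idx: int) -> "Posture":
        """Return a copy with the skeleton oriented so endpoint ``head_idx``
        (0 = current head end, 1 = current tail end) leads."""
        p = Posture(**{**self.__dict__})
        p.flags = set(self.flags)
        if head_idx == 0:
            return p
        p.skeleton = self.skeleton[::-1].copy()
        p.head, p.tail = self.tail.copy(), self.head.copy()
        p.endpoints = list(reversed(self.endpoints))
        return p


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered closed outer boundary of a filled mask, as (x, y) points.

    The boundary is traced at the half-level between body and background
    (sub-pixel). Interior holes are filled first, so only the outer boundary
    is returned. Orientation is normalized to positive signed area
    (interior on the left when x is rightward and y downward).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoObjectError("no_object: empty mask")
    filled = binary_fill_holes(mask)
    padded = np.pad(filled.astype(float), 1)
    contours = find_contours(padded, 0.5)
    longest = max(contours, key=len)
    # (row, col) -> (x, y); drop the duplicated closing vertex, undo padding
    xy = longest[:, ::-1] - 1.0
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    if _signed_area(xy) < 0:
        xy = xy[::-1].copy()
    return xy


def _signed_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def smooth_contour(contour: np.ndarray, window: int) -> np.ndarray:
    """Cyclic moving average of the contour coordinates.

    ``window`` must be odd; ``window=1`` is the identity. Point count is
    preserved and the contour stays closed (cyclic convolution).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(contour):
        raise SosError("smoothing window larger than contour")
    if window == 1:
        return contour.copy()
    kernel = np.ones(window) / window
    out = np.empty_like(contour, dtype=float)
    for k in range(2):
        out[:, k] = convolve(contour[:, k].astype(float), kernel, mode="wrap")
    return out


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Single-pixel-wide medial skeleton by topology-preserving thinning.

    Implements the classic two-subiteration parallel thinning rule
    (Zhang-Suen): a boundary pixel is deleted when it has 2-6 foreground
    neighbours, exactly one 0-to-1 transition around its 8-neighbourhood,
    and passes the subiteration's directional tests; both subiterations
    are applied until the image stops changing. Holes are filled first.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoObjectError("no_object: empty mask")
    img = np.pad(binary_fill_holes(mask), 1)
    while True:
        changed = False
        for step in (0, 1):
            # P2..P9 clockwise from north, on the current snapshot
            p = [np.roll(img, shift, axis=axis_pair)
                 for shift, axis_pair in (
                     ((1, 0), (0, 1)),      # P2: north
                     ((1, -1), (0, 1)),     # P3: north-east
                     ((0, -1), (0, 1)),     # P4: east
                     ((-1, -1), (0, 1)),    # P5: south-east
                     ((-1, 0), (0, 1)),     # P6: south
                     ((-1, 1), (0, 1)),     # P7: south-west
                     ((0, 1), (0, 1)),      # P8: west
                     ((1, 1), (0, 1)))]     # P9: north-west
            b = sum(x.astype(np.uint8) for x in p)
            a = sum((~p[k] & p[(k + 1) % 8]).astype(np.uint8) for k in range(8))
            p2, p3, p4, p5, p6, p7, p8, p9 = p
            if step == 0:
                direc = ~(p2 & p4 & p6) & ~(p4 & p6 & p8)
            else:
                direc = ~(p2 & p4 & p8) & ~(p2 & p6 & p8)
            delete = img & (b >= 2) & (b <= 6) & (a == 1) & direc
            if delete.any():
                img &= ~delete
                changed = True
        if not changed:
            break
    return img[1:-1, 1:-1]


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def skeleton_endpoints(skeleton: np.ndarray) -> tuple[list[np.ndarray], bool]:
    """Skeleton pixels with at most one 8-neighbour, and a spur flag.

    An isolated pixel (zero neighbours) counts as an endpoint. The spur
    flag is set whenever the endpoint count differs from two.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        raise NoObjectError("no_object: empty skeleton")
    neighbors = convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
    ys, xs = np.nonzero(skel & (neighbors <= 1))
    endpoints = [np.array([x, y]) for x, y in zip(xs, ys)]
    return endpoints, len(endpoints) != 2


def _cyclic_arclength(contour: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex; total length appended last."""
    steps = np.linalg.norm(np.diff(np.vstack([contour, contour[:1]]), axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def contour_curvature(contour: np.ndarray, arc_window: float | None = None) -> np.ndarray:
    """Signed curvature (1/px) at each contour point, positive = convex.

    Estimated as the turning angle between the chords to the points one
    ``arc_window`` of arc length behind and ahead, divided by the arc
    distance between the chord midpoints. Default window is 5% of the
    contour length, at least 3 px.
    """
    n = len(contour)
    cum = _cyclic_arclength(contour)
    total = cum[-1]
    if arc_window is None:
        arc_window = max(3.0, 0.05 * total)
    if total <= 2 * arc_window:
        raise SosError("contour too short for the curvature window")

    # index offset spanning ~arc_window of arc, per point (uniform offset
    # from mean spacing keeps it simple and cyclic)
    mean_step = total / n
    k = max(1, int(round(arc_window / mean_step)))
    fwd = np.roll(contour, -k, axis=0)
    bwd = np.roll(contour, k, axis=0)
    chord1 = contour - bwd
    chord2 = fwd - contour
    cross = chord1[:, 0] * chord2[:, 1] - chord1[:, 1] * chord2[:, 0]
    dot = (chord1 * chord2).sum(axis=1)
    angle = np.arctan2(cross, dot)
    # arc distance between the two chord midpoints ~ k steps of arc
    s_b = np.linalg.norm(chord1, axis=1)
    s_f = np.linalg.norm(chord2, axis=1)
    span = 0.5 * (s_b + s_f)
    return angle / np.maximum(span, 1e-12)


def head_tail_candidates(contour: np.ndarray, curvature: np.ndarray,
                         min_separation: float = 0.25,
                         ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Two sharpest well-separated convex points: head/tail candidates.

    Picks the two highest positive local curvature maxima whose arc
    separation is at least ``min_separation`` of the contour length and
    whose curvature stands out above the typical (median) level. Shapes
    without two such maxima (e.g. a near-circular blob) are flagged
    blob-like and the best effort returned.
    """
    n = len(contour)
    cum = _cyclic_arclength(contour)
    total = cum[-1]
    prev = np.roll(curvature, 1)
    nxt = np.roll(curvature, -1)
    is_max = (curvature > 0) & (curvature >= prev) & (curvature >= nxt) & \
             ((curvature > prev) | (curvature > nxt))
    # a closed convex curve averages 2*pi/perimeter of curvature; genuine
    # tips must stand well above both that and the typical level, which
    # rejects near-circular blobs whose curvature is uniform
    baseline = max(1.5 * np.median(np.abs(curvature)), 2.0 * 2 * np.pi / total)
    prominent = is_max & (curvature > baseline + 1e-9)
    idx = np.flatnonzero(prominent)
    order = idx[np.argsort(curvature[idx])[::-1]]

    chosen: list[int] = []
    for i in order:
        if not chosen:
            chosen.append(int(i))
            continue
        sep = abs(cum[i] - cum[chosen[0]])
        sep = min(sep, total - sep)
        if sep >= min_separation * total:
            chosen.append(int(i))
            break
    if len(chosen) == 2:
        return contour[chosen[0]], contour[chosen[1]], False
    # degenerate blob-like shape: fall back to the global max and its antipode
    i0 = int(np.argmax(curvature))
    i1 = (i0 + n // 2) % n
    return contour[i0], contour[i1], True


def order_skeleton(skeleton: np.ndarray, head: np.ndarray) -> np.ndarray:
    """Walk the skeleton from the endpoint nearest ``head`` to the other end.

    Returns an (M, 2) array of (x, y) pixel coordinates visiting every
    skeleton pixel once. Raises :class:`BranchedSkeletonError` for skeletons
    without exactly two endpoints.
    """
    skel = np.asarray(skeleton, dtype=bool)
    endpoints, spur = skeleton_endpoints(skel)
    if len(endpoints) != 2:
        raise BranchedSkeletonError(
            f"branched: skeleton has {len(endpoints)} endpoints")
    head = np.asarray(head, dtype=float)
    start = min(endpoints, key=lambda e: np.linalg.norm(e - head))

    remaining = {(int(x), int(y)) for y, x in zip(*np.nonzero(skel))}
    path = [(int(start[0]), int(start[1]))]
    remaining.discard(path[0])
    while remaining:
        cx, cy = path[-1]
        # prefer 4-connected steps so thick diagonals do not zigzag
        candidates = sorted(
            ((nx, ny) for nx in (cx - 1, cx, cx + 1) for ny in (cy - 1, cy, cy + 1)
             if (nx, ny) in remaining),
            key=lambda p: abs(p[0] - cx) + abs(p[1] - cy))
        if not candidates:
            raise BranchedSkeletonError("branched: skeleton walk got stuck")
        path.append(candidates[0])
        remaining.discard(candidates[0])
    return np.array(path, dtype=float)


def prune_spurs(skeleton: np.ndarray, max_branch_frac: float = 0.1) -> np.ndarray:
    """Iteratively remove branches shorter than ``max_branch_frac`` of the
    skeleton size until at most two endpoints remain (config-gated option)."""
    skel = np.asarray(skeleton, dtype=bool).copy()
    max_len = max(1, int(max_branch_frac * skel.sum()))
    for _ in range(max_len):
        endpoints, spur = skeleton_endpoints(skel)
        if len(endpoints) <= 2:
            break
        neighbors = convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
        tips = np.zeros_like(skel)
        for e in endpoints:
            tips[int(e[1]), int(e[0])] = True
        # shaving every tip shortens true ends too; re-grow is not attempted,
        # which is why this is off by default
        skel &= ~tips
    return skel


def _path_length(path: np.ndarray, stride: int = 3) -> float:
    """Arc length of a pixel path measured over ``stride``-pixel chords.

    Per-pixel Euclidean steps overestimate the length of digital staircase
    lines by up to ~8%; chords spanning several pixels track the underlying
    curve instead (body bend radii are far larger than the stride).
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        return 0.0
    anchors = path[::stride]
    if not np.array_equal(anchors[-1], path[-1]):
        anchors = np.vstack([anchors, path[-1]])
    return float(np.linalg.norm(np.diff(anchors, axis=0), axis=1).sum())


def refine_endpoints(path: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Correct the axial bias of thinning at the body ends.

    Thinning stops one to a few pixels short of the midline tip inside each
    rounded cap. Each end is moved to the point one local halfwidth back
    from the mask boundary along the end direction — the centre of the cap,
    i.e. the true midline extremity. The halfwidth is the median distance
    transform along the skeleton interior.
    """
    if len(path) < 8:
        return path
    mask = np.asarray(mask, dtype=bool)
    edt = distance_transform_edt(mask)
    interior = path[len(path) // 5: -len(path) // 5 or None]
    iy = np.clip(np.rint(interior[:, 1]).astype(int), 0, mask.shape[0] - 1)
    ix = np.clip(np.rint(interior[:, 0]).astype(int), 0, mask.shape[1] - 1)
    halfwidth = float(np.median(edt[iy, ix]))
    if halfwidth <= 0:
        return path
    out = path.astype(float).copy()
    # thinning can also consume a short, sharply bent anterior limb almost
    # entirely; a straight-line march exits through the limb's side, so the
    # tip is found by hill-climbing inside the mask away from an interior
    # anchor, which follows the limb whatever its curvature
    max_steps = max(8, len(path) // 2)
    for end, anchor_idx in ((0, min(max(3, int(2 * halfwidth)), len(path) - 1)),
                            (-1, -min(max(4, int(2 * halfwidth) + 1), len(path)))):
        anchor = out[anchor_idx]
        cur = np.rint(out[end]).astype(int)
        best = float(np.linalg.norm(cur - anchor))
        for _ in range(max_steps):
            nxt = None
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    cx, cy = cur[0] + dx, cur[1] + dy
                    if not (0 <= cy < mask.shape[0] and 0 <= cx < mask.shape[1]
                            and mask[cy, cx]):
                        continue
                    d = float(np.hypot(cx - anchor[0], cy - anchor[1]))
                    if d > best + 1e-9:
                        best, nxt = d, (cx, cy)
            if nxt is None:
                break
            cur = np.array(nxt)
        tip = cur.astype(float)
        u = tip - anchor
        norm = np.linalg.norm(u)
        if norm == 0:
            continue
        u = u / norm
        refined = tip - halfwidth * u
        # never retract behind the thinned endpoint
        if (refined - out[end]).dot(u) > 0:
            out[end] = refined
    return out


def posture_metrics(mask: np.ndarray, contour: np.ndarray,
                    skeleton_path: np.ndarray,
                    ) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """(area, perimeter, skeleton_length, centroid, midpoint).

    Area is the mask pixel count; perimeter and skeleton length use
    Euclidean step lengths; the midpoint is the skeleton vertex at half the
    arc length.
    """
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    ys, xs = np.nonzero(mask)
    centroid = np.array([xs.mean(), ys.mean()])
    perimeter = float(_cyclic_arclength(contour)[-1])
    if len(skeleton_path) > 1:
        steps = np.linalg.norm(np.diff(skeleton_path, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        skeleton_length = _path_length(skeleton_path)
        midpoint = skeleton_path[int(np.argmin(np.abs(cum - cum[-1] / 2)))]
    else:
        skeleton_length = 0.0
        midpoint = skeleton_path[0] if len(skeleton_path) else centroid
    return area, perimeter, skeleton_length, centroid, midpoint.astype(float)


def analyze_mask(mask: np.ndarray, smooth_px: int = 1,
                 contour_smooth_window: int = 5,
                 prune: bool = False) -> Posture:
    """Full shape analysis of one binary body mask.

    ``smooth_px`` applies a light morphological closing+opening (disk
    radius) before thinning to suppress boundary pixel noise; 0 disables
    it. ``contour_smooth_window`` smooths the traced contour for curvature
    estimation. Spur skeletons are flagged (optionally pruned) and
    blob-like shapes flagged by the chord/length ratio.
    """
    mask = binary_fill_holes(np.asarray(mask, dtype=bool))
    if not mask.any():
        raise NoObjectError("no_object: empty mask")
    flags: set = set()

    work = mask
    if smooth_px > 0:
        selem = disk(smooth_px)
        smoothed = _opening(_closing(mask, selem), selem)
        if smoothed.any():
            work = binary_fill_holes(smoothed)

    contour = extract_contour(work)
    if len(contour) >= contour_smooth_window:
        contour = smooth_contour(contour, contour_smooth_window)

    skel = skeletonize(work)
    endpoints, spur = skeleton_endpoints(skel)
    if spur and prune:
        skel = prune_spurs(skel)
        endpoints, spur = skeleton_endpoints(skel)
    if spur:
        flags.add("spur")

    curvature = None
    try:
        curvature = contour_curvature(contour)
    except SosError:
        flags.add("blob_like")

    if len(endpoints) == 2:
        path = refine_endpoints(order_skeleton(skel, endpoints[0]), work)
        endpoints = [path[0].copy(), path[-1].copy()]
    else:
        # best effort: raster-ordered pixels; downstream stages see the flag
        ys, xs = np.nonzero(skel)
        path = np.column_stack([xs, ys]).astype(float)
    head = path[0]
    tail = path[-1]

    area, perimeter, skeleton_length, centroid, midpoint = posture_metrics(
        mask, contour, path)
    if skeleton_length < MIN_SKELETON_PX or (
            skeleton_length > 0 and
            np.linalg.norm(head - tail) / skeleton_length < BLOB_CHORD_RATIO):
        flags.add("blob_like")

    return Posture(contour=contour, skeleton=path, head=np.asarray(head, float),
                   tail=np.asarray(tail, float), centroid=centroid,
                   midpoint=midpoint, area=area, perimeter=perimeter,
                   skeleton_length=skeleton_length, endpoints=endpoints,
                   curvature=curvature, flags=flags)


def translate(posture: Posture, offset) -> Posture:
    """Shift a crop-local posture into frame coordinates by its box offset.

    Identity propagation compares positions across frames, so postures must
    share one coordinate system before labelling.
    """
    off = np.asarray(offset[:2], dtype=float)
    p = posture.with_head(0)
    p.contour = posture.contour + off
    p.skeleton = posture.skeleton + off
    p.head = posture.head + off
    p.tail = posture.tail + off
    p.centroid = posture.centroid + off
    p.midpoint = posture.midpoint + off
    p.endpoints = [np.asarray(e, float) + off for e in posture.endpoints]
    return p


def qc_summary(postures: list[Posture]) -> dict:
    """Fractions of spur / blob-like / discarded frames across a trial."""
    if not postures:
        raise SosError("no postures to summarize")
    n = len(postures)
    return {
        "fraction_spur": sum("spur" in p.flags for p in postures) / n,
        "fraction_blob_like": sum("blob_like" in p.flags for p in postures) / n,
        "fraction_discarded": sum("discarded" in p.flags for p in postures) / n,
    }
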