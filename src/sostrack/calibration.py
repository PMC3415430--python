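"""Pixel-to-millimetre and frame-to-second calibration.

The spatial scale comes from landmark pairs in the arena whose physical
separation is known to the experimenter; the temporal scale defaults to the
reciprocal of the online sampling interval. A single isotropic scalar
factor is used (anisotropic pixels are out of scope).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sostrack.errors import SosError
from sostrack.posture import Posture

#: warn when landmark pairs disagree on the scale by more than this
SPREAD_WARN = 0.02


@dataclass(frozen=True)
class Calibration:
    mm_per_pixel: float
    frames_per_second: float
    landmarks: tuple = ()

    def __post_init__(self):
        if self.mm_per_pixel <= 0 or self.frames_per_second <= 0:
            raise ValueError("calibration factors must be positive")


def fit_scale(landmarks, frames_per_second: float = 1.0) -> Calibration:
    """Fit mm/px as the mean over landmark pairs of known-mm / pixel-distance.

    Each landmark is ``((x0, y0), (x1, y1), known_mm)`` in pixels. Emits a
    warning if the per-pair scales spread by more than 2% relative.
    """
    if not landmarks:
        raise SosError("at least one landmark pair required")
    scales = []
    for p0, p1, known_mm in landmarks:
        d = float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p0, float)))
        if d == 0:
            raise SosError("landmark pair with zero pixel distance")
        scales.append(known_mm / d)
    scales = np.asarray(scales)
    mean = float(scales.mean())
    if len(scales) > 1 and (scales.max() - scales.min()) / mean > SPREAD_WARN:
        warnings.warn(f"landmark scales disagree: {scales}", stacklevel=2)
    return Calibration(mm_per_pixel=mean, frames_per_second=frames_per_second,
                       landmarks=tuple((tuple(p0), tuple(p1), known_mm)
                                       for p0, p1, known_mm in landmarks))


def to_arena_frame(posture: Posture, bbox_offset, cal: Calibration) -> Posture:
    """Translate a crop-local posture by its box offset and convert to mm.

    Coordinates map as ``(c + offset) * mm_per_pixel``; areas scale by the
    square of the factor, lengths linearly.
    """
    off = np.asarray(bbox_offset[:2], dtype=float)
    s = cal.mm_per_pixel

    def pt(p):
        return (np.asarray(p, float) + off) * s

    return Posture(
        contour=(posture.contour + off) * s,
        skeleton=(posture.skeleton + off) * s,
        head=pt(posture.head), tail=pt(posture.tail),
        centroid=pt(posture.centroid), midpoint=pt(posture.midpoint),
        area=posture.area * s * s,
        perimeter=posture.perimeter * s,
        skeleton_length=posture.skeleton_length * s,
        endpoints=[pt(e) for e in posture.endpoints],
        curvature=None if posture.curvature is None else posture.curvature / s,
        flags=set(posture.flags),
    )


def save_calibration(cal: Calibration, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"mm_per_pixel": cal.mm_per_pixel,
                   "frames_per_second": cal.frames_per_second,
                   "landmarks": list(cal.landmarks)}, fh, indent=2)


def load_calibration(path: str | Path) -> Calibration:
    with open(path) as fh:
        d = json.load(fh)
    return Calibration(mm_per_pixel=d["mm_per_pixel"],
                       frames_per_second=d["frames_per_second"],
                       landmarks=tuple(tuple(x) if isinstance(x, list) else x
                                       for x in d.get("landmarks", ())))
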