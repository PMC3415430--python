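"""Experiment-design calculator relating posture resolution, field of view,
animal speed, trial duration and data storage.

Four scales govern a fixed-camera tracking experiment: the organism length
(lambda, mm), the field-of-view length (L, mm), the sampling interval
(tau, s) and the total duration (T, s). Zooming in raises posture
resolution but shrinks the trackable area; animal speed bounds the time to
the arena edge; frequency, duration and crop size set the storage bill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from sostrack.errors import SosError


@dataclass(frozen=True)
class PlanInputs:
    lambda_: float            # organism length, mm
    L: float                  # field-of-view length, mm
    tau: float                # sampling interval, s
    T: float                  # experiment duration, s
    P: int = 1024             # frame resolution along L, px
    v: float = 0.1            # speed, body lengths / s
    bytes_per_pixel: int = 1

    def __post_init__(self):
        if min(self.lambda_, self.L, self.tau, self.T, self.P,
               self.bytes_per_pixel) <= 0 or self.v < 0:
            raise ValueError("plan inputs must be positive (v >= 0)")
        if self.L < self.lambda_:
            raise ValueError("field of view must fit the organism (L >= lambda)")

    @property
    def ratio(self) -> float:
        return self.L / self.lambda_


def posture_resolution(P: int, ratio: float) -> float:
    """Pixels per body length for a P-pixel frame at arena/organism ratio."""
    if ratio < 1:
        raise SosError("arena/organism ratio must be >= 1")
    return P / ratio


def time_to_edge(ratio: float, v: float, start: str = "center") -> float:
    """Seconds until an animal moving at ``v`` body lengths/s reaches the
    arena edge: ratio/2 body lengths from the centre, ratio from the far
    edge. ``v = 0`` returns infinity."""
    if v < 0:
        raise SosError("speed must be non-negative")
    if start == "center":
        distance_bl = ratio / 2.0
    elif start == "edge":
        distance_bl = ratio
    else:
        raise ValueError("start must be 'center' or 'edge'")
    if v == 0:
        return math.inf
    return distance_bl / v


def storage_estimate(frequency: float, duration: float, crop_px: int,
                     bytes_per_pixel: int = 1,
                     full_frame_px: int | None = None) -> dict:
    """Bytes needed to store a trial, in bounding-box and full-frame modes.

    ``crop_px`` and ``full_frame_px`` are pixel counts per image. Partial
    frames are never stored, so the frame count is floored.
    """
    if min(frequency, duration, crop_px, bytes_per_pixel) < 0:
        raise SosError("storage inputs must be non-negative")
    n_frames = int(math.floor(frequency * duration))
    out = {"n_frames": n_frames,
           "bbox_bytes": n_frames * crop_px * bytes_per_pixel}
    if full_frame_px is not None:
        out["full_frame_bytes"] = n_frames * full_frame_px * bytes_per_pixel
    return out


def sampling_check(v: float, tau: float) -> tuple[float, bool]:
    """Body lengths moved per sample and whether the distance rule for head
    identity is safe (displacement under half a body length per sample)."""
    displacement = v * tau
    return displacement, displacement < 0.5


def plan_report(inputs: PlanInputs) -> dict:
    """All planner quantities for one set of experiment parameters."""
    ratio = inputs.ratio
    crop_px_side = posture_resolution(inputs.P, ratio)
    displacement, ok = sampling_check(inputs.v, inputs.tau)
    storage = storage_estimate(1.0 / inputs.tau, inputs.T,
                               int(round(crop_px_side)) ** 2,
                               inputs.bytes_per_pixel, inputs.P ** 2)
    return {
        "arena_organism_ratio": ratio,
        "posture_resolution_px_per_bl": crop_px_side,
        "time_to_edge_from_center_s": time_to_edge(ratio, inputs.v, "center"),
        "time_to_edge_from_edge_s": time_to_edge(ratio, inputs.v, "edge"),
        "bl_per_sample": displacement,
        "distance_rule_safe": ok,
        **storage,
    }
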