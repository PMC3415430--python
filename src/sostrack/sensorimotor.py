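"""Fusion of calibrated trajectories with stimulus landscapes.

Each retained frame becomes a sensorimotor record pairing motor variables
(positions of head, tail, centroid and midpoint; heading; speed; head-bend
angle) with the reconstructed sensory input (stimulus value at the head,
its time derivative, bearing of the animal to the local gradient, values
along the skeleton, and — for sideways light — the fraction of the body
contour that is lit). Discrete behavioural events (runs, turns, head
casts) are then labelled from the motor variables, and trials merged into
one flat table for population-level analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sostrack.calibration import Calibration
from sostrack.errors import (
    FlatFieldError,
    IncompatibleUnitsError,
    SosError,
    ZeroBaselineError,
)
from sostrack.identity import LabeledTrajectory
from sostrack.landscapes import (
    SidewaysLightLandscape,
    bearing_to_gradient,
    contour_light_fraction,
    sample_along_skeleton,
)

#: below this centroid speed (body lengths / s) the heading estimate falls
#: back from the centroid path to the tail-to-head body axis
SLOW_SPEED_BL_S = 0.05

DEFAULT_THRESHOLDS = {
    "turn_rate": 20.0,       # deg/s of heading change
    "cast_angle": 30.0,      # deg of head bend
    "min_duration": None,    # s; None = two sampling intervals
    # body lengths/s below which the animal counts as paused for the cast
    # criterion; None adapts to the trial (median centroid speed)
    "run_speed_bl": None,
}


@dataclass
class SensorimotorRecord:
    t: float
    frame: int
    head: np.ndarray
    tail: np.ndarray
    centroid: np.ndarray
    midpoint: np.ndarray
    head_value: float = np.nan
    head_value_derivative: float = np.nan
    bearing: float = np.nan              # deg in [0, 180]; NaN in flat fields
    skeleton_values: np.ndarray | None = None
    light_fraction: float = np.nan       # % of contour lit (sideways light)
    relative_change: float = np.nan      # % change of head value vs previous
    heading: float = np.nan              # deg, 0 = +x, y down
    bend: float = np.nan                 # deg deviation of body from straight
    speed: float = np.nan                # centroid speed, mm/s
    event_label: str = "none"


@dataclass
class EventAnnotation:
    type: str                            # run | turn | cast
    start_frame: int
    end_frame: int                       # inclusive
    magnitude: float = 0.0               # deg (turn/cast) or mm (run)


def relative_change(delta: float, baseline: float) -> float:
    """Percentage change of a stimulus: 100 * delta / baseline."""
    if baseline == 0:
        raise ZeroBaselineError("zero_baseline")
    return 100.0 * delta / baseline


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def _bend_angle(head, midpoint, tail) -> float:
    """Deviation from a straight body, in degrees: 180 minus the angle at
    the midpoint between the head and tail segments."""
    v1 = np.asarray(head, float) - np.asarray(midpoint, float)
    v2 = np.asarray(midpoint, float) - np.asarray(tail, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = np.clip(v1.dot(v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def build_records(trajectory: LabeledTrajectory, cal: Calibration,
                  landscape=None, smooth_derivative: bool = False,
                  ) -> list[SensorimotorRecord]:
    """One sensorimotor record per retained (non-discarded) frame.

    Postures must already be in arena millimetres. The head-value time
    derivative uses central differences (one-sided at the ends), optionally
    smoothed by a width-3 boxcar. The heading is the direction of centroid
    displacement over a 3-frame window, falling back to the tail-to-head
    body axis when the animal is nearly stationary. A flat stimulus field
    yields a missing bearing, not an error.
    """
    retained = trajectory.retained()
    if not retained:
        raise SosError("no retained frames")
    frames = [i for i, _ in retained]
    postures = [p for _, p in retained]
    times = np.array([i / cal.frames_per_second for i in frames])
    centroids = np.array([p.centroid for p in postures])
    body_length = float(np.median([p.skeleton_length for p in postures]))

    n = len(postures)
    # centroid velocity over a 3-frame window (one-sided at the ends)
    vel = np.zeros((n, 2))
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        dt_win = times[hi] - times[lo]
        vel[i] = (centroids[hi] - centroids[lo]) / dt_win if dt_win > 0 else 0.0
    speed = np.linalg.norm(vel, axis=1)

    records: list[SensorimotorRecord] = []
    for i, (fr, p) in enumerate(zip(frames, postures)):
        axis = p.head - p.tail
        if body_length > 0 and speed[i] < SLOW_SPEED_BL_S * body_length:
            hvec = axis
        else:
            hvec = vel[i]
        heading = float(np.degrees(np.arctan2(hvec[1], hvec[0]))) \
            if np.linalg.norm(hvec) > 0 else np.nan
        rec = SensorimotorRecord(
            t=float(times[i]), frame=fr, head=p.head, tail=p.tail,
            centroid=p.centroid, midpoint=p.midpoint, heading=heading,
            bend=_bend_angle(p.head, p.midpoint, p.tail), speed=float(speed[i]))
        if landscape is not None:
            rec.head_value = landscape.field_at(p.head)
            values, _ = sample_along_skeleton(landscape, p.skeleton)
            rec.skeleton_values = values
            try:
                rec.bearing = bearing_to_gradient(landscape, p.head, hvec)
            except (FlatFieldError, SosError):
                rec.bearing = np.nan
            if isinstance(landscape, SidewaysLightLandscape):
                rec.light_fraction = contour_light_fraction(landscape, p.contour)
        records.append(rec)

    if landscape is not None:
        values = np.array([r.head_value for r in records])
        deriv = np.gradient(values, times) if n > 1 else np.zeros(n)
        if smooth_derivative and n >= 3:
            deriv = np.convolve(deriv, np.ones(3) / 3, mode="same")
        for i, r in enumerate(records):
            r.head_value_derivative = float(deriv[i])
            if i == 0:
                r.relative_change = 0.0
            else:
                prev = records[i - 1].head_value
                r.relative_change = (relative_change(values[i] - prev, prev)
                                     if prev != 0 else np.nan)
    return records


def _spans(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, end) index pairs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def detect_events(records: list[SensorimotorRecord],
                  thresholds: dict | None = None) -> list[EventAnnotation]:
    """Segment the trial into runs, turns and head casts.

    Casts are spans where the head-bend angle exceeds ``cast_angle`` while
    the centroid is slower than the run-speed threshold. Turns are spans of
    heading rate above ``turn_rate`` sustained for at least
    ``min_duration``; frames inside or bordering a head-cast sweep are
    excluded, because the lateral head swing perturbs the centroid-path
    heading without reorienting the body. Runs are the remaining frames.
    Every frame carries exactly one label (cast wins over turn).
    """
    if len(records) < 3:
        raise SosError("at least 3 records required")
    t = np.array([r.t for r in records])
    if np.any(np.diff(t) <= 0):
        raise SosError("timestamps must be strictly increasing")
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    dt = float(np.median(np.diff(t)))
    min_dur = th["min_duration"] if th["min_duration"] is not None else 2 * dt
    min_frames = max(2, int(round(min_dur / dt)))

    heading = np.array([r.heading for r in records])
    bend = np.array([r.bend for r in records])
    speed = np.array([r.speed for r in records])
    # head-tail chord of the straightest frame approximates the body length
    body_length = th.get("body_length") or float(
        np.max([np.linalg.norm(r.head - r.tail) for r in records]))
    if th["run_speed_bl"] is not None:
        speed_gate = th["run_speed_bl"] * body_length
    else:
        # slower than typical running, with headroom for the residual
        # centroid motion the head sweep itself induces
        speed_gate = 1.5 * float(np.median(speed))
    slow = speed < speed_gate

    # centred heading rate (one-sided at the ends): robust to the heading
    # estimate plateauing mid-reorientation
    n = len(records)
    rate = np.zeros(n)
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        rate[i] = abs(_wrap_deg(heading[hi] - heading[lo])) / (t[hi] - t[lo])

    cast_frames = (bend > th["cast_angle"]) & slow
    # full sweep window: any contiguous region of appreciable bend around a
    # cast frame, dilated by ~0.5 s, is off-limits for turn detection — the
    # lateral head swing dominates the centroid path at sweep onset/offset
    # before the bend itself has grown
    sweep = bend > th["cast_angle"] / 3.0
    sweep_spans = [s for s in _spans(sweep)
                   if bend[s[0]:s[1] + 1].max() > th["cast_angle"]]
    dilate = max(1, int(round(0.5 / dt)))
    in_sweep = np.zeros(len(records), dtype=bool)
    for a, b in sweep_spans:
        in_sweep[max(a - dilate, 0):b + dilate + 1] = True

    turn_frames = (rate > th["turn_rate"]) & ~in_sweep

    labels = np.array(["run"] * len(records), dtype=object)
    for a, b in _spans(turn_frames):
        if b - a + 1 >= min_frames:
            labels[a:b + 1] = "turn"
    for a, b in _spans(cast_frames):
        if b - a + 1 >= min_frames:
            labels[a:b + 1] = "cast"

    events: list[EventAnnotation] = []
    for label in ("turn", "cast", "run"):
        for a, b in _spans(labels == label):
            if label == "turn":
                # net reorientation: compare settled headings on either side
                # (medians damp the centroid transient at the turn itself)
                pre = heading[max(a - 3, 0):max(a, 1)]
                post = heading[min(b + 1, n - 1):min(b + 4, n)]
                mag = abs(float(_wrap_deg(np.median(post) - np.median(pre))))
            elif label == "cast":
                mag = float(bend[a:b + 1].max())
            else:
                mag = float(np.sum(speed[a:b + 1]) * dt)
            events.append(EventAnnotation(type=label, start_frame=records[a].frame,
                                          end_frame=records[b].frame, magnitude=mag))
    events.sort(key=lambda e: e.start_frame)
    for r, lab in zip(records, labels):
        r.event_label = lab if lab != "run" else "run"
    return events


def records_to_dataframe(records: list[SensorimotorRecord],
                         units: str = "a.u.", trial_id: str = "trial0",
                         ) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "trial_id": trial_id, "frame": r.frame, "t": r.t,
            "head_x": r.head[0], "head_y": r.head[1],
            "tail_x": r.tail[0], "tail_y": r.tail[1],
            "centroid_x": r.centroid[0], "centroid_y": r.centroid[1],
            "midpoint_x": r.midpoint[0], "midpoint_y": r.midpoint[1],
            "head_value": r.head_value,
            "head_value_derivative": r.head_value_derivative,
            "bearing_deg": r.bearing, "heading_deg": r.heading,
            "bend_deg": r.bend, "speed_mm_s": r.speed,
            "light_fraction_pct": r.light_fraction,
            "relative_change_pct": r.relative_change,
            "event_label": r.event_label,
        }
        if r.skeleton_values is not None and len(r.skeleton_values):
            row["skeleton_tail_minus_head"] = float(
                r.skeleton_values[-1] - r.skeleton_values[0])
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["units"] = units
    return df


def merge_trials(trials: list[pd.DataFrame]) -> pd.DataFrame:
    """Row-concatenate per-trial record tables, preserving trial ids.

    All trials must share the same stimulus units (DataFrame
    ``attrs['units']``); a mismatch raises ``IncompatibleUnitsError``.
    """
    if not trials:
        raise SosError("no trials to merge")
    units = {df.attrs.get("units", "a.u.") for df in trials}
    if len(units) > 1:
        raise IncompatibleUnitsError(f"incompatible_units: {sorted(units)}")
    out = pd.concat(trials, ignore_index=True)
    out.attrs["units"] = units.pop()
    return out


def events_to_dataframe(events: list[EventAnnotation],
                        trial_id: str = "trial0") -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": trial_id, "type": e.type, "start_frame": e.start_frame,
        "end_frame": e.end_frame, "magnitude": e.magnitude} for e in events])
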