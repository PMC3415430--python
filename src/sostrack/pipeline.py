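"""End-to-end orchestration: simulate -> track -> process -> review ->
calibrate -> analyze, driven by a single validated configuration mapping.

Each stage writes its artifacts into the trial directory (background,
crops, offsets, postures, flags, calibration, sensorimotor records and
events) and a JSON manifest records the configuration, seeds and QC
fractions so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd

import sostrack
from sostrack import calibration as cal_mod
from sostrack import fixtures, identity, posture as posture_mod, segmentation
from sostrack import landscapes as land_mod
from sostrack import sensorimotor as sm_mod
from sostrack.errors import SosError

log = logging.getLogger("sostrack")

_KNOWN_SECTIONS = {"simulate", "track", "identity", "calibration", "landscape",
                   "events", "posture", "input", "out", "seed", "verbosity"}


def validate_config(config: dict) -> dict:
    """Schema-check a run configuration; unknown keys are rejected."""
    unknown = set(config) - _KNOWN_SECTIONS
    if unknown:
        raise SosError(f"unknown config keys: {sorted(unknown)}")
    sim = config.get("simulate")
    if sim is not None:
        valid = {f.name for f in dataclass_fields(fixtures.CrawlParams)}
        bad = set(sim) - valid
        if bad:
            raise SosError(f"unknown simulate keys: {sorted(bad)}")
    trk = config.get("track")
    if trk is not None:
        valid = {f.name for f in dataclass_fields(segmentation.TrackConfig)}
        bad = set(trk) - valid
        if bad:
            raise SosError(f"unknown track keys: {sorted(bad)}")
    if "input" not in config and sim is None:
        raise SosError("config needs either an 'input' path or a 'simulate' section")
    return config


def _coerce_params(section: dict) -> fixtures.CrawlParams:
    kwargs = dict(section)
    for key in ("cast_times",):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "turn_times_and_angles" in kwargs:
        kwargs["turn_times_and_angles"] = tuple(
            tuple(x) for x in kwargs["turn_times_and_angles"])
    for key in ("arena_size", "start_xy"):
        if kwargs.get(key) is not None:
            kwargs[key] = tuple(kwargs[key])
    if "clutter" in kwargs:
        kwargs["clutter"] = tuple((tuple(c), r, i) for c, r, i in kwargs["clutter"])
    return fixtures.CrawlParams(**kwargs)


def auto_seed_hints(postures: list) -> tuple[np.ndarray, np.ndarray]:
    """Motion-based head seed for frame-coordinate postures: the endpoint
    with the larger projection on the early direction of travel."""
    cents = np.array([p.centroid for p in postures])
    k = min(len(cents) - 1, 5)
    direction = cents[k] - cents[0]
    if np.linalg.norm(direction) == 0:
        direction = np.array([1.0, 0.0])
    e0, e1 = (np.asarray(e, float) for e in postures[0].endpoints)
    if (e0 - cents[0]).dot(direction) >= (e1 - cents[0]).dot(direction):
        return e0, e1
    return e1, e0


def run_pipeline(config: dict, outdir: str | Path | None = None) -> Path:
    """Run all stages described by ``config``; returns the trial directory."""
    config = validate_config(config)
    outdir = Path(outdir if outdir is not None else config.get("out", "trial_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    # --- frames ---------------------------------------------------------
    truths = None
    if "simulate" in config:
        params = _coerce_params(config["simulate"])
        log.info("simulating %s frames", int(params.duration / params.dt) + 1)
        frames, truths = fixtures.simulate_crawl(params)
        sampling = params.dt
    else:
        frames = fixtures.read_sequence(config["input"])
        sampling = config.get("track", {}).get("sampling_interval", 1.0)

    # --- online tracking ------------------------------------------------
    track_kwargs = dict(config.get("track", {}))
    track_kwargs.setdefault("sampling_interval", sampling)
    tc = segmentation.TrackConfig(**track_kwargs)
    trial = segmentation.track_stream(frames, tc)
    segmentation.save_trial(trial, outdir)
    log.info("tracked %d frames, stop reason: %s", len(trial.crops), trial.stop_reason)

    # --- offline posture processing --------------------------------------
    pcfg = config.get("posture", {})
    masks = segmentation.crop_masks(trial)
    # analyze in crop-local coordinates, then shift into frame coordinates
    # so identity propagation compares positions across moving crop boxes
    postures = [posture_mod.translate(posture_mod.analyze_mask(m, **pcfg), box[:2])
                for m, (_, box) in zip(masks, trial.crops)]
    qc = posture_mod.qc_summary(postures)
    log.info("posture QC: %s", qc)

    # --- head/tail identity ----------------------------------------------
    idc = config.get("identity", {})
    if "head_xy" in idc and "tail_xy" in idc:
        head_hint = np.asarray(idc["head_xy"], float)
        tail_hint = np.asarray(idc["tail_xy"], float)
    else:
        head_hint, tail_hint = auto_seed_hints(postures)
    traj = identity.label_trajectory(postures, head_hint, tail_hint)
    pd.DataFrame(traj.flagged_frames, columns=["frame", "reason"]).to_csv(
        outdir / "flags.csv", index=False)
    corrections_path = idc.get("corrections")
    if corrections_path:
        corr = pd.read_csv(corrections_path)
        traj = identity.resolve_flags(
            traj, list(zip(corr["frame"].astype(int), corr["action"])))

    # --- calibration ------------------------------------------------------
    ccfg = config.get("calibration", {})
    fps = ccfg.get("frames_per_second", 1.0 / trial.sampling_interval)
    if "landmarks" in ccfg:
        cal = cal_mod.fit_scale(ccfg["landmarks"], frames_per_second=fps)
    else:
        cal = cal_mod.Calibration(mm_per_pixel=ccfg.get("mm_per_pixel", 1.0),
                                  frames_per_second=fps)
    cal_mod.save_calibration(cal, outdir / "calibration.json")
    # postures are already in frame coordinates; only the scale applies
    arena_postures = [cal_mod.to_arena_frame(p, (0.0, 0.0), cal)
                      for p in traj.postures]
    arena_traj = identity.LabeledTrajectory(
        postures=arena_postures, flagged_frames=traj.flagged_frames,
        corrections=traj.corrections)
    _save_postures(arena_traj, outdir)

    # --- sensorimotor records and events ---------------------------------
    landscape = None
    if "landscape" in config:
        landscape = land_mod.landscape_from_config(config["landscape"])
    records = sm_mod.build_records(arena_traj, cal, landscape)
    events = sm_mod.detect_events(records, config.get("events"))
    units = getattr(landscape, "units", "a.u.") if landscape else "a.u."
    df = sm_mod.records_to_dataframe(records, units=units,
                                     trial_id=outdir.name)
    df.to_csv(outdir / "sensorimotor.csv", index=False)
    sm_mod.events_to_dataframe(events, trial_id=outdir.name).to_csv(
        outdir / "events.csv", index=False)

    manifest = {
        "version": sostrack.__version__,
        "config": _jsonable(config),
        "qc": qc,
        "n_frames": trial.n_frames,
        "stop_reason": trial.stop_reason,
        "n_flagged": len(traj.flagged_frames),
        "n_events": len(events),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _save_postures(traj: identity.LabeledTrajectory, outdir: Path) -> None:
    """Flat posture table (CSV) plus full per-frame geometry (HDF5)."""
    import h5py

    rows = []
    for i, p in enumerate(traj.postures):
        rows.append({
            "frame": i,
            "head_x": p.head[0], "head_y": p.head[1],
            "tail_x": p.tail[0], "tail_y": p.tail[1],
            "centroid_x": p.centroid[0], "centroid_y": p.centroid[1],
            "midpoint_x": p.midpoint[0], "midpoint_y": p.midpoint[1],
            "area": p.area, "perimeter": p.perimeter,
            "skeleton_length": p.skeleton_length,
            "flags": "|".join(sorted(p.flags)),
        })
    pd.DataFrame(rows).to_csv(outdir / "postures.csv", index=False)
    with h5py.File(outdir / "postures.h5", "w") as h5:
        for i, p in enumerate(traj.postures):
            grp = h5.create_group(f"frame_{i:04d}")
            grp.create_dataset("contour", data=np.asarray(p.contour, float))
            grp.create_dataset("skeleton", data=np.asarray(p.skeleton, float))
            grp.attrs["flags"] = "|".join(sorted(p.flags))
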