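"""Head/tail identity assignment and propagation across frames.

Skeleton endpoints are interchangeable until labelled. The first frame is
seeded from user-supplied hints (replacing an on-screen click); from then
on the head is the candidate closest to the previous head — a distance rule
that works for stationary and backward-crawling animals alike, provided the
per-frame displacement stays below about half a body length. Frames where
the rule could have failed (blob-like postures, large jumps, exact ties)
are flagged for review, and corrections (swap / discard / keep) are applied
from a replayable list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sostrack.errors import AmbiguousSeedError, SosError
from sostrack.posture import Posture

#: candidates closer than this (px) to equidistant trigger the tie-break
TIE_TOLERANCE_PX = 1.0
#: head jumps beyond this fraction of skeleton length get flagged
JUMP_FRACTION = 0.5


@dataclass
class LabeledTrajectory:
    postures: list[Posture]
    flagged_frames: list[tuple[int, str]] = field(default_factory=list)
    corrections: list[tuple[int, str]] = field(default_factory=list)

    def retained(self) -> list[tuple[int, Posture]]:
        return [(i, p) for i, p in enumerate(self.postures)
                if "discarded" not in p.flags]


def seed_identity(posture: Posture, head_hint, tail_hint) -> Posture:
    """Label endpoints from hints: the endpoint nearest ``head_hint``
    becomes the head. Raises ``AmbiguousSeedError`` when both hints select
    the same endpoint."""
    if len(posture.endpoints) != 2:
        raise SosError("posture does not have two endpoint candidates")
    head_hint = np.asarray(head_hint, dtype=float)
    tail_hint = np.asarray(tail_hint, dtype=float)
    e0, e1 = posture.endpoints
    head_pick = int(np.linalg.norm(e1 - head_hint) < np.linalg.norm(e0 - head_hint))
    tail_pick = int(np.linalg.norm(e1 - tail_hint) < np.linalg.norm(e0 - tail_hint))
    if head_pick == tail_pick:
        raise AmbiguousSeedError("ambiguous_seed: hints select the same endpoint")
    # orient so that the hinted head endpoint leads the skeleton
    near_head = np.asarray(posture.endpoints[head_pick], float)
    if np.linalg.norm(posture.skeleton[0] - near_head) <= \
            np.linalg.norm(posture.skeleton[-1] - near_head):
        return posture.with_head(0)
    return posture.with_head(1)


def propagate_identity(prev: Posture, curr: Posture) -> tuple[Posture, bool]:
    """Distance rule: the candidate nearest the previous head becomes the
    head. Returns (labelled posture, tie_flag); near-equidistant candidates
    are resolved by body-axis continuity and flagged."""
    if len(curr.endpoints) != 2:
        curr.flags.add("swap_suspect")
        return curr, True
    c0 = np.asarray(curr.skeleton[0], float)
    c1 = np.asarray(curr.skeleton[-1], float)
    d0 = np.linalg.norm(c0 - prev.head)
    d1 = np.linalg.norm(c1 - prev.head)
    tie = abs(d0 - d1) < TIE_TOLERANCE_PX
    if tie:
        # continuity of the tail->head axis direction with the previous frame
        prev_axis = prev.head - prev.tail
        a0 = c0 - c1
        pick = 0 if np.dot(prev_axis, a0) >= 0 else 1
        curr.flags.add("swap_suspect")
    else:
        pick = 0 if d0 < d1 else 1
    return curr.with_head(pick), tie


def label_trajectory(postures: list[Posture], head_hint, tail_hint,
                     ) -> LabeledTrajectory:
    """Seed the first frame and propagate identity through the sequence."""
    if not postures:
        raise SosError("empty trajectory")
    labelled = [seed_identity(postures[0], head_hint, tail_hint)]
    for p in postures[1:]:
        nxt, _ = propagate_identity(labelled[-1], p)
        labelled.append(nxt)
    traj = LabeledTrajectory(postures=labelled)
    traj.flagged_frames = flag_ambiguities(traj)
    return traj


def flag_ambiguities(trajectory: LabeledTrajectory) -> list[tuple[int, str]]:
    """Frames where head identity may be wrong: blob-like postures, head
    displacements above half a skeleton length, and distance-rule ties."""
    flags: list[tuple[int, str]] = []
    postures = trajectory.postures
    for i, p in enumerate(postures):
        if "blob_like" in p.flags:
            flags.append((i, "blob_like"))
        if "swap_suspect" in p.flags:
            flags.append((i, "tie"))
        if i > 0:
            jump = np.linalg.norm(p.head - postures[i - 1].head)
            limit = JUMP_FRACTION * max(p.skeleton_length, 1e-9)
            if jump > limit:
                flags.append((i, "large_jump"))
    return flags


def resolve_flags(trajectory: LabeledTrajectory,
                  corrections: list[tuple[int, str]]) -> LabeledTrajectory:
    """Apply review corrections.

    ``swap`` exchanges head and tail from that frame onward until the next
    correction; ``discard`` marks a single frame discarded; ``keep`` clears
    its flag. Corrections on unflagged frames are applied with a warning
    flag in the returned record.
    """
    flagged = {i for i, _ in trajectory.flagged_frames}
    ordered = sorted(corrections)
    postures = [p.with_head(0) for p in trajectory.postures]  # shallow rebuild
    swapped = False
    boundaries = {i for i, _ in ordered}
    actions = dict(ordered)
    for i in range(len(postures)):
        if i in boundaries:
            action = actions[i]
            if action == "swap":
                swapped = not swapped
            elif action == "discard":
                postures[i].flags.add("discarded")
            elif action == "keep":
                postures[i].flags.discard("swap_suspect")
        if swapped:
            postures[i] = postures[i].with_head(1)
    out = LabeledTrajectory(postures=postures,
                            corrections=trajectory.corrections + ordered)
    out.flagged_frames = [(i, r) for i, r in flag_ambiguities(out)
                          if actions.get(i) != "keep"]
    for i, _ in ordered:
        if i not in flagged:
            out.flagged_frames.append((i, "correction_on_unflagged"))
    return out
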