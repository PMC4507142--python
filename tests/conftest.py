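"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every statistic with explicit
scalar arithmetic (triple loops, closed forms) so they share no code path
with the vectorized/library implementations they check.
"""
from __future__ import annotations

import math

import numpy as np
import pytest

from gakit.channels import ChannelEvent, EventList
from gakit.synthetic import TrajectoryFrames


@pytest.fixture()
def two_step_events() -> EventList:
    """Hand-scheduled fixture: two non-overlapping 2.8 pA openings."""
    return EventList(events=[
        ChannelEvent(start=0.1, duration=0.10, step_amplitude=2.8, level=1),
        ChannelEvent(start=0.4, duration=0.05, step_amplitude=2.8, level=1),
    ])


# ---------------------------------------------------------------------------
# Brute-force oracles (explicit minimum-image scalar arithmetic)
# ---------------------------------------------------------------------------

def min_image_distance(a, b, box) -> float:
    d2 = 0.0
    for k in range(3):
        dd = float(a[k]) - float(b[k])
        dd -= box[k] * round(dd / box[k])
        d2 += dd * dd
    return math.sqrt(d2)


def brute_force_bound_counts(frames: TrajectoryFrames, cutoff: float,
                             ion="NA", phos="P_DOPC") -> list[int]:
    counts = []
    for f in range(frames.n_frames):
        box = frames.box[f]
        c = 0
        for a in frames.groups[ion][f]:
            best = math.inf
            for p in frames.groups[phos][f]:
                best = min(best, min_image_distance(a, p, box))
            if best < cutoff:
                c += 1
        counts.append(c)
    return counts


def brute_force_pair_histogram(frames: TrajectoryFrames, ref: str, tgt: str,
                               r_max: float, dr: float) -> np.ndarray:
    """Raw shell pair counts summed over frames, counting ordered pairs and
    skipping self pairs for a same-group RDF."""
    nbins = int(math.ceil(r_max / dr))
    hist = np.zeros(nbins)
    same = ref == tgt
    for f in range(frames.n_frames):
        box = frames.box[f]
        a_grp = frames.groups[ref][f]
        b_grp = frames.groups[tgt][f]
        for i, a in enumerate(a_grp):
            for j, b in enumerate(b_grp):
                if same and i == j:
                    continue
                r = min_image_distance(a, b, box)
                if r < r_max and r > 0:
                    hist[int(r / dr)] += 1
    return hist


def occupancy_at(events, t: float) -> int:
    """Number of events open at time t (brute force over the event list)."""
    return sum(1 for e in events if e.start <= t < e.start + e.duration)


def match_events(truth, detected, start_tol: float):
    """Greedy one-to-one matching of detected to true events by start time."""
    used = [False] * len(detected)
    matched = 0
    det_starts = [d.start for d in detected]
    for ev in truth:
        best, best_d = None, start_tol
        for j, s in enumerate(det_starts):
            if used[j]:
                continue
            d = abs(s - ev.start)
            if d <= best_d:
                best, best_d = j, d
        if best is not None:
            used[best] = True
            matched += 1
    return matched
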