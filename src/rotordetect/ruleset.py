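"""Rule-based rotational-activity detector (staircase rule).

The detector mirrors the published description of clinical
rotational-activity mapping on a star catheter: local activation times
(LATs) are the instants of maximum negative slope of each unipolar
electrogram; electrodes are arranged in concentric rings; a ring frames
one candidate rotation when its LATs, ordered by ring angle, form a
strictly monotone (cyclic) staircase spanning more than 50% of the
dominant cycle; and at least three consecutive same-chirality rotations
constitute a rotational event.

Ascending staircases along the counterclockwise ring order are labeled
"counterclockwise", descending ones "clockwise".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .catheter import CatheterLayout, ChannelOrdering, build_layout, ring_order
from .containers import Acquisition, RotationalEvent

__all__ = [
    "LatSeries",
    "CycleEstimate",
    "RotationCandidate",
    "RulesetParams",
    "InsufficientLats",
    "detect_lats",
    "dominant_cycle",
    "ring_staircase_scan",
    "group_consecutive",
    "detect_rotational_activity",
]


class InsufficientLats(ValueError):
    """Raised when too few activations exist to estimate a cycle length."""


@dataclass
class LatSeries:
    """Per-channel activation instants in ms, strictly increasing."""

    lats_ms: list[np.ndarray]
    refractory_ms: float

    def __post_init__(self) -> None:
        for c, lats in enumerate(self.lats_ms):
            d = np.diff(lats)
            if d.size and d.min() <= 0:
                raise ValueError(f"channel {c}: LATs not strictly increasing")

    def shift(self, delta_ms: float) -> "LatSeries":
        return LatSeries([l + delta_ms for l in self.lats_ms], self.refractory_ms)


@dataclass(frozen=True)
class CycleEstimate:
    """Dominant cycle length estimate in ms."""

    cl: float
    method: str = "pooled-median"

    def __post_init__(self) -> None:
        if self.cl <= 0:
            raise ValueError("cycle length must be positive")


@dataclass(frozen=True)
class RotationCandidate:
    """One candidate rotation frame found by the ring staircase scan."""

    t_start: float
    t_end: float
    chirality: str
    ring_index: int


@dataclass
class RulesetParams:
    """Tunables of the rule detector.

    slope_threshold : mV/ms, or None for the adaptive default (20% of the
        channel's 98th-percentile absolute slope).
    refractory_ms : minimum spacing between accepted LATs on one channel.
    span_fraction : required LAT span per rotation as a fraction of the
        dominant cycle (the ">50% of the dominant cycle" rule).
    min_rotations : consecutive same-chirality rotations needed for an
        event ("more than 2 consecutive events" read as >= 3).
    """

    slope_threshold: float | None = None
    refractory_ms: float = 90.0
    span_fraction: float = 0.5
    min_rotations: int = 3
    rings: tuple[int, ...] | None = None  # None = scan every ring


def detect_lats(
    acq: Acquisition,
    slope_threshold: float | None = None,
    refractory_ms: float = 90.0,
) -> LatSeries:
    """Detect LATs as instants of maximum negative slope per channel.

    Slope is the central-difference derivative in mV/ms.  Every local
    minimum of the slope below ``-slope_threshold`` is a candidate;
    candidates are accepted greedily in order of steepness subject to the
    refractory spacing.  With ``slope_threshold=None`` the threshold is
    adaptive: 20% of the channel's 98th-percentile absolute slope.
    """
    if acq.kind != "unipolar":
        raise ValueError("LAT detection requires unipolar electrograms")
    slope = np.gradient(acq.signal, axis=1) * acq.fs / 1000.0  # mV/ms
    refr_samp = refractory_ms * acq.fs / 1000.0
    out: list[np.ndarray] = []
    for c in range(acq.n_channels):
        s = slope[c]
        thr = slope_threshold
        if thr is None:
            thr = 0.2 * np.percentile(np.abs(s), 98.0)
        if thr <= 0:
            out.append(np.empty(0))
            continue
        peaks, props = find_peaks(-s, height=thr)
        if peaks.size == 0:
            out.append(np.empty(0))
            continue
        # steepest first, greedy refractory acceptance (sorted neighbors)
        import bisect

        order = np.argsort(-props["peak_heights"], kind="stable")
        accepted: list[int] = []
        for i in order:
            p = int(peaks[i])
            j = bisect.bisect_left(accepted, p)
            if j > 0 and p - accepted[j - 1] < refr_samp:
                continue
            if j < len(accepted) and accepted[j] - p < refr_samp:
                continue
            accepted.insert(j, p)
        out.append(np.array(accepted, dtype=float) * 1000.0 / acq.fs)
    return LatSeries(out, refractory_ms)


def dominant_cycle(
    lats: LatSeries, window: tuple[float, float] | None = None
) -> CycleEstimate:
    """Dominant cycle length: pooled median of consecutive inter-LAT gaps.

    The median is robust to occasional missed detections (a missed beat
    doubles one interval but barely moves the median).
    """
    intervals: list[np.ndarray] = []
    for l in lats.lats_ms:
        if window is not None:
            l = l[(l >= window[0]) & (l <= window[1])]
        if l.size >= 2:
            intervals.append(np.diff(l))
    if not intervals:
        raise InsufficientLats("need >= 2 LATs on at least one channel")
    return CycleEstimate(float(np.median(np.concatenate(intervals))))


def _cyclic_chirality(values: np.ndarray) -> str | None:
    """Chirality if the cyclic sequence is strictly monotone, else None.

    A cyclic sequence of distinct values ascends under exactly one
    rotation of its start iff exactly one of its cyclic successive
    differences is negative (descends iff exactly one is positive).
    """
    n = values.size
    if np.unique(values).size != n:
        return None
    d = np.roll(values, -1) - values
    neg = int(np.sum(d < 0))
    if neg == 1:
        return "counterclockwise"
    if neg == n - 1:
        return "clockwise"
    return None


def ring_staircase_scan(
    lats: LatSeries,
    ring: ChannelOrdering,
    cl: CycleEstimate,
    layout: CatheterLayout | None = None,
    span_fraction: float = 0.5,
) -> list[RotationCandidate]:
    """Scan one ring for candidate rotations (cycle-length frames).

    Every LAT of every ring electrode anchors a frame of one cycle
    length.  A frame passes when each ring electrode contributes exactly
    one LAT, the LATs ordered by ring angle are cyclically strictly
    monotone, and their span exceeds ``span_fraction`` of the dominant
    cycle.  Passing frames are thinned so consecutive candidates are at
    least 0.7 cycles apart (one candidate per rotation).
    """
    layout = layout or build_layout()
    if len(ring.index_map) < 3:
        raise ValueError("ring needs >= 3 electrodes")
    ring_idx = ring.index_map[0][1]
    elec = [layout.flat_index(s, p) for s, p in ring.index_map]
    ring_lats = [lats.lats_ms[e] for e in elec]
    nonempty = [l for l in ring_lats if l.size]
    if not nonempty:
        return []
    anchors = np.sort(np.concatenate(nonempty))
    eps = 1e-6
    n = len(elec)
    # vectorized over anchors: exactly-one-LAT-per-electrode frames
    lo = np.empty((n, anchors.size), dtype=np.intp)
    counts = np.zeros((n, anchors.size), dtype=np.intp)
    for i, l in enumerate(ring_lats):
        if l.size == 0:
            continue
        lo[i] = np.searchsorted(l, anchors - eps, side="left")
        counts[i] = np.searchsorted(l, anchors + cl.cl - eps, side="left") - lo[i]
    frame_ok = (counts == 1).all(axis=0)
    if not frame_ok.any():
        return []
    vals = np.stack([
        ring_lats[i][np.minimum(lo[i, frame_ok], ring_lats[i].size - 1)]
        for i in range(n)
    ])  # (n, n_frames)
    d = np.roll(vals, -1, axis=0) - vals
    neg = (d < 0).sum(axis=0)
    strict = (d != 0).all(axis=0)
    ccw = strict & (neg == 1)
    cw = strict & (neg == n - 1)
    span_ok = vals.max(axis=0) - vals.min(axis=0) > span_fraction * cl.cl
    keep = (ccw | cw) & span_ok
    candidates = [
        RotationCandidate(
            float(vals[:, j].min()), float(vals[:, j].max()),
            "counterclockwise" if ccw[j] else "clockwise", ring_idx,
        )
        for j in np.flatnonzero(keep)
    ]
    # thin near-duplicate frames: one candidate per rotation
    thinned: list[RotationCandidate] = []
    for c in sorted(candidates, key=lambda c: c.t_start):
        if not thinned or c.t_start >= thinned[-1].t_start + 0.7 * cl.cl:
            thinned.append(c)
    return thinned


def group_consecutive(
    candidates: list[RotationCandidate],
    cl: CycleEstimate,
    min_rotations: int = 3,
) -> list[RotationalEvent]:
    """Group candidate rotations into events of >= 3 consecutive rotations.

    A run continues while the next candidate has the same chirality and
    starts within one cycle of the previous candidate's end.  Runs
    shorter than ``min_rotations`` are discarded.
    """
    events: list[RotationalEvent] = []
    run: list[RotationCandidate] = []

    def flush() -> None:
        if len(run) >= min_rotations:
            events.append(
                RotationalEvent(
                    run[0].t_start,
                    run[-1].t_end,
                    run[0].chirality,
                    len(run),
                    run[0].ring_index,
                )
            )

    for c in sorted(candidates, key=lambda c: c.t_start):
        if run and (
            c.chirality != run[-1].chirality or c.t_start - run[-1].t_end > cl.cl
        ):
            flush()
            run = []
        run.append(c)
    flush()
    return events


def _merge_across_rings(events: list[RotationalEvent]) -> list[RotationalEvent]:
    """Merge overlapping same-chirality events from different rings.

    The merged event takes the union time interval and the maximum
    rotation count (with its ring index).
    """
    merged: list[RotationalEvent] = []
    for ev in sorted(events, key=lambda e: e.t_start):
        hit = None
        for i, m in enumerate(merged):
            if m.chirality == ev.chirality and ev.t_start <= m.t_end and ev.t_end >= m.t_start:
                hit = i
                break
        if hit is None:
            merged.append(ev)
        else:
            m = merged[hit]
            best = m if m.n_rotations >= ev.n_rotations else ev
            merged[hit] = RotationalEvent(
                min(m.t_start, ev.t_start),
                max(m.t_end, ev.t_end),
                m.chirality,
                best.n_rotations,
                best.ring_index,
            )
    return merged


def detect_rotational_activity(
    acq: Acquisition,
    layout: CatheterLayout | None = None,
    params: RulesetParams | None = None,
) -> list[RotationalEvent]:
    """Full rule detector: LATs -> dominant cycle -> ring scans -> events.

    Scans every concentric ring by default and merges overlapping
    same-chirality events across rings.  Returns an empty list when the
    signal has too few activations to estimate a cycle.
    """
    layout = layout or build_layout()
    params = params or RulesetParams()
    lats = detect_lats(acq, params.slope_threshold, params.refractory_ms)
    try:
        cl = dominant_cycle(lats)
    except InsufficientLats:
        return []
    rings = params.rings
    if rings is None:
        rings = tuple(range(layout.electrodes_per_spline))
    events: list[RotationalEvent] = []
    for r in rings:
        ring = ring_order(layout, r)
        cands = ring_staircase_scan(lats, ring, cl, layout, params.span_fraction)
        events.extend(group_consecutive(cands, cl, params.min_rotations))
    return _merge_across_rings(events)
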