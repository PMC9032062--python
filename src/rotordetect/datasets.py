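"""Window extraction, labeling, augmentation and patient-wise splits.

Turns labeled 30 s acquisitions into balanced training/validation/test
sets of fixed-length normalized windows: 50%-overlap sliding windows,
binary labels from rotational-event overlap, 5-fold ring-permutation
augmentation (optionally composed with time and channel flips), per-
patient 1:1 class rebalancing, and a chronological patient-level
train/test split with a stratified window-level validation carve-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catheter import (
    CatheterLayout,
    ChannelOrdering,
    bipolar_ordering,
    build_layout,
    spline_rotation,
    unipolar_ordering,
)
from .containers import Acquisition, LabeledWindow, RotationalEvent
from . import preprocess
from .ruleset import RulesetParams, detect_lats

__all__ = [
    "SplitSpec",
    "DataSplits",
    "slide_windows",
    "label_window",
    "flip_time",
    "flip_channels",
    "augment",
    "rebalance",
    "split_patients",
    "build_dataset",
]


@dataclass
class SplitSpec:
    """Patient-wise chronological split specification.

    90% of patients (floor) go to training, the rest to test, in
    enrollment order; validation windows are carved out of the training
    windows, stratified by label (fraction ``val_fraction``).
    """

    train_fraction: float = 0.9
    val_fraction: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (0 <= self.val_fraction < 1):
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class DataSplits:
    train: list[LabeledWindow] = field(default_factory=list)
    val: list[LabeledWindow] = field(default_factory=list)
    test: list[LabeledWindow] = field(default_factory=list)

    def counts(self) -> dict:
        def c(ws):
            pos = sum(w.y for w in ws)
            return {"n": len(ws), "pos": pos, "neg": len(ws) - pos}

        return {"train": c(self.train), "val": c(self.val), "test": c(self.test)}


def slide_windows(
    acq: Acquisition, window_ms: float, overlap_fraction: float = 0.5
) -> list[tuple[float, np.ndarray]]:
    """Sliding windows from t=0 with the given overlap; remainder dropped.

    Yields ``floor((duration - window) / step) + 1`` windows with
    ``step = window * (1 - overlap)``.
    """
    dur = acq.duration_ms
    if window_ms > dur:
        raise ValueError("window longer than acquisition")
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap must be in [0, 1)")
    step_ms = window_ms * (1.0 - overlap_fraction)
    n_win = int(np.floor((dur - window_ms) / step_ms)) + 1
    w_samp = int(round(window_ms * acq.fs / 1000.0))
    out = []
    for i in range(n_win):
        t0 = i * step_ms
        i0 = int(round(t0 * acq.fs / 1000.0))
        out.append((t0, acq.signal[:, i0 : i0 + w_samp]))
    return out


def label_window(
    t_offset_ms: float,
    window_ms: float,
    events: list[RotationalEvent],
    min_rotation_overlap: float = 1.0,
    rule: str = "rotation",
) -> int:
    """Binary rotor label for a window.

    ``rule="rotation"`` (default): positive iff some event overlaps the
    window by at least ``min_rotation_overlap`` rotations (one rotation's
    duration is the event duration over its rotation count).
    ``rule="any"``: positive on any strictly positive overlap.
    """
    t1 = t_offset_ms + window_ms
    for ev in events:
        ov = ev.overlap_ms(t_offset_ms, t1)
        if rule == "any":
            if ov > 0:
                return 1
        elif ov >= min_rotation_overlap * ev.duration_ms / ev.n_rotations:
            return 1
    return 0


def flip_time(w: LabeledWindow) -> LabeledWindow:
    """Reverse the time axis; the rotor label is preserved (a reversed
    staircase is a staircase of opposite chirality, still a rotor)."""
    return LabeledWindow(
        w.x[:, ::-1].copy(), w.y, w.patient_id, w.acq_index, w.t_offset_ms,
        _tag(w.augmentation, "tflip"),
    )


def flip_channels(w: LabeledWindow) -> LabeledWindow:
    """Reverse the channel-row order; label preserved."""
    return LabeledWindow(
        w.x[::-1].copy(), w.y, w.patient_id, w.acq_index, w.t_offset_ms,
        _tag(w.augmentation, "cflip"),
    )


def _tag(base: str, extra: str) -> str:
    if extra in base.split("+"):  # involution: applying twice removes the tag
        parts = [p for p in base.split("+") if p != extra]
        return "+".join(parts) or "orig"
    return extra if base == "orig" else f"{base}+{extra}"


def _row_permutation(ordering: ChannelOrdering, start_spline: int) -> list[int]:
    rot = spline_rotation(ordering, start_spline)
    row_of = {sp: i for i, sp in enumerate(ordering.index_map)}
    return [row_of[sp] for sp in rot.index_map]


def augment(
    w: LabeledWindow,
    layout: CatheterLayout | None = None,
    ordering: ChannelOrdering | None = None,
    flips: bool = False,
) -> list[LabeledWindow]:
    """Ring-permutation augmentation: the 5 spline rotations per window.

    With ``flips=True`` each rotation is additionally composed with the
    time flip, the channel flip, and both (4 variants per rotation, 20
    in total).  All variants keep the label.
    """
    layout = layout or build_layout()
    if ordering is None:
        ordering = (
            unipolar_ordering(layout)
            if w.x.shape[0] == layout.n_electrodes
            else bipolar_ordering(layout)
        )
    if len(ordering) != w.x.shape[0]:
        raise ValueError("ordering does not match window channel count")
    out = []
    for start in range(1, ordering.n_splines + 1):
        perm = _row_permutation(ordering, start)
        base = LabeledWindow(
            w.x[perm].copy(), w.y, w.patient_id, w.acq_index, w.t_offset_ms,
            _tag(w.augmentation, f"rot{start}") if start > 1 else w.augmentation,
        )
        out.append(base)
        if flips:
            ft = flip_time(base)
            out.extend([ft, flip_channels(base), flip_channels(ft)])
    return out


def rebalance(
    windows: list[LabeledWindow], ratio: float = 1.0, seed: int = 0
) -> list[LabeledWindow]:
    """Per-patient class rebalancing.

    Keeps every positive window and a seeded random sample of negatives
    at ``ratio`` negatives per positive (1:1 default).  Patients without
    any positive window are dropped entirely.
    """
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[LabeledWindow]] = {}
    for w in windows:
        by_patient.setdefault(w.patient_id, []).append(w)
    out: list[LabeledWindow] = []
    for pid in sorted(by_patient):
        ws = by_patient[pid]
        pos = [w for w in ws if w.y == 1]
        neg = [w for w in ws if w.y == 0]
        if not pos:
            continue
        n_keep = min(len(neg), int(round(ratio * len(pos))))
        keep_idx = rng.choice(len(neg), size=n_keep, replace=False) if n_keep else []
        out.extend(pos)
        out.extend(neg[i] for i in sorted(keep_idx))
    return out


def split_patients(
    windows: list[LabeledWindow], spec: SplitSpec | None = None
) -> DataSplits:
    """Chronological patient split plus stratified validation carve-out.

    Patients (sorted by id, i.e. enrollment order) are assigned first
    ``floor(train_fraction * n)`` to training and the rest to test; no
    patient appears in both.  Validation windows are sampled from the
    training windows stratified by label with the spec's seed.
    """
    spec = spec or SplitSpec()
    patients = sorted({w.patient_id for w in windows})
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    n_train = int(np.floor(spec.train_fraction * len(patients)))
    n_train = max(1, min(n_train, len(patients) - 1))
    train_pat = set(patients[:n_train])
    train_all = [w for w in windows if w.patient_id in train_pat]
    test = [w for w in windows if w.patient_id not in train_pat]
    rng = np.random.default_rng(spec.seed)
    val: list[LabeledWindow] = []
    train: list[LabeledWindow] = []
    for label in (0, 1):
        grp = [w for w in train_all if w.y == label]
        n_val = int(round(spec.val_fraction * len(grp)))
        idx = set(rng.choice(len(grp), size=n_val, replace=False)) if n_val else set()
        for i, w in enumerate(grp):
            (val if i in idx else train).append(w)
    return DataSplits(train=train, val=val, test=test)


def _acquisition_windows(
    acq: Acquisition,
    events: list[RotationalEvent],
    layout: CatheterLayout,
    signal_type: str,
    window_ms: float,
    target_fs: float,
    overlap: float,
    label_rule: str,
    min_rotation_overlap: float,
    filter_signals: bool,
    ruleset_params: RulesetParams | None,
) -> list[LabeledWindow]:
    uni = acq
    if filter_signals:
        uni = preprocess.bandpass(uni)
    if signal_type == "bipolar":
        sig = preprocess.derive_bipolar(acq, layout)
        if filter_signals:
            sig = preprocess.bandpass(sig)
    elif signal_type == "unipolar":
        sig = uni
    elif signal_type == "lat-train":
        lats = detect_lats(
            uni,
            (ruleset_params or RulesetParams()).slope_threshold,
            (ruleset_params or RulesetParams()).refractory_ms,
        )
        sig = preprocess.lat_train(uni, lats.lats_ms)
    else:
        raise ValueError(f"unknown signal type {signal_type!r}")
    sig = preprocess.resample(sig, target_fs)
    out = []
    for t0, x in slide_windows(sig, window_ms, overlap):
        y = label_window(t0, window_ms, events, min_rotation_overlap, label_rule)
        xn = x if sig.kind == "lat-train" else preprocess.percentile_normalize(x)
        out.append(
            LabeledWindow(np.asarray(xn, dtype=np.float32), y, acq.patient_id,
                          acq.acq_index, t0)
        )
    return out


def build_dataset(
    cohort: list[tuple[Acquisition, list[RotationalEvent]]],
    signal_type: str = "bipolar",
    window_ms: float = 2500.0,
    target_fs: float = 500.0,
    overlap: float = 0.5,
    *,
    layout: CatheterLayout | None = None,
    split: SplitSpec | None = None,
    label_rule: str = "rotation",
    min_rotation_overlap: float = 1.0,
    augment_flips: bool = False,
    rebalance_ratio: float = 1.0,
    filter_signals: bool = True,
    ruleset_params: RulesetParams | None = None,
    seed: int = 0,
) -> DataSplits:
    """Full window-set construction from a labeled cohort.

    Per acquisition: derive the requested signal representation
    (filtered unipolar, filtered bipolar, or binary LAT trains — LAT
    trains are not percentile-normalized, they are already 0/1),
    down-sample, window, normalize and label.  Then rebalance classes
    per patient, split patients chronologically, and apply the 5-fold
    ring-permutation augmentation (training windows optionally also get
    time/channel flips; test windows get the ring permutations only).
    """
    layout = layout or build_layout()
    split = split or SplitSpec(seed=seed)
    windows: list[LabeledWindow] = []
    for acq, events in cohort:
        windows.extend(
            _acquisition_windows(
                acq, events, layout, signal_type, window_ms, target_fs, overlap,
                label_rule, min_rotation_overlap, filter_signals, ruleset_params,
            )
        )
    windows = rebalance(windows, rebalance_ratio, seed)
    splits = split_patients(windows, split)
    ordering = (
        unipolar_ordering(layout)
        if signal_type in ("unipolar", "lat-train")
        else bipolar_ordering(layout)
    )
    splits.train = [
        v for w in splits.train
        for v in augment(w, layout, ordering, flips=augment_flips)
    ]
    splits.val = [v for w in splits.val for v in augment(w, layout, ordering)]
    splits.test = [v for w in splits.test for v in augment(w, layout, ordering)]
    return splits
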