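"""Windowing, labeling, augmentation, rebalancing and patient splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotordetect.catheter import build_layout, unipolar_ordering
from rotordetect.containers import Acquisition, LabeledWindow, RotationalEvent
from rotordetect.datasets import (
    SplitSpec,
    augment,
    build_dataset,
    flip_channels,
    flip_time,
    label_window,
    rebalance,
    slide_windows,
    split_patients,
)


def make_acq(duration_ms=30_000.0, fs=1000.0, channels=4):
    n = int(duration_ms * fs / 1000)
    return Acquisition(np.zeros((channels, n)), fs, "unipolar")


def make_window(y, pid="P1", seed=0, shape=(20, 100)):
    x = np.random.default_rng(seed).random(shape)
    return LabeledWindow(x, y, pid, 0, 0.0)


class TestSlideWindows:
    @pytest.mark.parametrize(
        "window_ms,expected", [(2500.0, 23), (500.0, 119), (30_000.0, 1)]
    )
    def test_reference_counts(self, window_ms, expected):
        assert len(slide_windows(make_acq(), window_ms, 0.5)) == expected

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(1000, 12_000), st.integers(200, 3000),
        st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_count_matches_brute_force(self, dur, win, overlap):
        if win > dur:
            return
        step = win * (1 - overlap)
        brute = sum(1 for k in range(dur * 4) if k * step + win <= dur + 1e-9)
        got = slide_windows(make_acq(duration_ms=float(dur)), float(win), overlap)
        assert len(got) == brute

    def test_window_longer_than_acquisition_rejected(self):
        with pytest.raises(ValueError):
            slide_windows(make_acq(duration_ms=1000.0), 2000.0)


class TestLabelWindow:
    EV = [RotationalEvent(5000.0, 5800.0, "clockwise", 4, 0)]  # 200 ms/rotation

    def test_window_inside_event_positive(self):
        assert label_window(5000.0, 500.0, self.EV) == 1

    def test_no_overlap_negative(self):
        assert label_window(0.0, 2500.0, self.EV) == 0

    def test_half_rotation_overlap_negative_by_default(self):
        # window ends 100 ms into the event = half of one rotation
        assert label_window(2600.0, 2500.0, self.EV) == 0
        assert label_window(2600.0, 2500.0, self.EV, rule="any") == 1


class TestFlips:
    def test_double_flips_are_identity(self):
        w = make_window(1)
        assert np.array_equal(flip_time(flip_time(w)).x, w.x)
        assert np.array_equal(flip_channels(flip_channels(w)).x, w.x)
        assert flip_time(flip_time(w)).augmentation == w.augmentation

    def test_labels_preserved(self):
        for y in (0, 1):
            w = make_window(y)
            assert flip_time(w).y == y and flip_channels(w).y == y

    def test_axes_actually_reversed(self):
        w = make_window(1)
        assert np.array_equal(flip_time(w).x, w.x[:, ::-1])
        assert np.array_equal(flip_channels(w).x, w.x[::-1])


class TestAugment:
    def test_five_ring_permutations_including_identity(self, layout):
        w = make_window(1)
        variants = augment(w, layout)
        assert len(variants) == 5
        assert np.array_equal(variants[0].x, w.x)
        for v in variants:
            assert v.y == 1
            # a permutation of rows: same multiset of row sums
            assert np.allclose(sorted(v.x.sum(axis=1)), sorted(w.x.sum(axis=1)))

    def test_flips_give_twenty_variants(self, layout):
        variants = augment(make_window(0), layout, flips=True)
        assert len(variants) == 20
        assert all(v.y == 0 for v in variants)

    def test_rotation_is_block_shift_of_splines(self, layout):
        w = make_window(1)
        v = augment(w, layout, unipolar_ordering(layout))[1]  # start spline 2
        assert np.array_equal(v.x[:4], w.x[4:8])


class TestRebalance:
    def test_one_to_one_sampling(self):
        ws = [make_window(1, seed=i) for i in range(10)]
        ws += [make_window(0, seed=100 + i) for i in range(50)]
        kept = rebalance(ws, seed=3)
        assert sum(w.y for w in kept) == 10
        assert len(kept) == 20

    def test_patient_without_positives_dropped(self):
        ws = [make_window(0, pid="P9", seed=i) for i in range(12)]
        ws += [make_window(1, pid="P2", seed=50), make_window(0, pid="P2", seed=51)]
        kept = rebalance(ws)
        assert {w.patient_id for w in kept} == {"P2"}

    def test_global_balance_after_rebalance(self):
        rng = np.random.default_rng(0)
        ws = []
        for p in range(5):
            n_pos = int(rng.integers(1, 8))
            ws += [make_window(1, pid=f"P{p}", seed=int(rng.integers(1e6)))
                   for _ in range(n_pos)]
            ws += [make_window(0, pid=f"P{p}", seed=int(rng.integers(1e6)))
                   for _ in range(20)]
        kept = rebalance(ws, seed=1)
        pos = sum(w.y for w in kept)
        assert pos == len(kept) - pos

    def test_deterministic_given_seed(self):
        ws = [make_window(1, seed=1)] + [make_window(0, seed=i) for i in range(9)]
        a = rebalance(ws, seed=5)
        b = rebalance(ws, seed=5)
        assert all(np.array_equal(x.x, y.x) for x, y in zip(a, b))


class TestSplitPatients:
    def windows_for(self, n_patients, per_patient=4):
        out = []
        for p in range(n_patients):
            for i in range(per_patient):
                out.append(make_window(i % 2, pid=f"P{p + 1:03d}",
                                       seed=p * 100 + i))
        return out

    @pytest.mark.parametrize("n,n_train", [(48, 43), (10, 9), (2, 1)])
    def test_chronological_fractions(self, n, n_train):
        splits = split_patients(self.windows_for(n), SplitSpec(val_fraction=0.0))
        train_pat = {w.patient_id for w in splits.train}
        test_pat = {w.patient_id for w in splits.test}
        assert len(train_pat) == n_train
        assert len(test_pat) == n - n_train
        assert max(train_pat) < min(test_pat)  # chronological order

    def test_patient_disjointness_and_val_from_train(self):
        splits = split_patients(self.windows_for(10), SplitSpec(val_fraction=0.25))
        train_pat = {w.patient_id for w in splits.train + splits.val}
        test_pat = {w.patient_id for w in splits.test}
        assert not train_pat & test_pat

    def test_validation_stratified(self):
        splits = split_patients(self.windows_for(20, 10),
                                SplitSpec(val_fraction=0.2))
        y = [w.y for w in splits.val]
        assert abs(np.mean(y) - 0.5) < 0.11

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            split_patients(self.windows_for(1))


class TestBuildDataset:
    def test_end_to_end_window_contracts(self, small_cohort):
        splits = build_dataset(small_cohort, signal_type="bipolar",
                               window_ms=2500.0, target_fs=250.0, seed=0)
        allw = splits.train + splits.val + splits.test
        assert allw, "cohort should yield windows"
        for w in allw[:20]:
            assert w.x.shape == (15, 625)  # 2500 ms at 250 Hz
            assert w.x.min() >= 0.0 and w.x.max() <= 1.0
        train_pat = {w.patient_id for w in splits.train}
        test_pat = {w.patient_id for w in splits.test}
        assert not train_pat & test_pat

    def test_lat_train_windows_stay_binary(self, small_cohort):
        splits = build_dataset(small_cohort, signal_type="lat-train",
                               window_ms=500.0, target_fs=100.0, seed=0)
        w = (splits.train + splits.test)[0]
        assert set(np.unique(w.x)) <= {0.0, 1.0}
        assert w.x.shape == (20, 50)
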