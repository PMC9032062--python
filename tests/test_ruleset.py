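"""Rule-based staircase detector: LATs, cycle estimate, ring scan, events."""

import numpy as np
import pytest

from rotordetect.catheter import ring_order
from rotordetect.containers import Acquisition
from rotordetect.ruleset import (
    CycleEstimate,
    InsufficientLats,
    LatSeries,
    RotationCandidate,
    RulesetParams,
    detect_lats,
    detect_rotational_activity,
    dominant_cycle,
    group_consecutive,
    ring_staircase_scan,
)
from rotordetect.simulate import (
    ActivationSchedule,
    SimConfig,
    render_unipolar,
    schedule_planar,
    schedule_rotor,
    render_unipolar as render,
)


@pytest.fixture(scope="module")
def short_clean():
    """Noise-free 8 s acquisition settings for detector tests."""
    return SimConfig(noise_sd=0.0, farfield_amplitude=0.0, duration_ms=8000.0,
                     seed=1)


class TestDetectLats:
    def test_flat_signal_no_lats(self):
        acq = Acquisition(np.zeros((20, 5000)), 1000.0, "unipolar")
        lats = detect_lats(acq)
        assert all(l.size == 0 for l in lats.lats_ms)

    def test_round_trip_recovers_schedule(self, short_clean):
        sched = schedule_planar(short_clean, 20.0, 0.0, 8000.0, cl=170.0,
                                rng=np.random.default_rng(4))
        cfg = short_clean
        acq = render(sched, cfg, rng=np.random.default_rng(4))
        lats = detect_lats(acq)
        for e in range(20):
            truth = sched.lat_times[e]
            interior = truth[(truth > 50) & (truth < 7800)]
            det = lats.lats_ms[e]
            err = np.abs(det[:, None] - interior[None, :]).min(axis=0)
            assert err.max() <= 2.0

    def test_refractory_greedy_acceptance(self, short_clean):
        sched = ActivationSchedule.empty(20)
        # two deflections 160 ms apart, second one steeper
        sched.add(0, 1000.0, np.array([0.7]), np.array([1000.0]), np.array([8.0]))
        sched.add(0, 1160.0, np.array([1.0]), np.array([1160.0]), np.array([8.0]))
        acq = render(sched, short_clean, rng=np.random.default_rng(0))
        both = detect_lats(acq, slope_threshold=0.1, refractory_ms=120.0)
        assert np.allclose(both.lats_ms[0], [1000.0, 1160.0], atol=1.0)
        one = detect_lats(acq, slope_threshold=0.1, refractory_ms=200.0)
        assert np.allclose(one.lats_ms[0], [1160.0], atol=1.0)  # steeper wins

    def test_non_unipolar_rejected(self):
        acq = Acquisition(np.zeros((15, 100)), 1000.0, "bipolar")
        with pytest.raises(ValueError):
            detect_lats(acq)


class TestDominantCycle:
    def test_perfectly_periodic(self):
        lats = LatSeries([np.arange(0.0, 2000.0, 167.0)] * 3, 90.0)
        assert dominant_cycle(lats).cl == pytest.approx(167.0)

    def test_median_robust_to_missed_beat(self):
        gaps = [160.0] * 9 + [400.0]
        times = np.cumsum([0.0] + gaps)
        lats = LatSeries([times], 90.0)
        assert dominant_cycle(lats).cl == pytest.approx(160.0)

    def test_three_lats_single_channel(self):
        lats = LatSeries([np.array([0.0, 170.0, 340.0])], 90.0)
        assert dominant_cycle(lats).cl == pytest.approx(170.0)

    def test_insufficient_lats_raises(self):
        lats = LatSeries([np.array([100.0])], 90.0)
        with pytest.raises(InsufficientLats):
            dominant_cycle(lats)


def periodic_ring_lats(layout, phases, cl, n_rot, t0=500.0):
    """LatSeries whose ring-0 electrodes fire at t0 + (k + phase)*cl."""
    lats = [np.empty(0)] * layout.n_electrodes
    ring = ring_order(layout, 0)
    for (s, p), phase in zip(ring.index_map, phases):
        e = layout.flat_index(s, p)
        lats[e] = t0 + (np.arange(n_rot) + phase) * cl
    return LatSeries(lats, 90.0)


class TestRingStaircaseScan:
    def test_staircase_candidate_detected(self, layout):
        lats = periodic_ring_lats(layout, [0, 0.2, 0.4, 0.6, 0.8], 160.0, 4)
        cands = ring_staircase_scan(lats, ring_order(layout, 0),
                                    CycleEstimate(160.0), layout)
        assert len(cands) == 4
        assert all(c.chirality == "counterclockwise" for c in cands)
        assert cands[0].t_end - cands[0].t_start == pytest.approx(128.0)

    def test_planar_pattern_rejected(self, layout):
        lats = periodic_ring_lats(
            layout, [0.0, 0.0625, 0.125, 0.0625, 0.0], 160.0, 4
        )  # symmetric [0, 10, 20, 10, 0] ms: non-monotone and tiny span
        cands = ring_staircase_scan(lats, ring_order(layout, 0),
                                    CycleEstimate(160.0), layout)
        assert cands == []

    def test_reversed_staircase_flips_chirality(self, layout):
        lats = periodic_ring_lats(layout, [0, 0.8, 0.6, 0.4, 0.2], 160.0, 4)
        cands = ring_staircase_scan(lats, ring_order(layout, 0),
                                    CycleEstimate(160.0), layout)
        assert cands and all(c.chirality == "clockwise" for c in cands)


class TestGroupConsecutive:
    def mk(self, starts, chir="counterclockwise"):
        return [RotationCandidate(t, t + 128.0, chir, 0) for t in starts]

    def test_three_adjacent_form_one_event(self):
        ev = group_consecutive(self.mk([0.0, 160.0, 320.0]), CycleEstimate(160.0))
        assert len(ev) == 1 and ev[0].n_rotations == 3

    def test_two_adjacent_insufficient(self):
        assert group_consecutive(self.mk([0.0, 160.0]), CycleEstimate(160.0)) == []

    def test_chirality_flip_splits_run(self):
        cands = self.mk([0.0, 160.0]) + self.mk([320.0, 480.0], "clockwise")
        assert group_consecutive(cands, CycleEstimate(160.0)) == []

    def test_large_gap_splits_run(self):
        cands = self.mk([0.0, 160.0, 320.0, 1200.0, 1360.0])
        ev = group_consecutive(cands, CycleEstimate(160.0))
        assert len(ev) == 1 and ev[0].n_rotations == 3


class TestDetectRotationalActivity:
    def _acq_with_rotor(self, cfg, chirality, seed=6):
        rng = np.random.default_rng(seed)
        bg1 = schedule_planar(cfg, 45.0, 200.0, 3500.0, cl=165.0, rng=rng)
        rot, ev = schedule_rotor(cfg, 3700.0, 4, chirality, cl=165.0, rng=rng)
        bg2 = schedule_planar(cfg, 200.0, 4600.0, 7800.0, cl=165.0, rng=rng)
        sched = bg1.merge(rot).merge(bg2)
        return render_unipolar(sched, cfg, rng=rng), ev

    @pytest.mark.parametrize("chirality", ["clockwise", "counterclockwise"])
    def test_clean_rotor_detected_with_chirality(self, short_clean, chirality):
        cfg = short_clean
        acq, truth = self._acq_with_rotor(cfg, chirality)
        events = detect_rotational_activity(acq)
        assert len(events) == 1
        ev = events[0]
        assert ev.chirality == chirality
        assert ev.overlap_ms(truth.t_start, truth.t_end) >= 0.8 * truth.duration_ms

    def test_pure_planar_yields_nothing(self, short_clean):
        rng = np.random.default_rng(8)
        sched = schedule_planar(short_clean, 110.0, 200.0, 7800.0, cl=170.0,
                                rng=rng)
        acq = render_unipolar(sched, short_clean, rng=rng)
        assert detect_rotational_activity(acq) == []

    def test_time_shift_equivariance(self, short_clean):
        acq, _ = self._acq_with_rotor(short_clean, "clockwise")
        shift = 500  # samples = ms at 1 kHz
        shifted = Acquisition(np.roll(acq.signal, shift, axis=1), acq.fs,
                              "unipolar")
        base = detect_rotational_activity(acq)
        moved = detect_rotational_activity(shifted)
        assert len(base) == len(moved) == 1
        assert moved[0].t_start - base[0].t_start == pytest.approx(shift, abs=3.0)
        assert moved[0].chirality == base[0].chirality

    def test_determinism(self, short_clean):
        acq, _ = self._acq_with_rotor(short_clean, "counterclockwise")
        assert (detect_rotational_activity(acq)
                == detect_rotational_activity(acq))

    def test_moderate_noise_keeps_event_overlap(self):
        cfg = SimConfig(noise_sd=0.05, farfield_amplitude=0.2,
                        duration_ms=8000.0, seed=3)
        rng = np.random.default_rng(13)
        bg = schedule_planar(cfg, 10.0, 200.0, 3500.0, cl=165.0, rng=rng)
        rot, truth = schedule_rotor(cfg, 3700.0, 5, "clockwise", cl=165.0, rng=rng)
        bg2 = schedule_planar(cfg, 300.0, 4800.0, 7800.0, cl=165.0, rng=rng)
        acq = render_unipolar(bg.merge(rot).merge(bg2), cfg, rng=rng)
        events = detect_rotational_activity(acq)
        assert any(
            e.chirality == "clockwise"
            and e.overlap_ms(truth.t_start, truth.t_end) >= 0.8 * truth.duration_ms
            for e in events
        )
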