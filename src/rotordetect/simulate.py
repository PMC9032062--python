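"""Synthetic unipolar electrogram simulator with ground-truth rotor events.

The simulator is a *statistical* emulator of multi-electrode atrial
fibrillation recordings, not a biophysical tissue model.  It schedules
local activation times (LATs) per electrode for four activation
patterns — planar wavefronts, focal (radial) spread, fractionated
bursts, and rotors — and renders each activation as a biphasic
deflection whose steepest negative slope falls exactly at the scheduled
LAT.  A rotor episode imprints the staircase LAT pattern on every
concentric electrode ring coherently (single core): the electrode at
ring angle theta activates at ``t0 + (k + theta/360) * CL`` during
rotation ``k``, so the per-ring LAT span is 4/5 of the cycle length for
5-electrode rings, comfortably above the 50%-of-cycle detection rule.

Cycle lengths are drawn per acquisition from a truncated normal with
mean 166.8 ms and SD 36.1 ms (floor 100 ms), matching the rotor cycle
duration statistics of persistent-AF cohorts mapped with a 20-pole star
catheter.  All randomness flows from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catheter import CatheterLayout, build_layout, electrode_positions
from .containers import Acquisition, RotationalEvent

__all__ = [
    "SimConfig",
    "ActivationSchedule",
    "schedule_planar",
    "schedule_focal",
    "schedule_fractionated",
    "schedule_rotor",
    "render_unipolar",
    "simulate_acquisition",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Simulation parameters (times in ms, amplitudes in mV).

    Defaults reflect the study conditions the pipeline assumes: 30 s
    acquisitions at 1 kHz from a 5-spline, 20-electrode catheter, rotor
    cycle lengths 166.8 +/- 36.1 ms.
    """

    duration_ms: float = 30_000.0
    fs: float = 1000.0
    cycle_length_mean: float = 166.8
    cycle_length_sd: float = 36.1
    cycle_length_floor: float = 100.0
    rotor_fraction: float = 0.5
    rotations_min: int = 3
    rotations_max: int = 8
    max_episodes: int = 2
    noise_sd: float = 0.05
    farfield_amplitude: float = 0.2
    farfield_width_ms: float = 30.0
    mains_amplitude: float = 0.0
    amplitude_mv: float = 1.0
    amplitude_jitter: float = 0.2
    deflection_width_ms: float = 8.0
    conduction_velocity: float = 0.5  # mm/ms
    refractory_floor_ms: float = 90.0
    segment_gap_ms: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        if not (0.0 <= self.rotor_fraction <= 1.0):
            raise ValueError("rotor_fraction must be in [0, 1]")
        if self.cycle_length_mean <= 0:
            raise ValueError("cycle_length_mean must be positive")
        if self.rotations_min < 1 or self.rotations_max < self.rotations_min:
            raise ValueError("invalid rotations range")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.fs / 1000.0))


@dataclass
class ActivationSchedule:
    """Per-electrode activation instants plus renderable deflections.

    ``lat_times`` holds the physiologic activations (strictly increasing,
    spaced by at least the refractory floor).  ``deflections`` holds what
    the renderer draws: one biphasic wave per LAT for regular patterns,
    a low-amplitude burst per LAT for fractionated segments.
    """

    n_electrodes: int
    lat_times: list[np.ndarray] = field(default_factory=list)
    d_times: list[np.ndarray] = field(default_factory=list)
    d_amps: list[np.ndarray] = field(default_factory=list)
    d_widths: list[np.ndarray] = field(default_factory=list)
    pattern_segments: list[tuple[float, float, str, dict]] = field(default_factory=list)

    @classmethod
    def empty(cls, n_electrodes: int) -> "ActivationSchedule":
        z = [np.empty(0) for _ in range(n_electrodes)]
        return cls(
            n_electrodes,
            [a.copy() for a in z],
            [a.copy() for a in z],
            [a.copy() for a in z],
            [a.copy() for a in z],
        )

    def add(
        self,
        electrode: int,
        lat_ms: float,
        amps: np.ndarray,
        times: np.ndarray,
        widths: np.ndarray,
    ) -> None:
        self.lat_times[electrode] = np.append(self.lat_times[electrode], lat_ms)
        self.d_times[electrode] = np.append(self.d_times[electrode], times)
        self.d_amps[electrode] = np.append(self.d_amps[electrode], amps)
        self.d_widths[electrode] = np.append(self.d_widths[electrode], widths)

    def merge(self, other: "ActivationSchedule") -> "ActivationSchedule":
        if other.n_electrodes != self.n_electrodes:
            raise ValueError("electrode count mismatch")
        out = ActivationSchedule.empty(self.n_electrodes)
        for e in range(self.n_electrodes):
            out.lat_times[e] = np.sort(
                np.concatenate([self.lat_times[e], other.lat_times[e]])
            )
            order = np.argsort(
                np.concatenate([self.d_times[e], other.d_times[e]]), kind="stable"
            )
            for name in ("d_times", "d_amps", "d_widths"):
                cat = np.concatenate([getattr(self, name)[e], getattr(other, name)[e]])
                getattr(out, name)[e] = cat[order]
        out.pattern_segments = sorted(
            self.pattern_segments + other.pattern_segments, key=lambda s: s[0]
        )
        return out

    def validate(self, refractory_floor_ms: float) -> None:
        """Check strict increase and refractory spacing of activations."""
        for e in range(self.n_electrodes):
            gaps = np.diff(self.lat_times[e])
            if gaps.size and gaps.min() < refractory_floor_ms - 1e-9:
                raise ValueError(
                    f"electrode {e}: activation gap {gaps.min():.1f} ms below "
                    f"refractory floor {refractory_floor_ms} ms"
                )


def _jitter_amp(config: SimConfig, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    j = config.amplitude_jitter
    return config.amplitude_mv * (1.0 + rng.uniform(-j, j, size=n))


def _cycle_anchors(t0: float, t1: float, cl: float) -> np.ndarray:
    """Cycle start times in [t0, t1) spaced by cl, leaving room for one cycle."""
    if t1 <= t0:
        return np.empty(0)
    n = int(math.floor((t1 - t0) / cl))
    return t0 + cl * np.arange(max(n, 0))


def schedule_planar(
    config: SimConfig,
    direction_deg: float,
    t0: float,
    t1: float,
    *,
    layout: CatheterLayout | None = None,
    cl: float | None = None,
    rng: np.random.Generator | None = None,
) -> ActivationSchedule:
    """Planar wavefront: LATs increase along the propagation direction.

    Each cycle, the wavefront crosses the catheter at the configured
    conduction velocity; the per-ring LAT span (at most the catheter
    diameter over the velocity) stays well below half a cycle length.
    """
    if not (0 <= t0 < t1 <= config.duration_ms):
        raise ValueError("segment outside acquisition")
    layout = layout or build_layout()
    rng = rng or np.random.default_rng(config.seed)
    cl = cl or config.cycle_length_mean
    xy = electrode_positions(layout)
    u = np.array([np.cos(np.deg2rad(direction_deg)), np.sin(np.deg2rad(direction_deg))])
    proj = xy @ u
    offsets = (proj - proj.min()) / config.conduction_velocity
    sched = ActivationSchedule.empty(layout.n_electrodes)
    w = config.deflection_width_ms
    for tc in _cycle_anchors(t0, t1, cl):
        for e in range(layout.n_electrodes):
            lat = tc + offsets[e]
            amp = _jitter_amp(config, rng)
            sched.add(e, lat, amp, np.array([lat]), np.array([w]))
    sched.pattern_segments.append((t0, t1, "planar", {"direction_deg": direction_deg}))
    return sched


def schedule_focal(
    config: SimConfig,
    origin_xy: tuple[float, float],
    t0: float,
    t1: float,
    *,
    layout: CatheterLayout | None = None,
    cl: float | None = None,
    rng: np.random.Generator | None = None,
) -> ActivationSchedule:
    """Focal source: activation spreads radially from an origin point."""
    if not (0 <= t0 < t1 <= config.duration_ms):
        raise ValueError("segment outside acquisition")
    layout = layout or build_layout()
    rng = rng or np.random.default_rng(config.seed)
    cl = cl or config.cycle_length_mean
    xy = electrode_positions(layout)
    dist = np.linalg.norm(xy - np.asarray(origin_xy), axis=1)
    offsets = dist / config.conduction_velocity
    sched = ActivationSchedule.empty(layout.n_electrodes)
    w = config.deflection_width_ms
    for tc in _cycle_anchors(t0, t1, cl):
        for e in range(layout.n_electrodes):
            lat = tc + offsets[e]
            amp = _jitter_amp(config, rng)
            sched.add(e, lat, amp, np.array([lat]), np.array([w]))
    sched.pattern_segments.append((t0, t1, "focal", {"origin": tuple(origin_xy)}))
    return sched


def schedule_fractionated(
    config: SimConfig,
    t0: float,
    t1: float,
    *,
    layout: CatheterLayout | None = None,
    cl: float | None = None,
    rng: np.random.Generator | None = None,
) -> ActivationSchedule:
    """Fractionated activity: bursts of 3-5 small deflections within 40 ms.

    Fractionation is the classic false-positive surrogate for rotational
    activity; it exercises detector and classifier specificity.  Each
    electrode keeps one physiologic LAT per cycle (burst onset), but the
    renderer draws a multi-deflection complex around it.
    """
    if not (0 <= t0 < t1 <= config.duration_ms):
        raise ValueError("segment outside acquisition")
    layout = layout or build_layout()
    rng = rng or np.random.default_rng(config.seed)
    cl = cl or config.cycle_length_mean
    sched = ActivationSchedule.empty(layout.n_electrodes)
    for tc in _cycle_anchors(t0, t1, cl):
        for e in range(layout.n_electrodes):
            lat = tc + rng.uniform(0.0, 15.0)
            n_defl = int(rng.integers(3, 6))
            times = lat + np.sort(rng.uniform(0.0, 40.0, size=n_defl))
            amps = config.amplitude_mv * rng.uniform(0.2, 0.5, size=n_defl)
            widths = rng.uniform(3.0, 5.0, size=n_defl)
            sched.add(e, lat, amps, times, widths)
    sched.pattern_segments.append((t0, t1, "fractionated", {}))
    return sched


def schedule_rotor(
    config: SimConfig,
    t0: float,
    n_rotations: int,
    chirality: str,
    *,
    layout: CatheterLayout | None = None,
    cl: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ActivationSchedule, RotationalEvent]:
    """Rotor episode: staircase LATs spanning the cycle on every ring.

    During rotation ``k`` the electrode on the spline at angle theta
    activates at ``t0 + (k + phase) * CL`` with ``phase = theta/360`` for
    a counterclockwise rotor and ``phase = (360 - theta)/360 mod 1`` for
    a clockwise one.  All rings share the same core, hence identical
    per-spline phases.
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    if chirality not in ("clockwise", "counterclockwise"):
        raise ValueError(f"unknown chirality {chirality!r}")
    layout = layout or build_layout()
    rng = rng or np.random.default_rng(config.seed)
    cl = cl or config.cycle_length_mean
    t_end = t0 + n_rotations * cl
    if t0 < 0 or t_end > config.duration_ms:
        raise ValueError("episode does not fit in the acquisition")
    sched = ActivationSchedule.empty(layout.n_electrodes)
    w = config.deflection_width_ms
    for s in range(layout.n_splines):
        theta = layout.spline_angles[s] % 360.0
        if chirality == "counterclockwise":
            phase = theta / 360.0
        else:
            phase = ((360.0 - theta) % 360.0) / 360.0
        for p in range(layout.electrodes_per_spline):
            e = layout.flat_index(s, p)
            for k in range(n_rotations):
                lat = t0 + (k + phase) * cl
                amp = _jitter_amp(config, rng)
                sched.add(e, lat, amp, np.array([lat]), np.array([w]))
    sched.pattern_segments.append(
        (t0, t_end, "rotor", {"chirality": chirality, "cl": cl})
    )
    event = RotationalEvent(t0, t_end, chirality, n_rotations, ring_index=0)
    return sched, event


def _add_deflection(
    row: np.ndarray, fs: float, t_ms: float, amp: float, width_ms: float
) -> None:
    """Add one biphasic wave in place; steepest negative slope at t_ms.

    Template: s(u) = -amp * e^{1/2} * (u/sigma) * exp(-u^2 / (2 sigma^2))
    with sigma = width/4 — positive then negative deflection with extrema
    +/- amp and derivative minimum exactly at u = 0.
    """
    sigma = width_ms / 4.0
    half = 5.0 * sigma
    i0 = max(0, int(math.floor((t_ms - half) * fs / 1000.0)))
    i1 = min(row.shape[0], int(math.ceil((t_ms + half) * fs / 1000.0)) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) * (1000.0 / fs)
    u = t - t_ms
    row[i0:i1] += -amp * math.sqrt(math.e) * (u / sigma) * np.exp(
        -(u**2) / (2.0 * sigma**2)
    )


def render_unipolar(
    schedule: ActivationSchedule,
    config: SimConfig,
    *,
    layout: CatheterLayout | None = None,
    rng: np.random.Generator | None = None,
    patient_id: str = "",
    acq_index: int = 0,
) -> Acquisition:
    """Render a schedule into a 20 x samples unipolar voltage matrix.

    Adds (in order): per-deflection biphasic waves, an optional periodic
    far-field wave identical on all channels (period drawn in 700-900 ms,
    so bipolar derivation cancels it exactly), optional 50 Hz mains, and
    white noise of SD ``noise_sd``.  Bit-reproducible given the rng.
    """
    layout = layout or build_layout()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_samples
    x = np.zeros((schedule.n_electrodes, n))
    for e in range(schedule.n_electrodes):
        for t_ms, amp, w in zip(
            schedule.d_times[e], schedule.d_amps[e], schedule.d_widths[e]
        ):
            _add_deflection(x[e], config.fs, t_ms, amp, w)
    if config.farfield_amplitude > 0:
        period = rng.uniform(700.0, 900.0)
        t_ff = rng.uniform(0.0, period)
        ff = np.zeros(n)
        while t_ff < config.duration_ms:
            _add_deflection(
                ff, config.fs, t_ff, config.farfield_amplitude, config.farfield_width_ms
            )
            t_ff += period
        x += ff  # common mode on every channel
    if config.mains_amplitude > 0:
        t = np.arange(n) / config.fs
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += config.mains_amplitude * np.sin(2.0 * np.pi * 50.0 * t + phase)
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=x.shape)
    return Acquisition(
        x,
        config.fs,
        "unipolar",
        patient_id=patient_id,
        acq_index=acq_index,
        meta={"synthetic": True, "segments": list(schedule.pattern_segments)},
    )


def _truncnorm_cl(config: SimConfig, rng: np.random.Generator) -> float:
    """Cycle length from a truncated normal (resampling below the floor)."""
    for _ in range(1000):
        cl = rng.normal(config.cycle_length_mean, config.cycle_length_sd)
        if cl >= config.cycle_length_floor:
            return float(cl)
    return float(config.cycle_length_floor)


def _background_segment(
    config: SimConfig,
    layout: CatheterLayout,
    t0: float,
    t1: float,
    cl: float,
    rng: np.random.Generator,
) -> ActivationSchedule:
    kind = rng.choice(["planar", "focal", "fractionated"], p=[0.5, 0.25, 0.25])
    if kind == "planar":
        return schedule_planar(
            config, rng.uniform(0, 360), t0, t1, layout=layout, cl=cl, rng=rng
        )
    if kind == "focal":
        r = rng.uniform(0.0, layout.electrode_radii[-1])
        th = rng.uniform(0.0, 2 * np.pi)
        origin = (r * np.cos(th), r * np.sin(th))
        return schedule_focal(config, origin, t0, t1, layout=layout, cl=cl, rng=rng)
    return schedule_fractionated(config, t0, t1, layout=layout, cl=cl, rng=rng)


def simulate_acquisition(
    config: SimConfig,
    rng: np.random.Generator,
    *,
    layout: CatheterLayout | None = None,
    patient_id: str = "",
    acq_index: int = 0,
    with_rotor: bool | None = None,
) -> tuple[Acquisition, list[RotationalEvent]]:
    """One 30 s acquisition: background patterns, optional rotor episodes.

    ``with_rotor=None`` draws rotor presence with probability
    ``config.rotor_fraction``; booleans force it either way.
    """
    layout = layout or build_layout()
    cl = _truncnorm_cl(config, rng)
    gap = config.segment_gap_ms
    t_lo, t_hi = gap, config.duration_ms - gap
    if with_rotor is None:
        with_rotor = bool(rng.random() < config.rotor_fraction)

    events: list[RotationalEvent] = []
    episodes: list[tuple[float, float, int, str]] = []
    if with_rotor:
        n_epi = int(rng.integers(1, config.max_episodes + 1))
        for _ in range(n_epi):
            n_rot = int(rng.integers(config.rotations_min, config.rotations_max + 1))
            dur = n_rot * cl
            for _try in range(50):
                t0 = rng.uniform(t_lo, t_hi - dur)
                ok = all(
                    t0 + dur + gap <= e0 or t0 >= e0 + ed + gap
                    for e0, ed, _, _ in episodes
                )
                if ok:
                    chir = "counterclockwise" if rng.random() < 0.5 else "clockwise"
                    episodes.append((t0, dur, n_rot, chir))
                    break
    episodes.sort(key=lambda e: e[0])

    sched = ActivationSchedule.empty(layout.n_electrodes)
    cursor = t_lo
    for t0, dur, n_rot, chir in episodes:
        if t0 - gap > cursor + cl:
            sched = sched.merge(
                _background_segment(config, layout, cursor, t0 - gap, cl, rng)
            )
        rot_sched, event = schedule_rotor(
            config, t0, n_rot, chir, layout=layout, cl=cl, rng=rng
        )
        sched = sched.merge(rot_sched)
        events.append(event)
        cursor = t0 + dur + gap
    if t_hi > cursor + cl:
        sched = sched.merge(_background_segment(config, layout, cursor, t_hi, cl, rng))

    sched.validate(min(config.refractory_floor_ms, 0.95 * cl))
    acq = render_unipolar(
        sched,
        config,
        layout=layout,
        rng=rng,
        patient_id=patient_id,
        acq_index=acq_index,
    )
    acq.meta["cl_ms"] = cl
    acq.meta["schedule"] = sched
    return acq, events


def simulate_cohort(
    config: SimConfig,
    n_patients: int,
    acquisitions_per_patient: int,
    *,
    layout: CatheterLayout | None = None,
) -> list[tuple[Acquisition, list[RotationalEvent]]]:
    """Simulate a cohort of patients with chronological acquisition indices.

    Patients are numbered in enrollment order (P001, P002, ...) so the
    chronological train/test patient split is exercised downstream.
    Identical configs (including seed) give identical cohorts.
    """
    if n_patients < 1 or acquisitions_per_patient < 1:
        raise ValueError("counts must be >= 1")
    layout = layout or build_layout()
    master = np.random.default_rng(config.seed)
    out = []
    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        for a in range(acquisitions_per_patient):
            rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            out.append(
                simulate_acquisition(
                    config, rng, layout=layout, patient_id=pid, acq_index=a
                )
            )
    return out
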