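"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["Acquisition", "RotationalEvent", "LabeledWindow"]


@dataclass
class Acquisition:
    """A multi-channel electrogram recording.

    Attributes
    ----------
    signal : ndarray, shape (channels, samples)
        Voltages in mV (or 0/1 for LAT trains).
    fs : float
        Sampling frequency in Hz.
    kind : str
        "unipolar", "bipolar" or "lat-train".
    patient_id : str
    acq_index : int
        Chronological index of the acquisition within the patient.
    meta : dict
        Provenance (filter bands, resampling, normalization percentiles...).
    """

    signal: np.ndarray
    fs: float
    kind: str
    patient_id: str = ""
    acq_index: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.kind not in ("unipolar", "bipolar", "lat-train"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def with_signal(self, signal: np.ndarray, **changes: Any) -> "Acquisition":
        """Copy with a new signal matrix (and optional field changes)."""
        out = replace(self, signal=signal)
        for k, v in changes.items():
            setattr(out, k, v)
        return out


@dataclass(frozen=True)
class RotationalEvent:
    """A rotational-activity (rotor) episode on one electrode ring.

    Chirality is defined relative to the counterclockwise ring order:
    "counterclockwise" means local activation times increase along the
    ring order (ascending staircase), "clockwise" the reverse.
    """

    t_start: float  # ms
    t_end: float  # ms
    chirality: str  # "clockwise" | "counterclockwise"
    n_rotations: int
    ring_index: int

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")
        if self.n_rotations < 1:
            raise ValueError("n_rotations must be >= 1")
        if self.chirality not in ("clockwise", "counterclockwise"):
            raise ValueError(f"unknown chirality {self.chirality!r}")

    @property
    def duration_ms(self) -> float:
        return self.t_end - self.t_start

    def overlap_ms(self, t0: float, t1: float) -> float:
        """Length of overlap with the interval [t0, t1] in ms."""
        return max(0.0, min(self.t_end, t1) - max(self.t_start, t0))


@dataclass
class LabeledWindow:
    """A fixed-length normalized signal window with a binary rotor label."""

    x: np.ndarray  # (channels, samples), values in [0, 1]
    y: int  # 1 = rotor present
    patient_id: str = ""
    acq_index: int = 0
    t_offset_ms: float = 0.0
    augmentation: str = "orig"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        if self.x.ndim != 2:
            raise ValueError("window must be 2-D (channels x samples)")
        if self.y not in (0, 1):
            raise ValueError("label must be binary")
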