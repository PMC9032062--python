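"""Signal conditioning: filtering, bipolar derivation, resampling, scaling.

Conventions follow clinical electrogram practice: bipolar channels are
band-passed at 30-240 Hz, unipolar channels at 0.1-100 Hz, mains removed
with a 50 Hz notch, and network inputs down-sampled from the 1 kHz
acquisition rate.  Filters are 4th-order Butterworth applied
forward-backward (zero phase), so local-activation timing — which the
rule detector reads off the filtered unipolar signal — is not shifted.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .catheter import CatheterLayout, bipolar_pairs, build_layout
from .containers import Acquisition

__all__ = [
    "bandpass",
    "notch50",
    "derive_bipolar",
    "resample",
    "percentile_normalize",
    "lat_train",
    "DEFAULT_BANDS",
]

#: Default band edges (Hz) by channel kind.
DEFAULT_BANDS = {"bipolar": (30.0, 240.0), "unipolar": (0.1, 100.0)}


def bandpass(
    acq: Acquisition, low: float | None = None, high: float | None = None
) -> Acquisition:
    """Zero-phase 4th-order Butterworth band-pass.

    Band edges default by channel kind: 30-240 Hz for bipolar, 0.1-100 Hz
    for unipolar electrograms.
    """
    if low is None or high is None:
        try:
            d_low, d_high = DEFAULT_BANDS[acq.kind]
        except KeyError:
            raise ValueError(f"no default band for kind {acq.kind!r}") from None
        low = d_low if low is None else low
        high = d_high if high is None else high
    nyq = acq.fs / 2.0
    if not (0 <= low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, {nyq}) Hz")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=acq.fs, output="sos")
    y = sps.sosfiltfilt(sos, acq.signal, axis=1)
    out = acq.with_signal(y)
    out.meta = {**acq.meta, "band_hz": (low, high)}
    return out


def notch50(acq: Acquisition, q: float = 30.0) -> Acquisition:
    """Zero-phase 50 Hz notch (IIR, quality factor ``q``)."""
    if acq.fs <= 100.0:
        raise ValueError("sampling rate must exceed 100 Hz for a 50 Hz notch")
    b, a = sps.iirnotch(50.0, q, fs=acq.fs)
    y = sps.filtfilt(b, a, acq.signal, axis=1)
    out = acq.with_signal(y)
    out.meta = {**acq.meta, "notch_hz": 50.0}
    return out


def derive_bipolar(acq: Acquisition, layout: CatheterLayout | None = None) -> Acquisition:
    """Derive bipolar channels as proximal-minus-distal within-spline pairs.

    Common-mode components (e.g. ventricular far field identical on both
    electrodes of a pair) cancel exactly.  20 unipolar channels yield 15
    bipoles for the default layout.
    """
    if acq.kind != "unipolar":
        raise ValueError("bipolar derivation requires a unipolar acquisition")
    layout = layout or build_layout()
    if acq.n_channels != layout.n_electrodes:
        raise ValueError(
            f"expected {layout.n_electrodes} unipolar channels, got {acq.n_channels}"
        )
    pairs = bipolar_pairs(layout)
    y = np.stack([acq.signal[i] - acq.signal[j] for i, j in pairs])
    out = acq.with_signal(y, kind="bipolar")
    out.meta = {**acq.meta, "bipolar_pairs": pairs}
    return out


def resample(acq: Acquisition, target_fs: float) -> Acquisition:
    """Down-sample to ``target_fs`` with anti-alias filtering.

    The output has exactly ``floor(n * target_fs / fs)`` samples.  Binary
    LAT trains are re-binned (max-pooled over the decimation groups)
    instead of filtered, preserving their 0/1 nature.
    """
    if target_fs > acq.fs:
        raise ValueError("upsampling not supported")
    if target_fs == acq.fs:
        return acq.with_signal(acq.signal.copy())
    n_out = int(np.floor(acq.n_samples * target_fs / acq.fs))
    if acq.kind == "lat-train":
        y = np.zeros((acq.n_channels, n_out), dtype=acq.signal.dtype)
        idx = np.floor(np.arange(acq.n_samples) * target_fs / acq.fs).astype(int)
        keep = idx < n_out
        np.maximum.at(y, (slice(None), idx[keep]), acq.signal[:, keep])
    else:
        from fractions import Fraction

        frac = Fraction(target_fs / acq.fs).limit_denominator(1000)
        y = sps.resample_poly(acq.signal, frac.numerator, frac.denominator, axis=1)
        y = y[:, :n_out]
    out = acq.with_signal(y, fs=float(target_fs))
    out.meta = {**acq.meta, "resampled_from_hz": acq.fs}
    return out


def percentile_normalize(window: np.ndarray) -> np.ndarray:
    """Map a window affinely to [0, 1] using its 2nd/98th percentiles.

    Percentiles are computed jointly over all entries; values outside the
    percentile range are clipped, which suppresses isolated noise peaks.
    A degenerate window (p98 == p2) maps uniformly to 0.5.
    """
    w = np.asarray(window)
    if w.size == 0:
        raise ValueError("empty window")
    p2, p98 = np.percentile(w, [2.0, 98.0])
    if p98 <= p2:
        return np.full_like(w, 0.5, dtype=float)
    return np.clip((w - p2) / (p98 - p2), 0.0, 1.0)


def lat_train(acq: Acquisition, lats_ms: list[np.ndarray]) -> Acquisition:
    """Binary LAT-train representation: 1 at activation samples, else 0.

    ``lats_ms`` gives per-channel activation instants in ms (as produced
    by the rule detector on the unipolar signal).
    """
    if acq.kind != "unipolar":
        raise ValueError("LAT trains are defined for unipolar acquisitions")
    if len(lats_ms) != acq.n_channels:
        raise ValueError("one LAT sequence per channel required")
    y = np.zeros_like(acq.signal, dtype=np.float64)
    for c, lats in enumerate(lats_ms):
        lats = np.asarray(lats, dtype=float)
        if lats.size == 0:
            continue
        if lats.min() < 0 or lats.max() >= acq.duration_ms:
            raise ValueError("LAT outside acquisition duration")
        idx = np.round(lats * acq.fs / 1000.0).astype(int)
        idx = np.clip(idx, 0, acq.n_samples - 1)
        y[c, idx] = 1.0
    out = acq.with_signal(y, kind="lat-train")
    out.meta = {**acq.meta, "lat_train": True}
    return out
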