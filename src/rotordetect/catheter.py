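"""Star-catheter (PentaRay-style) topology and channel orderings.

A 5-spline, 4-electrodes-per-spline star catheter records 20 unipolar
electrograms; adjacent within-spline electrode pairs yield 15 bipolar
electrograms.  Electrodes at the same within-spline position form
concentric *rings*; the staircase rule detector and the ring-permutation
augmentation both operate on ring orderings, which this module defines
once for every consumer.

Indexing is 0-based internally; CLI output and file headers use 1-based
spline/electrode labels (clinical convention).  The flat electrode index
of (spline s, position p) is ``s * electrodes_per_spline + p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CatheterLayout",
    "ChannelOrdering",
    "build_layout",
    "ring_order",
    "bipolar_pairs",
    "spline_rotation",
    "unipolar_ordering",
    "electrode_positions",
]

#: Default radial distance (mm) of within-spline electrode positions.
#: Only the relative order matters for ring logic; absolute values are
#: consumed by the simulator's conduction geometry.
DEFAULT_RADII_MM = (2.0, 5.0, 8.0, 11.0)


@dataclass(frozen=True)
class CatheterLayout:
    """Geometry of a star catheter.

    Attributes
    ----------
    n_splines : int
        Number of radial splines (5 for the reference catheter).
    electrodes_per_spline : int
        Electrodes on each spline, innermost first (4 for the reference).
    spline_angles : tuple of float
        Angular position of each spline in degrees, strictly increasing,
        spanning less than a full turn.
    electrode_radii : tuple of float
        Radial distance of each within-spline position in mm, strictly
        increasing outward.
    """

    n_splines: int
    electrodes_per_spline: int
    spline_angles: tuple[float, ...]
    electrode_radii: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_splines < 1 or self.electrodes_per_spline < 1:
            raise ValueError("n_splines and electrodes_per_spline must be >= 1")
        if len(self.spline_angles) != self.n_splines:
            raise ValueError("one angle per spline required")
        if len(self.electrode_radii) != self.electrodes_per_spline:
            raise ValueError("one radius per within-spline position required")
        a = np.asarray(self.spline_angles, dtype=float)
        if self.n_splines > 1 and not np.all(np.diff(a) > 0):
            raise ValueError("spline_angles must be strictly increasing")
        if a[-1] - a[0] >= 360.0:
            raise ValueError("spline_angles must span less than 360 degrees")
        r = np.asarray(self.electrode_radii, dtype=float)
        if self.electrodes_per_spline > 1 and not np.all(np.diff(r) > 0):
            raise ValueError("electrode_radii must be strictly increasing")

    @property
    def n_electrodes(self) -> int:
        return self.n_splines * self.electrodes_per_spline

    @property
    def n_bipoles(self) -> int:
        return self.n_splines * (self.electrodes_per_spline - 1)

    def flat_index(self, spline: int, position: int) -> int:
        """Flat electrode index of (spline, within-spline position)."""
        if not (0 <= spline < self.n_splines):
            raise ValueError(f"spline {spline} out of range")
        if not (0 <= position < self.electrodes_per_spline):
            raise ValueError(f"position {position} out of range")
        return spline * self.electrodes_per_spline + position


@dataclass(frozen=True)
class ChannelOrdering:
    """An ordered enumeration of electrodes (or bipoles).

    ``index_map`` is a sequence of (spline, position) pairs; for bipolar
    orderings ``position`` is the proximal position of the pair.  The map
    must not repeat entries.
    """

    kind: str  # "unipolar-by-spline" | "ring-order" | "bipolar-by-spline"
    index_map: tuple[tuple[int, int], ...]
    n_splines: int = field(default=5)

    def __post_init__(self) -> None:
        if len(set(self.index_map)) != len(self.index_map):
            raise ValueError("index_map must not repeat channels")

    def __len__(self) -> int:
        return len(self.index_map)


def build_layout(
    n_splines: int = 5,
    electrodes_per_spline: int = 4,
    *,
    radii_mm: tuple[float, ...] | None = None,
) -> CatheterLayout:
    """Build a star-catheter layout with evenly spaced spline angles.

    The default call ``build_layout(5, 4)`` reproduces the 20-electrode
    reference catheter.
    """
    if n_splines < 1 or electrodes_per_spline < 1:
        raise ValueError("counts must be positive")
    angles = tuple(360.0 * i / n_splines for i in range(n_splines))
    if radii_mm is None:
        if electrodes_per_spline <= len(DEFAULT_RADII_MM):
            radii_mm = DEFAULT_RADII_MM[:electrodes_per_spline]
        else:
            radii_mm = tuple(2.0 + 3.0 * i for i in range(electrodes_per_spline))
    return CatheterLayout(n_splines, electrodes_per_spline, angles, tuple(radii_mm))


def unipolar_ordering(layout: CatheterLayout) -> ChannelOrdering:
    """Canonical spline-major unipolar channel ordering."""
    idx = tuple(
        (s, p)
        for s in range(layout.n_splines)
        for p in range(layout.electrodes_per_spline)
    )
    return ChannelOrdering("unipolar-by-spline", idx, layout.n_splines)


def bipolar_ordering(layout: CatheterLayout) -> ChannelOrdering:
    """Spline-major bipolar ordering; entry (s, p) pairs positions p, p+1."""
    if layout.electrodes_per_spline < 2:
        raise ValueError("bipolar ordering needs >= 2 electrodes per spline")
    idx = tuple(
        (s, p)
        for s in range(layout.n_splines)
        for p in range(layout.electrodes_per_spline - 1)
    )
    return ChannelOrdering("bipolar-by-spline", idx, layout.n_splines)


def ring_order(layout: CatheterLayout, ring_index: int) -> ChannelOrdering:
    """Electrodes of one concentric ring, counterclockwise by spline angle.

    Ring ``ring_index`` collects the electrode at within-spline position
    ``ring_index`` on every spline.  Chirality labels elsewhere are defined
    relative to this counterclockwise order.
    """
    if not (0 <= ring_index < layout.electrodes_per_spline):
        raise ValueError(
            f"ring_index {ring_index} out of range "
            f"[0, {layout.electrodes_per_spline})"
        )
    order = np.argsort(layout.spline_angles, kind="stable")
    idx = tuple((int(s), ring_index) for s in order)
    return ChannelOrdering("ring-order", idx, layout.n_splines)


def bipolar_pairs(layout: CatheterLayout) -> list[tuple[int, int]]:
    """Adjacent within-spline electrode pairs as flat indices.

    Returns ``n_splines * (electrodes_per_spline - 1)`` (proximal, distal)
    pairs; 15 for the reference catheter.
    """
    if layout.electrodes_per_spline < 2:
        raise ValueError("bipolar pairs need >= 2 electrodes per spline")
    pairs = []
    for s in range(layout.n_splines):
        for p in range(layout.electrodes_per_spline - 1):
            pairs.append((layout.flat_index(s, p), layout.flat_index(s, p + 1)))
    return pairs


def spline_rotation(ordering: ChannelOrdering, start_spline: int) -> ChannelOrdering:
    """Cyclically relabel splines so enumeration begins at ``start_spline``.

    ``start_spline`` is 1-based (clinical convention): 1 is the identity,
    and applying the rotation ``n_splines`` times with any fixed start
    returns to the original ordering.  The ring-permutation augmentation
    uses the 5 rotations start_spline = 1..5.
    """
    n = ordering.n_splines
    if not (1 <= start_spline <= n):
        raise ValueError(f"start_spline {start_spline} out of range [1, {n}]")
    shift = start_spline - 1
    idx = tuple(((s + shift) % n, p) for s, p in ordering.index_map)
    return ChannelOrdering(ordering.kind, idx, n)


def electrode_positions(layout: CatheterLayout) -> np.ndarray:
    """(n_electrodes, 2) Cartesian xy coordinates in mm, spline-major order."""
    xy = np.zeros((layout.n_electrodes, 2))
    for s in range(layout.n_splines):
        theta = np.deg2rad(layout.spline_angles[s])
        for p in range(layout.electrodes_per_spline):
            r = layout.electrode_radii[p]
            xy[layout.flat_index(s, p)] = (r * np.cos(theta), r * np.sin(theta))
    return xy
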