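"""Localized, linearised 3D Ripley's L statistic with toroidal edge correction.

For each localization j the statistic counts neighbours within a sphere of
radius r, normalises by the overall density n/V and linearises by the cube
root, so that under complete spatial randomness (CSR) its expected scale is
r itself:

    L3D(r)_j = ( 3 V c_j / (4 (n - 1) pi) )^(1/3),
    c_j = #{ i != j : d_torus(i, j) < r }.

Edge effects are removed by computing distances on the 3-torus (each axis
difference wrapped as min(|d|, L - |d|)), which makes the CSR neighbour
count exactly Binomial(n - 1, p) with p = (4 pi r^3 / 3) / V — the basis of
the analytic eligibility threshold below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .locio import ROI, LocalizationTable


@dataclass(frozen=True)
class LocalLValues:
    """Per-point L values (nm) computed at a single radius r (nm)."""

    L: np.ndarray       # (n,) float, >= 0
    counts: np.ndarray  # (n,) int, neighbours strictly within r
    r: float


def toroidal_distance(p, q, roi: ROI) -> float:
    """Euclidean distance on the 3-torus defined by the ROI box."""
    d = np.abs(np.asarray(p, float) - np.asarray(q, float))
    d = np.minimum(d, roi.lengths - d)
    return float(np.sqrt((d * d).sum()))


def _check_radius(r: float, roi: ROI) -> None:
    if not (0 < r < min(roi.Lx, roi.Ly, roi.Lz) / 2):
        raise ValueError(
            f"radius r={r} must lie in (0, min(L)/2) for the toroidal wrap to be valid"
        )


def neighbour_counts(xyz: np.ndarray, roi: ROI, r: float) -> np.ndarray:
    """Number of other points strictly within toroidal distance r, per point.

    Uses a periodic KD-tree; pairs at exactly distance r (measure zero for
    continuous data) are excluded to honour the strict inequality.
    """
    n = len(xyz)
    counts = np.zeros(n, dtype=np.int64)
    if n < 2:
        return counts
    tree = cKDTree(np.mod(xyz, roi.lengths), boxsize=roi.lengths)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs):
        d = np.abs(xyz[pairs[:, 0]] - xyz[pairs[:, 1]])
        d = np.minimum(d, roi.lengths - d)
        strict = (d * d).sum(axis=1) < r * r
        pairs = pairs[strict]
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    return counts


def neighbour_counts_bruteforce(xyz: np.ndarray, roi: ROI, r: float) -> np.ndarray:
    """O(n^2) reference implementation of :func:`neighbour_counts`."""
    n = len(xyz)
    counts = np.zeros(n, dtype=np.int64)
    for j in range(n):
        d = np.abs(xyz - xyz[j])
        d = np.minimum(d, roi.lengths - d)
        within = (d * d).sum(axis=1) < r * r
        counts[j] = int(within.sum()) - 1  # remove self
    return counts


def counts_to_l(counts: np.ndarray, n: int, roi: ROI) -> np.ndarray:
    """Linearise neighbour counts into L values (nm)."""
    return np.cbrt(3.0 * roi.volume * np.asarray(counts, float) / (4.0 * (n - 1) * np.pi))


def l3d_all(table: LocalizationTable, roi: ROI, r: float) -> LocalLValues:
    """Localized linearised Ripley's L at radius r for every point."""
    if table.n < 2:
        raise ValueError("l3d_all requires at least 2 points")
    _check_radius(r, roi)
    counts = neighbour_counts(table.xyz, roi, r)
    return LocalLValues(counts_to_l(counts, table.n, roi), counts, float(r))


def csr_eligibility_threshold(n: int, roi: ROI, r: float):
    """CSR mean-plus-one-SD threshold, in count space and L space.

    Under CSR on the torus each point's neighbour count is
    Binomial(n - 1, p) with p = (4 pi r^3 / 3) / V.  A point is eligible —
    potentially part of a cluster — iff its count strictly exceeds
    c* = (n-1) p + sqrt((n-1) p (1-p)).  Returns ``(c_star, L_star)``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    _check_radius(r, roi)
    p = (4.0 * np.pi * r**3 / 3.0) / roi.volume
    if p > 1:
        raise ValueError("radius too large for ROI volume (p > 1)")
    mean = (n - 1) * p
    c_star = mean + np.sqrt(mean * (1.0 - p))
    L_star = float(counts_to_l(np.array([c_star]), n, roi)[0])
    return float(c_star), L_star


def eligible_mask(lvals: LocalLValues, n: int, roi: ROI) -> np.ndarray:
    """Boolean mask of points whose count strictly exceeds the CSR threshold."""
    c_star, _ = csr_eligibility_threshold(n, roi, lvals.r)
    return lvals.counts > c_star
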