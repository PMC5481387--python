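"""Ground-truth 3D SMLM point-pattern simulator.

Generates localization tables with known labels for validating the cluster
analysis.  The reference setup — the Standard Condition — is a
3000 × 3000 × 600 nm ROI containing 10 spherical Gaussian clusters of
radius (standard deviation) 30 nm with 50 molecules each, overlaid with an
equal number of non-clustered molecules, 1000 molecules in total, uniform
in z.  Each molecular coordinate is scrambled by independent Gaussian
measurement error whose standard deviation is drawn from a Gamma
distribution with mean 30 nm, mimicking the localisation process; the draw
is recorded as that point's precision triple.

Variants: totals from 100 to 2000 molecules, non-clustered fractions from
10% to 90%, membrane-proximal Beta z backgrounds (e.g. Beta(2, 5) and
Beta(2, 20) on z/Lz), hard-edge (uniform ball) clusters, ellipsoidal
clusters with axis ratio (1, 1, 2) oriented along a random coordinate axis,
and pure CSR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .locio import ROI, LocalizationTable

DEFAULT_ROI = ROI(3000.0, 3000.0, 600.0)
#: Gamma precision law: mean 30 nm; shape 4 gives scale 7.5 nm (SD 15 nm),
#: spanning the realistic 10-60 nm precision range.
DEFAULT_PRECISION_MEAN = 30.0
DEFAULT_PRECISION_SHAPE = 4.0


@dataclass(frozen=True)
class SimulationSpec:
    """Complete recipe for one simulated ROI.

    ``z_bg`` / ``z_centres`` are Beta shape pairs for z/Lz, or ``None`` for
    uniform.  ``precision_shape`` is the Gamma shape k (scale = mean/k).
    ``isotropic_precision`` draws one sigma per point for all three
    dimensions (iPALM-like); set False for independent per-dimension draws.
    """

    roi: ROI = DEFAULT_ROI
    n_total: int = 1000
    n_clusters: int = 10
    molecules_per_cluster: int = 50
    cluster_radius: float = 30.0
    shape: str = "gaussian"            # gaussian | hard_sphere | ellipsoid
    f_bg: float = 0.5
    z_bg: tuple | None = None
    z_centres: tuple | None = None
    precision_mean: float = DEFAULT_PRECISION_MEAN
    precision_shape: float = DEFAULT_PRECISION_SHAPE
    isotropic_precision: bool = True
    seed: int = 0

    def __post_init__(self):
        n_bg = int(round(self.f_bg * self.n_total))
        if self.n_clusters * self.molecules_per_cluster + n_bg != self.n_total:
            raise ValueError(
                f"inconsistent spec: {self.n_clusters} clusters x "
                f"{self.molecules_per_cluster} + {n_bg} background != {self.n_total}"
            )
        if self.shape not in ("gaussian", "hard_sphere", "ellipsoid"):
            raise ValueError(f"unknown cluster shape {self.shape!r}")
        if self.n_clusters > 0:
            margin = 3.0 * self.cluster_radius
            if 2 * margin >= min(self.roi.Lx, self.roi.Ly, self.roi.Lz):
                raise ValueError("cluster radius too large for the ROI interior")

    @property
    def n_background(self) -> int:
        return int(round(self.f_bg * self.n_total))


@dataclass
class GroundTruth:
    """True labels (0 background, 1..K), centres and cluster parameters."""

    labels: np.ndarray
    centres: np.ndarray          # (K, 3)
    radius: float
    shape: str
    axes: np.ndarray = field(default=None)  # ellipsoid long-axis index per cluster
    molecular_xyz: np.ndarray = field(default=None)  # noise-free positions (n, 3)


def standard_condition(seed: int = 0) -> SimulationSpec:
    """The Standard Condition: 10 Gaussian clusters (s = 30 nm, 50 molecules
    each) plus 500 uniform background molecules, 1000 total, uniform z."""
    return SimulationSpec(seed=seed)


def csr_condition(n_total: int = 1000, roi: ROI = DEFAULT_ROI, seed: int = 0) -> SimulationSpec:
    """Complete spatial randomness: no clusters, same total count."""
    return SimulationSpec(roi=roi, n_total=n_total, n_clusters=0,
                          molecules_per_cluster=0, f_bg=1.0, seed=seed)


def total_locs_condition(n_total: int, seed: int = 0) -> SimulationSpec:
    """Standard Condition with the total count varied (100-2000): 10 clusters,
    50% clustered, so molecules per cluster scales with the total."""
    if n_total % 20:
        raise ValueError("n_total must be a multiple of 20 (10 clusters, 50% clustered)")
    return SimulationSpec(n_total=n_total, molecules_per_cluster=n_total // 20, seed=seed)


def background_fraction_condition(f_bg: float, seed: int = 0) -> SimulationSpec:
    """Standard Condition with the non-clustered fraction varied (0.1-0.9)."""
    n_bg = int(round(f_bg * 1000))
    if (1000 - n_bg) % 10:
        raise ValueError("clustered count must split evenly over 10 clusters")
    return SimulationSpec(molecules_per_cluster=(1000 - n_bg) // 10, f_bg=f_bg, seed=seed)


def beta_background_condition(alpha: float = 2.0, beta: float = 20.0,
                              seed: int = 0) -> SimulationSpec:
    """Membrane-proximal condition: localisation z follows Beta(alpha, beta).

    The law applies to background molecules and cluster centres alike
    (centres additionally respect the 3s interior margin), emulating a
    membrane-associated protein whose whole population hugs one ROI face.
    """
    return SimulationSpec(z_bg=(alpha, beta), z_centres=(alpha, beta), seed=seed)


def hard_sphere_condition(seed: int = 0) -> SimulationSpec:
    """Hard-edge clusters: uniform density in a ball of radius s."""
    return SimulationSpec(shape="hard_sphere", seed=seed)


def ellipsoid_condition(seed: int = 0) -> SimulationSpec:
    """Ellipsoidal clusters, semi-axis ratio (1, 1, 2), long axis drawn
    uniformly from {x, y, z} per cluster."""
    return SimulationSpec(shape="ellipsoid", seed=seed)


def _sample_z(rng, law, size, Lz):
    if law is None:
        return rng.uniform(0.0, Lz, size)
    a, b = law
    return rng.beta(a, b, size) * Lz


def _uniform_ball(rng, m):
    """m points uniform in the unit ball (radial inversion)."""
    d = rng.standard_normal((m, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d * rng.uniform(0.0, 1.0, (m, 1)) ** (1.0 / 3.0)


def simulate_roi(spec: SimulationSpec):
    """Generate one ROI: returns ``(LocalizationTable, GroundTruth)``.

    Cluster centres are placed so the 3s sphere lies inside the ROI.
    Molecule coordinates falling outside the ROI after measurement noise
    are reflected at the faces, preserving exact counts.
    """
    rng = np.random.default_rng(spec.seed)
    roi, s, K = spec.roi, spec.cluster_radius, spec.n_clusters
    margin = 3.0 * s
    positions = []
    labels = []
    centres = np.empty((K, 3))
    axes = np.full(K, -1, dtype=int)
    for k in range(K):
        c = np.empty(3)
        c[0] = rng.uniform(margin, roi.Lx - margin)
        c[1] = rng.uniform(margin, roi.Ly - margin)
        while True:
            z = _sample_z(rng, spec.z_centres, 1, roi.Lz)[0]
            if margin <= z <= roi.Lz - margin:
                c[2] = z
                break
        centres[k] = c
        m = spec.molecules_per_cluster
        if spec.shape == "gaussian":
            pts = c + rng.standard_normal((m, 3)) * s
        elif spec.shape == "hard_sphere":
            pts = c + _uniform_ball(rng, m) * s
        else:  # ellipsoid (1, 1, 2) along a random coordinate axis
            axis = rng.integers(0, 3)
            axes[k] = axis
            semi = np.full(3, s)
            semi[axis] = 2.0 * s
            pts = c + _uniform_ball(rng, m) * semi
        positions.append(pts)
        labels.append(np.full(m, k + 1, dtype=np.int64))

    n_bg = spec.n_background
    bg = np.column_stack([
        rng.uniform(0.0, roi.Lx, n_bg),
        rng.uniform(0.0, roi.Ly, n_bg),
        _sample_z(rng, spec.z_bg, n_bg, roi.Lz),
    ])
    positions.append(bg)
    labels.append(np.zeros(n_bg, dtype=np.int64))

    xyz = np.vstack(positions) if positions else np.empty((0, 3))
    labels = np.concatenate(labels) if labels else np.empty(0, dtype=np.int64)

    n = len(xyz)
    scale = spec.precision_mean / spec.precision_shape
    if spec.isotropic_precision:
        sigma = np.repeat(rng.gamma(spec.precision_shape, scale, (n, 1)), 3, axis=1)
    else:
        sigma = rng.gamma(spec.precision_shape, scale, (n, 3))
    noisy = xyz + rng.standard_normal((n, 3)) * sigma
    # Reflect at the ROI faces: keeps exact counts and, unlike a toroidal
    # wrap, keeps membrane-proximal molecules near their face instead of
    # teleporting them across the box.
    noisy = np.mod(noisy, 2.0 * roi.lengths)
    noisy = roi.lengths - np.abs(roi.lengths - noisy)
    noisy = np.minimum(noisy, np.nextafter(roi.lengths, 0.0))

    table = LocalizationTable(noisy, sigma)
    truth = GroundTruth(labels=labels, centres=centres, radius=s,
                        shape=spec.shape, axes=axes, molecular_xyz=xyz)
    return table, truth


def true_descriptors(spec: SimulationSpec) -> dict:
    """The simulated ground-truth values of the four headline descriptors."""
    return {
        "K": spec.n_clusters,
        "percent_in_clusters": 100.0 * (1.0 - spec.f_bg),
        "mean_locs_per_cluster": float(spec.molecules_per_cluster),
        "mean_radius": spec.cluster_radius,
    }


def count_artificial_clusters(truth: GroundTruth, descriptors: dict,
                              match_factor: float = 3.0) -> int:
    """Detected clusters whose centroid lies farther than ``match_factor``
    times the true radius from every true centre."""
    det = np.array([[c["x"], c["y"], c["z"]] for c in descriptors["clusters"]])
    if len(det) == 0:
        return 0
    if len(truth.centres) == 0:
        return len(det)
    d = np.linalg.norm(det[:, None, :] - truth.centres[None, :, :], axis=2)
    return int((d.min(axis=1) > match_factor * truth.radius).sum())


def recovery_metrics(truth: GroundTruth, spec: SimulationSpec, descriptors: dict) -> dict:
    """Detected-vs-true comparison for the four headline descriptors plus the
    artificial-cluster count."""
    true = true_descriptors(spec)
    out = {}
    for key in ("K", "percent_in_clusters", "mean_locs_per_cluster", "mean_radius"):
        out[f"true_{key}"] = true[key]
        out[f"detected_{key}"] = descriptors[key]
        out[f"error_{key}"] = descriptors[key] - true[key]
    out["artificial_clusters"] = count_artificial_clusters(truth, descriptors)
    return out
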