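"""Localization-table I/O, ROI definition and coordinate conventions.

The universal input is a pointillist table: one row per localization with
coordinates ``(x, y, z)`` in nanometres and per-dimension localization
precisions ``(sigma_x, sigma_y, sigma_z)`` — the standard deviations of the
Gaussian fitting error, also in nanometres.  Coordinates are continuous,
0-based and half-open per axis: a point inside an ROI satisfies
``0 <= x < Lx`` and likewise for y and z.  All units are fixed to nm; no
unit autodetection is attempted.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column names, in order.
CANONICAL_COLUMNS = ("x", "y", "z", "sigma_x", "sigma_y", "sigma_z")

#: ThunderSTORM-style header aliases mapped onto the canonical names.
THUNDERSTORM_DIALECT = {
    "x [nm]": "x",
    "y [nm]": "y",
    "z [nm]": "z",
    "uncertainty_x [nm]": "sigma_x",
    "uncertainty_y [nm]": "sigma_y",
    "uncertainty_z [nm]": "sigma_z",
    "uncertainty_xy [nm]": "sigma_x",
    "uncertainty [nm]": "sigma_x",
}


class FormatError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


@dataclass(frozen=True)
class ROI:
    """Axis-aligned analysis box with its origin fixed at (0, 0, 0).

    Parameters
    ----------
    Lx, Ly, Lz
        Side lengths in nm.  The box volume ``V = Lx * Ly * Lz`` normalises
        the Ripley statistic, and the box topology is toroidal (periodic)
        for all neighbour computations.
    """

    Lx: float
    Ly: float
    Lz: float

    def __post_init__(self) -> None:
        if not (self.Lx > 0 and self.Ly > 0 and self.Lz > 0):
            raise ValueError("ROI side lengths must be strictly positive")

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.Lz

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz], dtype=float)


@dataclass
class LocalizationTable:
    """Validated per-point coordinates and localization precisions (nm).

    Rows violating the invariants (non-finite values, non-positive
    precisions) are rejected at construction by :meth:`from_arrays` /
    :func:`read_localizations`; direct construction trusts its input.
    """

    xyz: np.ndarray          # (n, 3) float64, nm
    sigma: np.ndarray        # (n, 3) float64, nm, strictly positive
    point_id: np.ndarray = field(default=None)  # (n,) int64

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(-1, 3)
        if self.xyz.shape != self.sigma.shape:
            raise ValueError("coordinate and precision arrays differ in length")
        if self.point_id is None:
            self.point_id = np.arange(len(self.xyz), dtype=np.int64)
        else:
            self.point_id = np.asarray(self.point_id, dtype=np.int64).ravel()
            if len(self.point_id) != len(self.xyz):
                raise ValueError("point_id length mismatch")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def n(self) -> int:
        return len(self.xyz)

    @classmethod
    def from_arrays(cls, xyz, sigma, point_id=None) -> "LocalizationTable":
        """Build a table, dropping (and logging) rows that violate invariants."""
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        sigma = np.asarray(sigma, dtype=float).reshape(-1, 3)
        ok = np.isfinite(xyz).all(axis=1) & np.isfinite(sigma).all(axis=1)
        ok &= (sigma > 0).all(axis=1)
        dropped = int((~ok).sum())
        if dropped:
            logger.warning("dropped %d invalid localization row(s)", dropped)
        pid = None if point_id is None else np.asarray(point_id)[ok]
        return cls(xyz[ok], sigma[ok], pid)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.xyz, columns=["x", "y", "z"])
        df[["sigma_x", "sigma_y", "sigma_z"]] = self.sigma
        df.insert(0, "point_id", self.point_id)
        return df


def read_localizations(path, dialect: dict | None = None) -> LocalizationTable:
    """Read a delimited localization table (CSV or TSV, header required).

    ``dialect`` maps file column names onto the canonical six
    (``x, y, z, sigma_x, sigma_y, sigma_z``); pass
    :data:`THUNDERSTORM_DIALECT` for ThunderSTORM exports.  Rows with any
    non-finite value or non-positive precision are dropped with a logged
    count.  An empty file yields an empty table.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return LocalizationTable(np.empty((0, 3)), np.empty((0, 3)))
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    pid = df["point_id"].to_numpy() if "point_id" in df.columns else None
    return LocalizationTable.from_arrays(
        df[["x", "y", "z"]].to_numpy(float),
        df[["sigma_x", "sigma_y", "sigma_z"]].to_numpy(float),
        pid,
    )


def crop_to_roi(table: LocalizationTable, roi: ROI, corner=(0.0, 0.0, 0.0)) -> LocalizationTable:
    """Translate by ``-corner`` and keep points strictly inside ``[0, L)`` per axis.

    Order is preserved and the operation is idempotent for ``corner=(0,0,0)``.
    """
    corner = np.asarray(corner, dtype=float)
    shifted = table.xyz - corner
    keep = ((shifted >= 0) & (shifted < roi.lengths)).all(axis=1)
    return LocalizationTable(shifted[keep], table.sigma[keep], table.point_id[keep])


def write_results(table: LocalizationTable, labels, l_values, descriptors: dict,
                  out_dir, prefix: str = "roi") -> dict:
    """Write the standard result triple for one ROI.

    Emits ``<prefix>_points.csv`` (input columns + ``cluster_label`` +
    ``L_value``), ``<prefix>_clusters.csv`` (one row per detected cluster)
    and ``<prefix>_summary.json`` (ROI-level descriptors).  Returns the
    paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    labels = np.asarray(labels, dtype=int)
    if len(labels) != table.n:
        raise ValueError("labels length must equal table length")

    df = table.to_dataframe()
    df["cluster_label"] = labels
    df["L_value"] = np.asarray(l_values, dtype=float) if l_values is not None else np.nan
    points_path = os.path.join(out_dir, f"{prefix}_points.csv")
    df.to_csv(points_path, index=False, float_format="%.17g")

    clusters = pd.DataFrame(descriptors.get("clusters", []))
    clusters_path = os.path.join(out_dir, f"{prefix}_clusters.csv")
    clusters.to_csv(clusters_path, index=False, float_format="%.17g")

    summary = {k: v for k, v in descriptors.items() if k != "clusters"}
    summary_path = os.path.join(out_dir, f"{prefix}_summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return {"points": points_path, "clusters": clusters_path, "summary": summary_path}
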