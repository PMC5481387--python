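"""Cluster descriptors and z-resolved profiles for a MAP proposal.

Reported per cluster: the model radius (the radius-prior bin maximising the
cluster's marginal term — the model-consistent estimate of the Gaussian
standard deviation s), the empirical RMS radius, the precision-weighted
centroid and the point count.  Reported per ROI: number of clusters K,
percentage of localisations in clusters, mean localisations per cluster and
mean radius.  The z profile resolves clustering along the optical axis in
30 nm bins by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locio import ROI, LocalizationTable
from .model import (ModelConfig, ScoredProposal, ZBackgroundModel,
                    log_marginal_cluster_terms)


@dataclass
class ZProfile:
    """Per-z-bin clustering profile (bin width 30 nm by default).

    ``cluster_fraction``: fraction of detected clusters whose centroid z
    falls in the bin (sums to 1 when K > 0).  ``percent_in_clusters``:
    clustered localisations in the bin / all localisations in the bin × 100
    (per-bin normalisation).
    """

    edges: np.ndarray
    cluster_fraction: np.ndarray
    percent_in_clusters: np.ndarray
    locs_per_bin: np.ndarray
    clustered_locs_per_bin: np.ndarray


def summarize(best: ScoredProposal, table: LocalizationTable, roi: ROI,
              config: ModelConfig, z_model: ZBackgroundModel | None = None) -> dict:
    """Per-cluster and per-ROI descriptors of the MAP proposal."""
    z_model = z_model or ZBackgroundModel.uniform()
    labels = best.proposal.labels
    n = table.n
    clusters = []
    centres = np.asarray(config.radius_prior.centres)
    log_w = config.radius_prior.log_weights
    for k in range(1, best.proposal.K + 1):
        members = labels == k
        m = int(members.sum())
        if m == 0:
            continue
        xyz = table.xyz[members]
        sig = table.sigma[members]
        terms = log_marginal_cluster_terms(xyz, sig, roi, z_model, config.radius_prior)
        s_star = float(centres[int(np.argmax(terms + log_w))])
        v = s_star * s_star + sig * sig
        w = 1.0 / v
        centroid = (w * xyz).sum(axis=0) / w.sum(axis=0)
        rms = float(np.sqrt(((xyz - centroid) ** 2).sum() / (3 * m)))
        clusters.append({
            "id": k, "n_points": m,
            "x": float(centroid[0]), "y": float(centroid[1]), "z": float(centroid[2]),
            "map_radius": s_star, "rms_radius": rms,
        })
    n_clustered = int((labels > 0).sum())
    K = len(clusters)
    return {
        "n_total": n,
        "n_background": n - n_clustered,
        "K": K,
        "percent_in_clusters": 100.0 * n_clustered / n if n else 0.0,
        "mean_locs_per_cluster": float(np.mean([c["n_points"] for c in clusters])) if K else 0.0,
        "mean_radius": float(np.mean([c["map_radius"] for c in clusters])) if K else 0.0,
        "best_r": best.proposal.r,
        "best_T": best.proposal.T,
        "log_score": best.log_score,
        "clusters": clusters,
    }


def z_profile(descriptors: dict, table: LocalizationTable, roi: ROI,
              labels: np.ndarray, bin_width: float = 30.0) -> ZProfile:
    """Z-resolved clustering profile; final bin truncated if the width does
    not divide Lz."""
    edges = np.arange(0.0, roi.Lz + bin_width, bin_width)
    edges[-1] = min(edges[-1], roi.Lz)
    edges = np.unique(edges)
    z = table.xyz[:, 2]
    total, _ = np.histogram(z, bins=edges)
    clustered, _ = np.histogram(z[np.asarray(labels) > 0], bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * clustered / np.maximum(total, 1), 0.0)
    cz = np.array([c["z"] for c in descriptors["clusters"]])
    if len(cz):
        counts, _ = np.histogram(np.clip(cz, 0, roi.Lz - 1e-9), bins=edges)
        frac = counts / counts.sum()
    else:
        frac = np.zeros(len(edges) - 1)
    return ZProfile(edges=edges, cluster_fraction=frac, percent_in_clusters=pct,
                    locs_per_bin=total, clustered_locs_per_bin=clustered)


def batch_summary(per_roi: list[dict]) -> pd.DataFrame:
    """Condition-level table: one row per ROI plus mean and SEM rows.

    With a single ROI the SEM is undefined and reported as 0 with the
    ``sem_defined`` flag set to False on the SEM row.
    """
    if not per_roi:
        raise ValueError("need at least one ROI")
    fields = ["n_total", "K", "percent_in_clusters", "mean_locs_per_cluster", "mean_radius"]
    rows = pd.DataFrame([{f: d[f] for f in fields} for d in per_roi])
    rows.insert(0, "roi", range(len(per_roi)))
    rows["kind"] = "roi"
    mean = rows[fields].mean()
    if len(per_roi) > 1:
        sem = rows[fields].std(ddof=1) / np.sqrt(len(per_roi))
        sem_defined = True
    else:
        sem = pd.Series(0.0, index=fields)
        sem_defined = False
    mean_row = {"roi": -1, **mean.to_dict(), "kind": "mean"}
    sem_row = {"roi": -1, **sem.to_dict(), "kind": "sem", "sem_defined": sem_defined}
    out = pd.concat([rows, pd.DataFrame([mean_row, sem_row])], ignore_index=True)
    if "sem_defined" in out.columns:
        out["sem_defined"] = out["sem_defined"].astype(object).where(out["kind"] == "sem", pd.NA)
    return out
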