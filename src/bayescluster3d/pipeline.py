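"""End-to-end analysis: fit the z background, sweep proposals, score, select
the MAP proposal and extract descriptors — for one ROI or a batch."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .descriptors import ZProfile, summarize, z_profile
from .locio import ROI, LocalizationTable
from .model import (ModelConfig, ScoredProposal, ZBackgroundModel, fit_beta_z,
                    score_proposal, select_best)
from .proposal import sweep
from .ripley3d import l3d_all

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything the pipeline produces for one ROI."""

    best: ScoredProposal
    descriptors: dict
    z_model: ZBackgroundModel
    profile: ZProfile
    n_proposals: int

    @property
    def labels(self) -> np.ndarray:
        return self.best.proposal.labels


def analyze_roi(table: LocalizationTable, roi: ROI,
                config: ModelConfig | None = None,
                z_bin_width: float = 30.0) -> AnalysisResult:
    """Run the full Bayesian cluster analysis on one ROI.

    An ROI with fewer than 2 points yields the trivial all-background
    result.  The winning (r, T, K, score) is logged at INFO level.
    """
    config = config or ModelConfig()
    if config.z_mode == "fit-beta":
        z_model = fit_beta_z(table, roi)
    else:
        z_model = ZBackgroundModel.uniform()

    if table.n < 2:
        from .proposal import ClusterProposal
        trivial = ClusterProposal(np.zeros(table.n, dtype=np.int64), 0.0, 0.0)
        best = score_proposal(trivial, table, roi, config, z_model)
        proposals = [trivial]
    else:
        proposals = sweep(table, roi, config.grid, config.min_cluster_size)
        scored = [score_proposal(p, table, roi, config, z_model) for p in proposals]
        best = select_best(scored)
    logger.info("MAP proposal: r=%.0f T=%.0f K=%d score=%.2f (%d proposals)",
                best.proposal.r, best.proposal.T, best.proposal.K,
                best.log_score, len(proposals))
    desc = summarize(best, table, roi, config, z_model)
    profile = z_profile(desc, table, roi, best.proposal.labels, z_bin_width)
    return AnalysisResult(best=best, descriptors=desc, z_model=z_model,
                          profile=profile, n_proposals=len(proposals))


def best_l_values(result: AnalysisResult, table: LocalizationTable, roi: ROI) -> np.ndarray:
    """L3D values at the MAP proposal's generating radius (zeros if trivial)."""
    r = result.best.proposal.r
    if r <= 0 or table.n < 2:
        return np.zeros(table.n)
    return l3d_all(table, roi, r).L


def analyze_batch(tables: list[LocalizationTable], roi: ROI,
                  config: ModelConfig | None = None) -> list[AnalysisResult]:
    """Analyze a list of ROIs sequentially (deterministic order)."""
    return [analyze_roi(t, roi, config) for t in tables]
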