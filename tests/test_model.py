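import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import logsumexp

from bayescluster3d import (LocalizationTable, ModelConfig, RadiusPrior, ROI,
                            ZBackgroundModel, fit_beta_z, log_background_density,
                            log_marginal_cluster, score_proposal, select_best)
from bayescluster3d.model import _log_centre_integral_1d, log_marginal_cluster_terms
from bayescluster3d.proposal import ClusterProposal
from bayescluster3d.model import ScoredProposal

from .conftest import make_table


def quad_log_integral_1d(x, v):
    """Numerical oracle for the centre integral in one dimension."""
    x = np.asarray(x, float)
    v = np.asarray(v, float)
    mu0 = np.average(x, weights=1 / v)

    def integrand(mu):
        return np.exp(stats.norm.logpdf(x, mu, np.sqrt(v)).sum())

    span = 12 * np.sqrt(v.min() / len(x)) + 2 * (x.max() - x.min() + 1)
    val, _ = quad(integrand, mu0 - span, mu0 + span, limit=200)
    return np.log(val)


class TestCentreIntegral:
    def test_single_point_integrates_to_one(self):
        logI, mu = _log_centre_integral_1d(np.array([42.0]), np.array([900.0]))
        assert logI == pytest.approx(0.0, abs=1e-12)
        assert mu == 42.0

    def test_two_identical_points_closed_form(self):
        v = 400.0
        logI, _ = _log_centre_integral_1d(np.array([7.0, 7.0]), np.array([v, v]))
        assert logI == pytest.approx(-0.5 * np.log(4 * np.pi * v), rel=1e-12)

    def test_matches_quadrature_on_random_clusters(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 7))
            x = rng.normal(500.0, 30.0, m)
            v = rng.uniform(200.0, 2500.0, m)
            closed, _ = _log_centre_integral_1d(x, v)
            assert closed == pytest.approx(quad_log_integral_1d(x, v), rel=1e-6)


class TestBetaFit:
    @pytest.mark.parametrize("a,b,tol", [(1.0, 1.0, 0.05), (2.0, 5.0, 0.10),
                                         (2.0, 20.0, 0.10)])
    def test_recovers_shape_parameters(self, rng, roi, a, b, tol):
        z = rng.beta(a, b, 10_000) * roi.Lz
        xyz = np.column_stack([rng.uniform(0, roi.Lx, 10_000),
                               rng.uniform(0, roi.Ly, 10_000), z])
        fit = fit_beta_z(make_table(xyz), roi)
        assert fit.alpha == pytest.approx(a, rel=tol)
        assert fit.beta == pytest.approx(b, rel=tol)

    def test_small_sample_falls_back_to_uniform(self, rng, roi):
        xyz = rng.uniform(0, 1, (5, 3)) * roi.lengths
        assert fit_beta_z(make_table(xyz), roi).is_uniform


class TestBackgroundDensity:
    def test_uniform_model_is_log_inverse_volume(self, roi):
        val = log_background_density(np.array([300.0]), roi, ZBackgroundModel.uniform())
        assert val[0] == pytest.approx(-np.log(roi.volume))
        assert val[0] == pytest.approx(-22.41, abs=0.01)

    def test_beta_one_one_equals_uniform(self, roi):
        z = np.linspace(1.0, 599.0, 25)
        uni = log_background_density(z, roi, ZBackgroundModel.uniform())
        b11 = log_background_density(z, roi, ZBackgroundModel(1.0, 1.0))
        np.testing.assert_allclose(uni, b11)

    def test_membrane_proximal_beta_orders_depths(self, roi):
        zm = ZBackgroundModel(2.0, 20.0)
        shallow = log_background_density(np.array([0.05 * roi.Lz]), roi, zm)
        deep = log_background_density(np.array([0.5 * roi.Lz]), roi, zm)
        assert shallow[0] > deep[0]
        # direct pdf cross-check
        assert np.exp(zm.logpdf(0.05)) == pytest.approx(stats.beta.pdf(0.05, 2, 20))


class TestClusterMarginal:
    def _random_cluster(self, rng, m):
        xyz = rng.normal((1500, 1500, 300), 25.0, (m, 3))
        sigma = rng.uniform(10.0, 40.0, (m, 3))
        return xyz, sigma

    def test_full_marginal_matches_assembled_quadrature(self, rng, roi):
        prior = RadiusPrior((20.0, 40.0))
        zm = ZBackgroundModel(2.0, 5.0)
        for _ in range(5):
            xyz, sigma = self._random_cluster(rng, int(rng.integers(2, 6)))
            parts = []
            for s, w in zip(prior.centres, prior.weights):
                v = s**2 + sigma**2
                dims = sum(quad_log_integral_1d(xyz[:, d], v[:, d]) for d in range(3))
                mu_z = np.average(xyz[:, 2], weights=1 / v[:, 2])
                centre = (-np.log(roi.Lx) - np.log(roi.Ly) - np.log(roi.Lz)
                          + zm.logpdf(mu_z / roi.Lz))
                parts.append(np.log(w) + dims + centre)
            oracle = logsumexp(parts)
            ours = log_marginal_cluster(xyz, sigma, roi, zm, prior)
            assert ours == pytest.approx(oracle, rel=1e-6)

    def test_terms_peak_near_true_radius(self, rng, roi):
        rngl = np.random.default_rng(7)
        xyz = rngl.normal((1500, 1500, 300), 30.0, (200, 3))
        sigma = np.full((200, 3), 10.0)
        prior = RadiusPrior()
        terms = log_marginal_cluster_terms(xyz, sigma, roi,
                                           ZBackgroundModel.uniform(), prior)
        assert prior.centres[int(np.argmax(terms))] == pytest.approx(30.0, abs=5.0)


class TestScoring:
    def _score(self, labels, table, roi, config, zm):
        prop = ClusterProposal(np.asarray(labels), 50.0, 0.0)
        return score_proposal(prop, table, roi, config, zm).log_score

    def test_all_background_score_exact(self, rng, roi):
        xyz = rng.uniform(0, 1, (30, 3)) * roi.lengths
        table = make_table(xyz)
        cfg = ModelConfig(z_mode="uniform")
        s = self._score(np.zeros(30, int), table, roi, cfg, ZBackgroundModel.uniform())
        assert s == pytest.approx(-30 * np.log(roi.volume) + 30 * np.log(0.5))

    def test_tight_cluster_beats_background(self, roi):
        rng = np.random.default_rng(3)
        xyz = rng.normal((1500, 1500, 300), 10.0, (20, 3))
        table = LocalizationTable(xyz, np.full((20, 3), 10.0))
        cfg = ModelConfig()
        zm = ZBackgroundModel.uniform()
        clustered = self._score(np.ones(20, int), table, roi, cfg, zm)
        background = self._score(np.zeros(20, int), table, roi, cfg, zm)
        assert clustered > background

    def test_csr_points_prefer_background(self, roi):
        rng = np.random.default_rng(4)
        xyz = rng.uniform(0, 1, (20, 3)) * roi.lengths
        table = LocalizationTable(xyz, np.full((20, 3), 10.0))
        cfg = ModelConfig()
        zm = ZBackgroundModel.uniform()
        clustered = self._score(np.ones(20, int), table, roi, cfg, zm)
        background = self._score(np.zeros(20, int), table, roi, cfg, zm)
        assert background > clustered

    def test_score_invariant_to_cluster_id_permutation(self, rng, roi):
        xyz = rng.uniform(0, 1, (40, 3)) * roi.lengths
        table = make_table(xyz)
        cfg = ModelConfig()
        zm = ZBackgroundModel(2.0, 5.0)
        labels = rng.integers(0, 3, 40)
        permuted = np.choose(labels, [0, 2, 1])
        assert (self._score(labels, table, roi, cfg, zm)
                == pytest.approx(self._score(permuted, table, roi, cfg, zm)))

    def test_bernoulli_term_constant_at_half(self, rng, roi):
        # at p_bg = 0.5 the labelling prior contributes n log(1/2) for any
        # labelling, so score differences equal likelihood differences
        xyz = rng.uniform(0, 1, (25, 3)) * roi.lengths
        table = make_table(xyz)
        cfg = ModelConfig(p_bg=0.5)
        zm = ZBackgroundModel.uniform()
        la = np.zeros(25, int)
        lb = np.zeros(25, int); lb[:6] = 1
        diff = self._score(la, table, roi, cfg, zm) - self._score(lb, table, roi, cfg, zm)
        bg = log_background_density(table.xyz[:6, 2], roi, zm).sum()
        marg = log_marginal_cluster(table.xyz[:6], table.sigma[:6], roi, zm,
                                    cfg.radius_prior)
        assert diff == pytest.approx(bg - marg)


class TestSelectBest:
    def _sp(self, score, K, r=50.0, T=0.0, n=4):
        labels = np.zeros(n, int)
        labels[:K] = np.arange(1, K + 1)
        return ScoredProposal(ClusterProposal(labels, r, T), score)

    def test_single_proposal_returned(self):
        sp = self._sp(-10.0, 1)
        assert select_best([sp]) is sp

    def test_highest_score_wins(self):
        best = select_best([self._sp(-100.0, 1), self._sp(-90.0, 2), self._sp(-95.0, 3)])
        assert best.log_score == -90.0

    def test_tie_broken_by_fewer_clusters(self):
        best = select_best([self._sp(-50.0, 3, n=6), self._sp(-50.0, 5, n=6)])
        assert best.proposal.K == 3

    def test_tie_broken_by_smaller_r_then_t(self):
        a = self._sp(-50.0, 2, r=80.0, T=10.0, n=4)
        b = self._sp(-50.0, 2, r=50.0, T=20.0, n=4)
        c = self._sp(-50.0, 2, r=50.0, T=10.0, n=4)
        assert select_best([a, b, c]) is c
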