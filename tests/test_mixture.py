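"""EM fitting of the per-group mixture over paired z-scores."""

import math
import warnings

import numpy as np
import pytest

from dcseq import (
    ModelSpec,
    PosteriorResult,
    MixtureParams,
    SubsamplingConfig,
    ZScorePairs,
    dc_posterior_summary,
    e_step,
    elevated_dc_classes,
    enumerate_pairs,
    fit_em,
    fit_em_subsampled,
    m_step,
)
from dcseq.mixture import collapse_component_label, independent_pair_sample
from dcseq.errors import ValidationError

SPEC3 = ModelSpec(3)


def hand_params():
    return MixtureParams(
        mu1=np.array([-1.0, 0.0, 1.2]),
        mu2=np.array([-0.9, 0.0, 1.1]),
        sigma1=np.array([0.5, 0.3, 0.6]),
        sigma2=np.array([0.4, 0.35, 0.5]),
        pi=np.array([[0.05, 0.02, 0.03], [0.04, 0.60, 0.06], [0.02, 0.08, 0.10]]),
        spec=SPEC3,
    )


def simulate_z(params, n, seed):
    """Draw z-pairs from a mixture — the generative oracle for recovery tests."""
    rng = np.random.default_rng(seed)
    k = params.spec.components
    flat = params.pi.ravel()
    cls = rng.choice(k * k, size=n, p=flat)
    a, b = np.divmod(cls, k)
    z1 = rng.normal(params.mu1[a], params.sigma1[a])
    z2 = rng.normal(params.mu2[b], params.sigma2[b])
    return ZScorePairs(z1, z2, np.zeros(n, bool)), a, b


class TestEStep:
    def test_matches_nine_term_hand_evaluation(self):
        params = hand_params()
        z1, z2 = 0.3, -0.2

        def phi(x, mu, sd):
            return math.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))

        terms = np.array(
            [
                [
                    params.pi[a, b]
                    * phi(z1, params.mu1[a], params.sigma1[a])
                    * phi(z2, params.mu2[b], params.sigma2[b])
                    for b in range(3)
                ]
                for a in range(3)
            ]
        )
        expected = terms / terms.sum()
        res = e_step(ZScorePairs(np.array([z1]), np.array([z2]), np.zeros(1, bool)), params)
        np.testing.assert_allclose(res.class_posteriors[0].reshape(3, 3), expected, atol=1e-12)
        assert res.loglik == pytest.approx(math.log(terms.sum()), abs=1e-12)
        assert res.dc_posterior[0] == pytest.approx(
            expected.sum() - np.trace(expected), abs=1e-12
        )

    def test_diagonal_pi_gives_zero_dc(self, rng):
        params = hand_params()
        pi = np.zeros((3, 3))
        np.fill_diagonal(pi, [0.2, 0.5, 0.3])
        params = MixtureParams(params.mu1, params.mu2, params.sigma1, params.sigma2, pi, SPEC3)
        z = ZScorePairs(rng.normal(size=40), rng.normal(size=40), np.zeros(40, bool))
        res = e_step(z, params)
        np.testing.assert_allclose(res.dc_posterior, 0.0, atol=1e-12)

    def test_symmetric_params_symmetric_posterior(self, rng):
        mu = np.array([-1.0, 0.0, 1.0])
        sd = np.array([0.4, 0.3, 0.4])
        pi = np.array([[0.1, 0.05, 0.02], [0.05, 0.4, 0.05], [0.02, 0.05, 0.26]])
        params = MixtureParams(mu, mu, sd, sd, pi, SPEC3)
        zv = rng.normal(size=25)
        res = e_step(ZScorePairs(zv, zv.copy(), np.zeros(25, bool)), params)
        g = res.class_posteriors.reshape(-1, 3, 3)
        np.testing.assert_allclose(g, np.transpose(g, (0, 2, 1)), atol=1e-12)

    def test_rows_sum_to_one_and_extreme_z_finite(self):
        params = hand_params()
        z = ZScorePairs(np.array([8.4, -8.4]), np.array([-8.4, 0.0]), np.zeros(2, bool))
        res = e_step(z, params)
        np.testing.assert_allclose(res.class_posteriors.sum(axis=1), 1.0, atol=1e-8)
        assert np.isfinite(res.loglik)

    def test_missing_pairs_reported_as_nan(self):
        params = hand_params()
        z = ZScorePairs(np.array([0.1, np.nan]), np.array([0.2, 0.3]), np.zeros(2, bool))
        res = e_step(z, params)
        assert np.isnan(res.dc_posterior[1]) and res.class_assignment[1] == -1
        assert np.isfinite(res.dc_posterior[0])


class TestMStep:
    def test_all_mass_on_null_class(self):
        z = ZScorePairs(np.array([0.1, -0.1]), np.array([0.0, 0.05]), np.zeros(2, bool))
        gamma = np.zeros((2, 9))
        gamma[:, 4] = 1.0  # class (0, 0)
        post = PosteriorResult(gamma, np.zeros(2), np.full(2, 4), 0.0, SPEC3)
        with pytest.warns(UserWarning, match="empty"):
            params = m_step(z, post, SPEC3, hand_params())
        assert params.pi[1, 1] == pytest.approx(1.0)
        assert params.pi.sum() == pytest.approx(1.0)

    def test_hard_responsibilities_give_subgroup_means(self):
        z = ZScorePairs(np.array([0.8, -0.6]), np.array([0.7, -0.5]), np.zeros(2, bool))
        gamma = np.zeros((2, 9))
        gamma[0, 8] = 1.0  # pair 0 -> (+, +)
        gamma[1, 0] = 1.0  # pair 1 -> (-, -)
        post = PosteriorResult(gamma, np.ones(2), np.array([8, 0]), 0.0, SPEC3)
        with pytest.warns(UserWarning, match="empty"):
            params = m_step(z, post, SPEC3, hand_params())
        assert params.mu1[2] == pytest.approx(0.8)
        assert params.mu1[0] == pytest.approx(-0.6)
        assert params.mu2[2] == pytest.approx(0.7)
        assert params.mu1[1] == 0.0  # pinned null mean
        # single-point components bottom out at the SD floor
        assert params.sigma1[2] == pytest.approx(0.01)
        # empty null component keeps its previous SD
        assert params.sigma1[1] == pytest.approx(hand_params().sigma1[1])

    def test_fixed_point_does_not_decrease_loglik(self):
        z, _, _ = simulate_z(hand_params(), 800, seed=5)
        fit = fit_em(z, SPEC3, restarts=0)
        post = e_step(z, fit.params)
        params2 = m_step(z, post, SPEC3, fit.params)
        post2 = e_step(z, params2)
        assert post2.loglik >= post.loglik - 1e-10


def _pi5():
    pi = np.full((5, 5), 0.3 / 20)
    np.fill_diagonal(pi, [0.1, 0.1, 0.3, 0.1, 0.1])
    return pi


class TestFitEm:
    def test_parameter_recovery_from_known_mixture(self):
        truth = MixtureParams(
            mu1=np.array([-1.2, 0.0, 1.2]),
            mu2=np.array([-1.2, 0.0, 1.2]),
            sigma1=np.array([0.25, 0.25, 0.25]),
            sigma2=np.array([0.25, 0.25, 0.25]),
            pi=np.array([[0.20, 0.02, 0.03], [0.04, 0.30, 0.05], [0.03, 0.06, 0.27]]),
            spec=SPEC3,
        )
        z, _, _ = simulate_z(truth, 5000, seed=1)
        fit = fit_em(z, SPEC3, seed=1)
        assert fit.converged
        np.testing.assert_allclose(fit.params.mu1, truth.mu1, atol=0.05)
        np.testing.assert_allclose(fit.params.mu2, truth.mu2, atol=0.05)
        np.testing.assert_allclose(fit.params.pi, truth.pi, atol=0.02)

    def test_loglik_monotone_along_trace(self):
        z, _, _ = simulate_z(hand_params(), 1500, seed=9)
        fit = fit_em(z, SPEC3, restarts=0)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-10)

    def test_null_data_concentrates_on_null_class(self):
        z = ZScorePairs(np.zeros(300), np.zeros(300), np.zeros(300, bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_em(z, SPEC3, restarts=0)
        assert np.all(fit.posterior.dc_posterior < 0.05)

    def test_same_seed_bit_identical(self):
        z, _, _ = simulate_z(hand_params(), 600, seed=2)
        f1 = fit_em(z, SPEC3, seed=42)
        f2 = fit_em(z, SPEC3, seed=42)
        np.testing.assert_array_equal(f1.posterior.dc_posterior, f2.posterior.dc_posterior)
        np.testing.assert_array_equal(f1.params.pi, f2.params.pi)

    def test_sign_symmetry(self):
        z, _, _ = simulate_z(hand_params(), 2000, seed=3)
        neg = ZScorePairs(-z.z1, -z.z2, z.clipped)
        f = fit_em(z, SPEC3, restarts=0)
        g = fit_em(neg, SPEC3, restarts=0)
        np.testing.assert_allclose(g.params.mu1, -f.params.mu1[::-1], atol=1e-3)
        np.testing.assert_allclose(g.params.pi, f.params.pi[::-1, ::-1], atol=1e-3)

    def test_five_component_smoke(self):
        truth5 = MixtureParams(
            mu1=np.array([-2.0, -0.8, 0.0, 0.8, 2.0]),
            mu2=np.array([-2.0, -0.8, 0.0, 0.8, 2.0]),
            sigma1=np.full(5, 0.2),
            sigma2=np.full(5, 0.2),
            pi=_pi5(),
            spec=ModelSpec(5),
        )
        z, _, _ = simulate_z(truth5, 4000, seed=4)
        fit = fit_em(z, ModelSpec(5), seed=4)
        assert fit.posterior.class_posteriors.shape[1] == 25
        np.testing.assert_allclose(fit.params.mu1, truth5.mu1, atol=0.1)


class TestSubsampling:
    def test_within_matching_uses_each_feature_once(self, rng):
        idx = enumerate_pairs(10)
        pos = independent_pair_sample(idx, rng)
        assert pos.size == 5
        feats = idx.pairs[pos].ravel()
        assert len(set(feats.tolist())) == 10

    def test_between_matching_no_feature_reuse(self, rng):
        idx = enumerate_pairs(6, 40)
        pos = independent_pair_sample(idx, rng)
        pairs = idx.pairs[pos]
        assert pos.size == 6
        assert len(set(pairs[:, 0].tolist())) == 6
        assert len(set(pairs[:, 1].tolist())) == 6

    def test_single_round_equals_fit_on_subset(self):
        truth = hand_params()
        z, _, _ = simulate_z(truth, 400, seed=6)
        idx = enumerate_pairs(z.n_pairs // 20, 20)  # 20x20 grid covering 400 pairs
        cfg = SubsamplingConfig(iterations=1, seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = fit_em_subsampled(z, idx, SPEC3, cfg)
            pos = independent_pair_sample(idx, np.random.default_rng(13))
            direct = fit_em(
                ZScorePairs(z.z1[pos], z.z2[pos], np.zeros(pos.size, bool)), SPEC3
            )
        np.testing.assert_allclose(sub.params.mu1, direct.params.mu1, atol=1e-12)
        np.testing.assert_allclose(sub.params.pi, direct.params.pi, atol=1e-12)

    def test_agrees_with_standard_em_given_adequate_rounds(self):
        """With enough independent pairs per round the subsampled posteriors
        rank pairs like the standard fit."""
        from scipy.stats import spearmanr

        truth = hand_params()
        idx = enumerate_pairs(120, 120)
        z, _, _ = simulate_z(truth, idx.n_pairs, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            std = fit_em(z, SPEC3, seed=0)
            sub = fit_em_subsampled(
                z, idx, SPEC3, SubsamplingConfig(iterations=30, seed=5)
            )
        rho = spearmanr(std.posterior.dc_posterior, sub.posterior.dc_posterior).statistic
        assert rho >= 0.95


class TestOutputsAndClasses:
    def test_within_summary_fills_lower_triangle(self):
        params = hand_params()
        idx = enumerate_pairs(3)
        z = ZScorePairs(np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.2, 0.3]), None)
        res = e_step(z, params)
        pp, cls = dc_posterior_summary(res, idx)
        assert pp.shape == (3, 3)
        filled = ~np.isnan(pp)
        assert filled.sum() == 3
        assert np.all(np.tril(np.ones((3, 3)), k=-1).astype(bool) == filled)
        # flattening in enumeration order reproduces the vector
        np.testing.assert_array_equal(
            pp[idx.pairs[:, 1], idx.pairs[:, 0]], res.dc_posterior
        )

    def test_between_summary_fills_rectangle(self):
        params = hand_params()
        idx = enumerate_pairs(2, 3)
        z = ZScorePairs(np.linspace(-1, 1, 6), np.linspace(1, -1, 6), None)
        res = e_step(z, params)
        pp, _ = dc_posterior_summary(res, idx)
        assert pp.shape == (2, 3)
        assert np.isfinite(pp).all()

    def test_elevated_classes_enumeration(self):
        got = elevated_dc_classes(ModelSpec(5))
        assert got == {(0, 1), (1, 0), (3, 4), (4, 3)}
        with pytest.raises(ValidationError):
            elevated_dc_classes(ModelSpec(3))

    def test_label_collapse(self):
        assert collapse_component_label("++") == "+"
        assert collapse_component_label("--") == "-"
        # (++, +) collapses to a concordant class; (--, +) stays discordant
        assert collapse_component_label("++") == collapse_component_label("+")
        assert collapse_component_label("--") != collapse_component_label("+")

    def test_class_counts(self):
        assert ModelSpec(3).n_classes == 9
        assert ModelSpec(5).n_classes == 25
        assert len(ModelSpec(5).class_labels()) == 25
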