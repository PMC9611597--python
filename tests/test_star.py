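"""Model-stage tests: multinomial link, likelihood oracle, PG moments,
sampler structure, DIC arithmetic, posterior summaries."""

import math

import numpy as np
import pytest

import empowermap as em
from empowermap.design import DesignMatrices
from empowermap.pg import polya_gamma
from empowermap.star import (
    ParameterState,
    _loglik_eta,
    compute_dic,
    deviance,
    summarize_posterior,
)


class TestMultinomialProbs:
    def test_symmetry_at_zero(self):
        assert np.allclose(em.multinomial_probs(0.0, 0.0), (1 / 3, 1 / 3, 1 / 3))

    def test_ln2_example(self):
        p = em.multinomial_probs(math.log(2.0), 0.0)
        assert np.allclose(p, (0.5, 0.25, 0.25))

    def test_limiting_case(self):
        p = em.multinomial_probs(-50.0, 0.0)
        assert p[0] == pytest.approx(0.0, abs=1e-12)
        assert p[1] == pytest.approx(0.5, abs=1e-12)
        assert p[2] == pytest.approx(0.5, abs=1e-12)

    def test_sums_to_one_and_nonnegative_everywhere(self):
        rng = np.random.default_rng(0)
        e1 = rng.uniform(-700, 700, 2000)
        e2 = rng.uniform(-700, 700, 2000)
        p1, p2, p3 = em.multinomial_probs(e1, e2)
        total = p1 + p2 + p3
        assert np.allclose(total, 1.0, atol=1e-12)
        assert (p1 >= 0).all() and (p2 >= 0).all() and (p3 >= 0).all()


def _tiny_design(y_codes, x=None):
    n = len(y_codes)
    y = np.zeros((n, 3), dtype=np.int8)
    y[np.arange(n), np.asarray(y_codes) - 1] = 1
    return DesignMatrices(
        X=np.ones((n, 1)) if x is None else x,
        B=np.zeros((n, 3)),
        Y=y,
        psu_index=np.zeros(n, dtype=int),
        region_index=np.zeros(n, dtype=int),
        psu_ids=np.array([1]),
        region_ids=np.array([1]),
        ages=np.zeros(n),
        knots=np.zeros(1),
    )


def _zero_state(p=1, m=3):
    return ParameterState.initial(m, 1, 1, p=p)


class TestLogLikelihood:
    def test_single_reference_respondent(self):
        d = _tiny_design([3])
        assert em.log_likelihood(_zero_state(), d) == pytest.approx(math.log(1 / 3))

    def test_additivity_under_duplication(self):
        d1 = _tiny_design([1, 2, 3, 1, 2])
        d2 = _tiny_design([1, 2, 3, 1, 2] * 2)
        state = _zero_state()
        state.beta[:] = [[0.4], [-0.2]]
        assert em.log_likelihood(state, d2) == pytest.approx(
            2 * em.log_likelihood(state, d1)
        )

    def test_matches_bruteforce_substitution(self):
        """Direct per-respondent evaluation of the link and likelihood."""
        rng = np.random.default_rng(1)
        n = 5
        x = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        y_codes = [1, 2, 3, 1, 2]
        d = _tiny_design(y_codes, x=x)
        state = _zero_state(p=2)
        state.beta[:] = [[0.3, -0.5], [-0.1, 0.8]]
        expected = 0.0
        for i in range(n):
            eta1 = x[i] @ state.beta[0]
            eta2 = x[i] @ state.beta[1]
            denom = 1 + math.exp(eta1) + math.exp(eta2)
            pis = [math.exp(eta1) / denom, math.exp(eta2) / denom, 1 / denom]
            expected += math.log(pis[y_codes[i] - 1])
        assert em.log_likelihood(state, d) == pytest.approx(expected)


class TestPolyaGamma:
    def test_moments_at_zero(self):
        x = polya_gamma(np.zeros(120_000), 99)
        assert x.mean() == pytest.approx(0.25, abs=0.003)
        assert x.var() == pytest.approx(1 / 24, rel=0.03)

    @pytest.mark.parametrize("z", [0.7, 2.0, 6.0, 25.0])
    def test_mean_tanh_identity(self, z):
        x = polya_gamma(np.full(60_000, z), 3)
        assert x.mean() == pytest.approx(math.tanh(z / 2) / (2 * z), rel=0.02)

    def test_seed_reproducible_and_sign_symmetric_in_law(self):
        a = polya_gamma(np.full(1000, 1.5), 5)
        b = polya_gamma(np.full(1000, 1.5), 5)
        assert np.array_equal(a, b)
        c = polya_gamma(np.full(60_000, -1.5), 8)
        assert c.mean() == pytest.approx(math.tanh(0.75) / 3.0, rel=0.02)


class TestMcmcStructure:
    def test_retained_draw_count(self, small_fit):
        _, _, _, fit = small_fit
        assert fit.n_draws == (800 - 200) // 4
        assert fit.chains["beta"].shape == (1, 150, 2, 8)

    def test_region_effects_sum_to_zero_every_draw(self, small_fit):
        _, _, _, fit = small_fit
        sums = fit.pooled("s").sum(axis=2)
        assert np.abs(sums).max() < 1e-8

    def test_variances_positive(self, small_fit):
        _, _, _, fit = small_fit
        for name in ("tau2_age", "tau2_psu", "tau2_region"):
            assert (fit.pooled(name) > 0).all()

    def test_null_model_has_zero_region_effects(self, small_survey):
        df, gt = small_survey
        design = em.build_design(df, gt.labels)
        fit = em.mcmc_fit(design, graph=None,
                          settings=em.McmcSettings(200, 100, 2),
                          spatial=False, seed=5)
        assert fit.model == "null"
        assert np.abs(fit.pooled("s")).max() == 0.0

    def test_spatial_requires_graph(self, small_survey):
        df, gt = small_survey
        design = em.build_design(df, gt.labels)
        with pytest.raises(ValueError, match="graph"):
            em.mcmc_fit(design, graph=None, spatial=True,
                        settings=em.McmcSettings(20, 10, 1), seed=1)

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            em.McmcSettings(100, 100, 1)
        with pytest.raises(ValueError):
            em.McmcSettings(100, 20, 3)  # 80 not divisible by 3
        assert em.McmcSettings(120_000, 20_000, 100).n_retained == 1000


class TestComputeDic:
    def test_constant_chain_has_zero_pd(self):
        out = compute_dic([100.0, 100.0, 100.0], 100.0)
        assert out.p_d == 0.0
        assert out.dic == 100.0

    def test_pd_definition(self):
        out = compute_dic([10.0, 14.0], 9.0)
        assert out.dbar == 12.0
        assert out.p_d == 3.0
        assert out.dic == 15.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_dic([], 0.0)

    def test_deviance_consistency(self, small_fit):
        _, _, design, fit = small_fit
        state = ParameterState.initial(23, design.n_psu, design.n_regions)
        assert deviance(state, design) == pytest.approx(
            -2 * em.log_likelihood(state, design)
        )


class TestSummaries:
    def test_degenerate_chain_gives_unit_odds(self):
        draws = np.zeros(100)
        med = float(np.median(draws))
        assert math.exp(med) == 1.0
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert math.exp(lo) == math.exp(hi) == 1.0

    def test_type7_quantiles(self):
        x = np.arange(1, 101, dtype=float)
        assert float(np.median(x)) == 50.5
        lo, hi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_exp_commutes_with_interval(self, small_fit):
        _, _, _, fit = small_fit
        table = summarize_posterior(fit)
        beta_rows = table[table.parameter.str.startswith("beta")]
        assert np.allclose(beta_rows["odds_q2.5"], np.exp(beta_rows["q2.5"]))
        assert np.allclose(beta_rows["odds_q97.5"], np.exp(beta_rows["q97.5"]))
        assert (beta_rows["odds_q2.5"] <= beta_rows["odds_ratio"]).all()
        assert (beta_rows["odds_ratio"] <= beta_rows["odds_q97.5"]).all()

    def test_loglik_guarded_against_underflow(self):
        d = _tiny_design([1])
        assert np.isfinite(_loglik_eta(np.array([-800.0]), np.array([0.0]), d.Y))
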