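"""Data generator: determinism, moment convergence and layer ordering."""

import numpy as np
import pytest

from negctrl import (
    BinaryErrorSpec,
    ConfoundingStructure,
    StructuralParams,
    ValidationError,
    add_continuous_error,
    dichotomize_top_quantile,
    draw_latents,
    generate_outcome,
    misclassify,
    simulate_binary,
)

N_BIG = 1_000_000


class TestDrawLatents:
    def test_deterministic_given_seed(self, conf04):
        a = draw_latents(1000, conf04, seed=42)
        b = draw_latents(1000, conf04, seed=42)
        assert np.array_equal(a.U, b.U)
        assert np.array_equal(a.E_T, b.E_T)
        assert np.array_equal(a.C_T, b.C_T)
        c = draw_latents(1000, conf04, seed=43)
        assert not np.array_equal(a.U, c.U)

    def test_empirical_correlations_converge(self, conf04):
        """At n = 10^6 the empirical correlation matrix of (U, E_T, C_T)
        matches the configured structure, in particular corr(E_T, C_T)
        within 0.005 of 0.16."""
        ls = draw_latents(N_BIG, conf04, seed=7)
        corr = np.corrcoef([ls.U, ls.E_T, ls.C_T])
        assert corr[0, 1] == pytest.approx(0.4, abs=0.005)
        assert corr[0, 2] == pytest.approx(0.4, abs=0.005)
        assert corr[1, 2] == pytest.approx(0.16, abs=0.005)
        assert np.var(ls.E_T) == pytest.approx(1.0, abs=0.01)

    def test_independence_case(self):
        conf = ConfoundingStructure(rho_UE=0.0, rho_UC=0.0)
        n = 100_000
        ls = draw_latents(n, conf, seed=3)
        assert abs(np.corrcoef(ls.U, ls.E_T)[0, 1]) < 3 / np.sqrt(n)

    def test_rejects_tiny_n(self, conf04):
        with pytest.raises(ValidationError):
            draw_latents(1, conf04, seed=0)


class TestAddContinuousError:
    def test_zero_variance_is_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(add_continuous_error(x, 0.0, seed=0), x)

    def test_error_independent_and_icc_correct(self, conf04):
        """Unit error variance on a unit-variance true score gives an
        empirical ICC of 0.5, and the added error is uncorrelated with
        the true values."""
        ls = draw_latents(N_BIG, conf04, seed=11)
        obs = add_continuous_error(ls.E_T, 1.0, seed=12)
        v = obs - ls.E_T
        icc_hat = np.var(ls.E_T) / np.var(obs)
        assert icc_hat == pytest.approx(0.5, abs=0.005)
        assert abs(np.corrcoef(v, ls.E_T)[0, 1]) < 3 / np.sqrt(N_BIG)

    def test_rejects_negative_variance(self):
        with pytest.raises(ValidationError):
            add_continuous_error(np.zeros(5), -1.0, seed=0)


class TestDichotomize:
    def test_small_example(self):
        assert np.array_equal(
            dichotomize_top_quantile(np.array([1.0, 2, 3, 4, 5]), 0.8),
            np.array([0.0, 0, 0, 0, 1]),
        )

    def test_top_twenty_percent_coded_one(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(100_000)
        b = dichotomize_top_quantile(x)
        assert b.mean() == pytest.approx(0.2, abs=0.005)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(5000)
        assert np.array_equal(
            dichotomize_top_quantile(x), dichotomize_top_quantile(np.exp(x))
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            dichotomize_top_quantile(np.ones(100))


class TestMisclassify:
    def test_zero_rate_is_identity(self):
        x = np.array([0.0, 1, 1, 0])
        assert np.array_equal(misclassify(x, 0.0, seed=0), x)

    def test_half_rate_destroys_association(self):
        rng = np.random.default_rng(8)
        x = (rng.random(N_BIG) < 0.2).astype(float)
        out = misclassify(x, 0.5, seed=9)
        assert abs(np.corrcoef(out, x)[0, 1]) < 0.005

    def test_marginal_mixture(self):
        """P(observed = 1) = P(true = 1)(1-p) + P(true = 0)p: with 20%
        prevalence and 10% flips, 0.26."""
        rng = np.random.default_rng(10)
        x = (rng.random(N_BIG) < 0.2).astype(float)
        out = misclassify(x, 0.1, seed=11)
        assert out.mean() == pytest.approx(0.26, abs=0.005)

    def test_symmetric_between_classes(self):
        rng = np.random.default_rng(12)
        x = (rng.random(N_BIG) < 0.2).astype(float)
        out = misclassify(x, 0.1, seed=13)
        flipped = out != x
        assert flipped[x == 1].mean() == pytest.approx(0.1, abs=0.005)
        assert flipped[x == 0].mean() == pytest.approx(0.1, abs=0.005)

    def test_rejects_nonbinary(self):
        with pytest.raises(ValidationError):
            misclassify(np.array([0.0, 2.0]), 0.1, seed=0)


class TestGenerateOutcome:
    def test_pure_noise_when_all_effects_zero(self, conf04):
        sp = StructuralParams(beta1=0.0, beta2=0.0, gamma=0.0)
        n = 100_000
        ls = draw_latents(n, conf04, seed=20)
        y = generate_outcome(ls, sp, ls.E_T, ls.C_T, seed=21)
        assert abs(np.corrcoef(y, ls.E_T)[0, 1]) < 3 / np.sqrt(n)

    def test_deterministic_limit(self, conf04):
        sp = StructuralParams(beta1=1.0, beta2=0.0, gamma=0.0, sigma_eps=1e-12)
        ls = draw_latents(100, conf04, seed=22)
        y = generate_outcome(ls, sp, ls.E_T, ls.C_T, seed=23)
        assert y == pytest.approx(ls.E_T, abs=1e-9)

    def test_oracle_regression_recovers_structure(self, conf04):
        """Regressing y on the true binary regressors plus the confounder
        (the correctly specified model) recovers (beta1, beta2, gamma)."""
        import statsmodels.api as sm

        sp = StructuralParams(beta1=0.2, beta2=0.0, gamma=0.2)
        n = 100_000
        ls = draw_latents(n, conf04, seed=24)
        Eb = dichotomize_top_quantile(ls.E_T)
        Cb = dichotomize_top_quantile(ls.C_T)
        y = generate_outcome(ls, sp, Eb, Cb, seed=25)
        X = sm.add_constant(np.column_stack([Eb, Cb, ls.U]))
        fit = sm.OLS(y, X).fit()
        for est, truth, se in zip(fit.params[1:], (0.2, 0.0, 0.2), fit.bse[1:]):
            assert abs(est - truth) < 3 * se

    def test_length_mismatch_rejected(self, conf04):
        ls = draw_latents(10, conf04, seed=0)
        sp = StructuralParams(beta1=0.0, beta2=0.0)
        with pytest.raises(ValidationError):
            generate_outcome(ls, sp, np.zeros(5), np.zeros(10), seed=0)


class TestSimulateBinary:
    def test_bit_reproducible(self, conf04, exposure_effect):
        err = BinaryErrorSpec(p_E=0.1, p_C=0.5)
        a = simulate_binary(500, exposure_effect, conf04, err, seed=30)
        b = simulate_binary(500, exposure_effect, conf04, err, seed=30)
        assert np.array_equal(a.E_O, b.E_O)
        assert np.array_equal(a.y, b.y)

    def test_outcome_unaffected_by_misclassification(self, conf04, exposure_effect):
        """Misclassification corrupts only the observed regressors; the
        outcome generated from the true binary values is identical whether
        or not flips are applied."""
        clean = simulate_binary(
            2000, exposure_effect, conf04, BinaryErrorSpec(p_E=0.0, p_C=0.0), seed=31
        )
        noisy = simulate_binary(
            2000, exposure_effect, conf04, BinaryErrorSpec(p_E=0.5, p_C=0.5), seed=31
        )
        assert np.array_equal(clean.y, noisy.y)
        assert not np.array_equal(clean.E_O, noisy.E_O)

    def test_observed_regressors_are_binary(self, conf04, null_effects):
        d = simulate_binary(1000, null_effects, conf04, BinaryErrorSpec(0.1, 0.1), seed=32)
        assert set(np.unique(d.E_O)) <= {0.0, 1.0}
        assert d.design == "binary"
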