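import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hurdleda import (
    CovariateRole,
    MetadataTable,
    ModelSpec,
    augment_prevalence,
    fit_abundance,
    fit_prevalence,
    flag_abundance_induced,
    median_comparison_test,
)
from hurdleda.design import INTERCEPT, build_design
from hurdleda.hurdle_models import FitResult

from oracles import reml_random_intercept, weighted_logistic_mle


def _md(df, roles=None):
    return MetadataTable(df, roles=roles or {})


class TestFitAbundance:
    def test_noiseless_ols_recovers_exact_slope(self):
        x = np.arange(10.0)
        md = _md(pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(10)]))
        y = pd.Series(1 + 2 * x, index=md.data.index)
        fit = fit_abundance(y, ModelSpec(fixed_terms=["x"]), md)
        assert fit.ok
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params[INTERCEPT] == pytest.approx(1.0, abs=1e-10)

    def test_constant_covariate_reports_rank_deficiency(self):
        md = _md(pd.DataFrame({"x": np.ones(10)}, index=[f"s{i}" for i in range(10)]))
        y = pd.Series(np.random.default_rng(0).normal(size=10), index=md.data.index)
        fit = fit_abundance(y, ModelSpec(fixed_terms=["x"]), md)
        assert fit.error is not None and "x" in fit.error

    def test_too_few_nonzero_observations_errors(self):
        md = _md(pd.DataFrame({"x": np.arange(4.0)}, index=[f"s{i}" for i in range(4)]))
        y = pd.Series([1.0, 2.0, np.nan, np.nan], index=md.data.index)
        fit = fit_abundance(y, ModelSpec(fixed_terms=["x"]), md)
        assert fit.error is not None and "too few" in fit.error

    def test_mixed_model_matches_reml_oracle(self):
        rng = np.random.default_rng(7)
        n, n_subj = 200, 10
        subj = np.repeat(np.arange(n_subj), n // n_subj)
        x = rng.normal(size=n)
        u = rng.normal(0, 1.0, size=n_subj)
        y_arr = 1.0 + 2.0 * x + u[subj] + rng.normal(0, 1.0, size=n)
        idx = [f"s{i}" for i in range(n)]
        md = _md(
            pd.DataFrame({"x": x, "subject": [f"p{s}" for s in subj]}, index=idx),
            roles={"x": CovariateRole("continuous"), "subject": CovariateRole("random_grouping")},
        )
        y = pd.Series(y_arr, index=idx)
        fit = fit_abundance(
            y, ModelSpec(fixed_terms=["x"], random_intercepts=["subject"]), md
        )
        assert fit.ok
        X = np.column_stack([np.ones(n), x])
        beta_o, se_o, sd_u, sd_e = reml_random_intercept(y_arr, X, subj)
        assert fit.params["x"] == pytest.approx(beta_o[1], abs=1e-3)
        assert fit.stderr["x"] == pytest.approx(se_o[1], rel=0.05)
        assert abs(fit.params["x"] - 2.0) < 3 * fit.stderr["x"]


class TestMedianComparison:
    def test_all_equal_coefficients_give_p_one(self):
        coefs = pd.Series([1.5] * 6, index=list("abcdef"))
        ses = pd.Series([0.1] * 6, index=list("abcdef"))
        res = median_comparison_test(coefs, ses)
        assert res.median == 1.5
        assert np.allclose(res.statistic.to_numpy(), 0.0)
        assert np.allclose(res.pval.to_numpy(), 1.0)

    def test_outlier_detected_against_monte_carlo_null(self):
        # features a-d share coef 0, feature e is far off with tiny SE
        coefs = pd.Series([0.0, 0.0, 0.0, 0.0, 5.0], index=list("abcde"))
        ses = pd.Series([0.01] * 5, index=list("abcde"))
        res = median_comparison_test(coefs, ses, seed=3)
        assert res.pval["e"] < 1e-6
        assert (res.pval[list("abcd")] > 0.5).all()
        # Monte-Carlo null: resample null coefficients, recompute the
        # median-offset statistic, and confirm |z_e| is extreme
        rng = np.random.default_rng(0)
        null_stats = []
        for _ in range(2000):
            b = rng.normal(0, 0.01, size=5)
            m = np.median(b)
            null_stats.append((b[4] - m) / np.sqrt(0.01**2 + res.var_median))
        assert abs(res.statistic["e"]) > np.quantile(np.abs(null_stats), 0.999)

    def test_zero_variance_median_reduces_to_plain_z_test(self):
        rng = np.random.default_rng(5)
        coefs = pd.Series(rng.normal(size=12))
        ses = pd.Series(rng.uniform(0.5, 1.5, size=12))
        res = median_comparison_test(coefs, ses, var_median=0.0)
        z_expected = (coefs - res.median) / ses
        p_expected = 2 * stats.norm.sf(np.abs(z_expected))
        assert np.allclose(res.statistic, z_expected)
        assert np.allclose(res.pval, p_expected)

    def test_subtracting_median_centers_reported_coefficients(self):
        rng = np.random.default_rng(6)
        coefs = pd.Series(rng.normal(2.0, 1.0, size=11))
        ses = pd.Series(np.full(11, 0.3))
        res = median_comparison_test(coefs, ses, subtract_median=True, seed=1)
        res2 = median_comparison_test(res.coef, ses, seed=1)
        assert res2.median == pytest.approx(0.0, abs=1e-12)


class TestAugmentation:
    def test_example_dimensions_and_weights(self):
        idx = [f"s{i}" for i in range(4)]
        B = pd.Series([1.0, 0.0, 1.0, 1.0], index=idx)
        X = pd.DataFrame(
            {INTERCEPT: np.ones(4), "a": [0, 1, 0, 1.0], "b": [1, 2, 3, 4.0]}, index=idx
        )
        aug = augment_prevalence(B, X)
        assert len(aug.response) == 12
        assert np.allclose(aug.weights[4:], 0.25)
        assert aug.weights[4:].sum() == pytest.approx(2.0)
        assert np.all(aug.response[4:8] == 1) and np.all(aug.response[8:] == 0)

    def test_single_sample_single_covariate(self):
        B = pd.Series([1.0], index=["s0"])
        X = pd.DataFrame({INTERCEPT: [1.0], "a": [2.0]}, index=["s0"])
        aug = augment_prevalence(B, X)
        assert len(aug.response) == 3
        assert np.allclose(aug.weights[1:], 0.5)

    def test_group_labels_replicated(self):
        idx = [f"s{i}" for i in range(3)]
        B = pd.Series([1.0, 0.0, 1.0], index=idx)
        X = pd.DataFrame({INTERCEPT: np.ones(3), "a": [0.0, 1.0, 2.0]}, index=idx)
        groups = pd.Series(["g1", "g2", "g1"], index=idx)
        aug = augment_prevalence(B, X, groups)
        n = 3
        for k in range(n):
            assert aug.grouping[n + k] == aug.grouping[k]
            assert aug.grouping[2 * n + k] == aug.grouping[k]


class TestFitPrevalence:
    def test_null_balanced_covariate_gives_flat_fit(self):
        # presence rate identical in both covariate groups -> coef ~ 0
        idx = [f"s{i}" for i in range(40)]
        x = np.array([0.0, 1.0] * 20)
        B = pd.Series(np.tile([1.0, 1.0, 0.0, 0.0], 10), index=idx)
        md = _md(pd.DataFrame({"x": x}, index=idx))
        fit = fit_prevalence(B, ModelSpec(fixed_terms=["x"]), md)
        assert fit.ok
        assert abs(fit.params["x"]) < 0.2
        assert fit.pvals["x"] > 0.5

    def test_separation_unaugmented_errors_augmented_finite(self):
        idx = [f"s{i}" for i in range(10)]
        x = np.linspace(-2, 2, 10)
        B = pd.Series((x > 0).astype(float), index=idx)
        md = _md(pd.DataFrame({"x": x}, index=idx))
        unaug = fit_prevalence(B, ModelSpec(fixed_terms=["x"], augment=False), md)
        assert unaug.error is not None
        aug = fit_prevalence(B, ModelSpec(fixed_terms=["x"]), md)
        assert aug.ok and np.isfinite(aug.params["x"])
        # oracle: the exact weighted-likelihood maximizer is finite and matches
        Xd = np.column_stack([np.ones(30), np.tile(x, 3)])
        ya = np.concatenate([B.to_numpy(), np.ones(10), np.zeros(10)])
        w = np.concatenate([np.ones(10), np.full(20, 1 / 20)])
        beta_o = weighted_logistic_mle(ya, Xd, w, x0=aug.params.to_numpy())
        assert aug.params["x"] == pytest.approx(beta_o[1], abs=1e-4)

    def test_all_present_feature_estimable_with_augmentation(self):
        idx = [f"s{i}" for i in range(12)]
        B = pd.Series(np.ones(12), index=idx)
        md = _md(pd.DataFrame({"x": np.linspace(-1, 1, 12)}, index=idx))
        fit = fit_prevalence(B, ModelSpec(fixed_terms=["x"]), md)
        assert fit.ok and np.isfinite(fit.params[INTERCEPT])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_augmented_fit_matches_bruteforce_weighted_mle(self, seed):
        # oracle equivalence on tiny instances: <=12 samples, <=2 covariates
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 13)
        k = rng.integers(1, 3)
        idx = [f"s{i}" for i in range(n)]
        cols = {f"x{j}": rng.normal(size=n) for j in range(k)}
        md = _md(pd.DataFrame(cols, index=idx))
        B = pd.Series(rng.binomial(1, 0.5, size=n).astype(float), index=idx)
        fit = fit_prevalence(B, ModelSpec(fixed_terms=list(cols)), md)
        assert fit.ok
        Xd = np.column_stack([np.ones(n)] + [cols[f"x{j}"] for j in range(k)])
        Xa = np.vstack([Xd, Xd, Xd])
        ya = np.concatenate([B.to_numpy(), np.ones(n), np.zeros(n)])
        w = np.concatenate([np.ones(n), np.full(2 * n, k / (2 * n))])
        beta_o = weighted_logistic_mle(ya, Xa, w, x0=fit.params.to_numpy())
        assert np.allclose(fit.params.to_numpy(), beta_o, atol=1e-4)

    def test_augmented_estimate_converges_to_mle_at_large_n(self):
        rng = np.random.default_rng(11)
        n = 5000
        idx = [f"s{i}" for i in range(n)]
        x = rng.normal(size=n)
        B = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-(0.2 + 0.8 * x)))).astype(float), index=idx)
        md = _md(pd.DataFrame({"x": x}, index=idx))
        aug = fit_prevalence(B, ModelSpec(fixed_terms=["x"]), md)
        plain = fit_prevalence(B, ModelSpec(fixed_terms=["x"], augment=False), md)
        assert abs(aug.params["x"] - plain.params["x"]) < 0.01


class TestFlagAbundanceInduced:
    def _fits(self, b_ab, b_prev):
        prev = FitResult(
            model="logistic",
            params=pd.Series({"x": b_prev}),
            stderr=pd.Series({"x": 0.1}),
            pvals=pd.Series({"x": 0.001}),
            converged=True,
        )
        ab = FitResult(
            model="linear",
            params=pd.Series({"x": b_ab}),
            stderr=pd.Series({"x": 0.1}),
            pvals=pd.Series({"x": 0.001}),
            converged=True,
        )
        return prev, ab

    def test_all_three_conditions_flag(self):
        prev, ab = self._fits(2.0, 1.0)
        flags = flag_abundance_induced(prev, ab, pd.Series({"x": 0.05}), 0.1)
        assert flags["x"]

    def test_opposite_signs_not_flagged(self):
        prev, ab = self._fits(2.0, -1.0)
        assert not flag_abundance_induced(prev, ab, pd.Series({"x": 0.05}), 0.1)["x"]

    def test_insignificant_abundance_not_flagged(self):
        prev, ab = self._fits(2.0, 1.0)
        assert not flag_abundance_induced(prev, ab, pd.Series({"x": 0.5}), 0.1)["x"]

    def test_zero_prevalence_coefficient_never_flagged(self):
        prev, ab = self._fits(2.0, 0.0)
        assert not flag_abundance_induced(prev, ab, pd.Series({"x": 0.05}), 0.1)["x"]

    def test_errored_fit_never_flagged(self):
        prev, ab = self._fits(2.0, 1.0)
        ab.error, ab.converged = "boom", False
        flags = flag_abundance_induced(prev, ab, pd.Series({"x": 0.05}), 0.1)
        assert not flags.any()
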