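import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hurdleda import (
    ContrastSpec,
    CovariateRole,
    MetadataTable,
    ModelSpec,
    contrast_test,
    fit_abundance,
    fit_prevalence,
    omnibus_test,
    ordered_contrasts,
    read_contrasts,
)


def _group_md(n_per_group, levels=("a", "b", "c"), rng=None, reference="a"):
    labels = np.repeat(list(levels), n_per_group)
    idx = [f"s{i}" for i in range(len(labels))]
    md = MetadataTable(
        pd.DataFrame({"grp": labels}, index=idx),
        roles={"grp": CovariateRole("group", reference=reference, levels=list(levels))},
    )
    return md, idx


class TestOmnibus:
    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 400
        md, idx = _group_md(100)
        spec = ModelSpec(fixed_terms=["grp"], median_comparison=False)
        for _ in range(n_sims):
            y = pd.Series(rng.normal(size=300), index=idx)
            fit = fit_abundance(y, spec, md)
            res = omnibus_test(fit, ["grp:b", "grp:c"])
            rejections += res.pval < 0.05
        # binomial(400, 0.05): 3 sd band around 20
        assert 7 <= rejections <= 34

    def test_shifted_group_strongly_rejected(self):
        rng = np.random.default_rng(1)
        md, idx = _group_md(100)
        y = pd.Series(rng.normal(size=300), index=idx)
        y.iloc[200:] += 5.0
        fit = fit_abundance(y, ModelSpec(fixed_terms=["grp"], median_comparison=False), md)
        assert omnibus_test(fit, ["grp:b", "grp:c"]).pval < 1e-6

    def test_two_levels_reduces_to_squared_t(self):
        rng = np.random.default_rng(2)
        md, idx = _group_md(50, levels=("a", "b"))
        y = pd.Series(rng.normal(size=100) + 0.4 * (md.data["grp"] == "b"), index=idx)
        fit = fit_abundance(y, ModelSpec(fixed_terms=["grp"], median_comparison=False), md)
        res = omnibus_test(fit, ["grp:b"])
        t = fit.params["grp:b"] / fit.stderr["grp:b"]
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.pval == pytest.approx(fit.pvals["grp:b"], rel=1e-10)

    def test_invariant_to_reference_level(self):
        rng = np.random.default_rng(3)
        y_vals = rng.normal(size=300)
        pvals = []
        for ref in ("a", "b", "c"):
            md, idx = _group_md(100, reference=ref)
            y = pd.Series(y_vals, index=idx)
            fit = fit_abundance(y, ModelSpec(fixed_terms=["grp"], median_comparison=False), md)
            cols = [c for c in fit.params.index if c.startswith("grp:")]
            pvals.append(omnibus_test(fit, cols).pval)
        assert np.allclose(pvals, pvals[0], rtol=1e-8)

    def test_logistic_lrt_agrees_with_f_at_large_n(self):
        rng = np.random.default_rng(4)
        md, idx = _group_md(500)
        spec = ModelSpec(fixed_terms=["grp"], median_comparison=False)
        B = pd.Series(rng.binomial(1, 0.35, size=1500).astype(float), index=idx)
        pfit = fit_prevalence(B, spec, md)
        y = pd.Series(rng.normal(size=1500), index=idx)
        afit = fit_abundance(y, spec, md)
        p_lrt = omnibus_test(pfit, ["grp:b", "grp:c"]).pval
        p_f = omnibus_test(afit, ["grp:b", "grp:c"]).pval
        # both are null tests on independent nulls; just check validity range
        assert 0 <= p_lrt <= 1 and 0 <= p_f <= 1

    def test_lrt_and_f_asymptotically_equal_on_same_linear_fit(self):
        # nested linear models: compare F-test p with the LRT chi2 p computed
        # from the same fits at large n
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        md, idx = _group_md(1500)
        y = pd.Series(rng.normal(size=4500) + 0.08 * (md.data["grp"] == "b"), index=idx)
        fit = fit_abundance(y, ModelSpec(fixed_terms=["grp"], median_comparison=False), md)
        p_f = omnibus_test(fit, ["grp:b", "grp:c"]).pval
        X_full = pd.get_dummies(md.data["grp"], drop_first=True).astype(float)
        X_full.insert(0, "const", 1.0)
        full = sm.OLS(y.to_numpy(), X_full.to_numpy()).fit()
        red = sm.OLS(y.to_numpy(), np.ones((4500, 1))).fit()
        lr = 2 * (full.llf - red.llf)
        p_lrt = stats.chi2.sf(lr, 2)
        assert abs(p_lrt - p_f) < 0.01


class TestOrderedContrasts:
    def _ordered_md(self, n, rng, levels=4):
        names = [f"lev{j+1}" for j in range(levels)]
        labels = rng.choice(names, size=n)
        idx = [f"s{i}" for i in range(n)]
        md = MetadataTable(
            pd.DataFrame({"stage": labels}, index=idx),
            roles={"stage": CovariateRole("ordered", levels=names)},
        )
        return md, idx, names

    def test_step_pattern_recovered(self):
        # step effects (0, 2, 0): only the lev2->lev3 step is real
        rng = np.random.default_rng(6)
        md, idx, names = self._ordered_md(500, rng)
        rank = md.data["stage"].map({n: i for i, n in enumerate(names)})
        y = pd.Series(rng.normal(size=500) + 2.0 * (rank >= 2), index=idx)
        fit = fit_abundance(y, ModelSpec(fixed_terms=["stage"], median_comparison=False), md)
        res = ordered_contrasts(fit, ["stage:lev2", "stage:lev3", "stage:lev4"])
        pvals = {r.name: r.pval for r in res}
        assert pvals["stage:lev3"] < 1e-10
        assert pvals["stage:lev2"] > 0.01 and pvals["stage:lev4"] > 0.01

    def test_step_estimates_sum_to_total_effect(self):
        rng = np.random.default_rng(7)
        md, idx, names = self._ordered_md(800, rng)
        rank = md.data["stage"].map({n: i for i, n in enumerate(names)})
        y = pd.Series(0.5 * rank + rng.normal(size=800), index=idx)
        fit = fit_abundance(y, ModelSpec(fixed_terms=["stage"], median_comparison=False), md)
        steps = [fit.params[f"stage:{n}"] for n in names[1:]]
        # total (last - first) effect equals the sum of consecutive steps
        top = md.data["stage"] == names[-1]
        bottom = md.data["stage"] == names[0]
        total = y[top.to_numpy()].mean() - y[bottom.to_numpy()].mean()
        assert sum(steps) == pytest.approx(total, abs=1e-8)

    def test_median_rhs_absorbs_shared_steps(self):
        # identical step effects across features: with the median step as
        # right-hand side no feature deviates
        rng = np.random.default_rng(8)
        md, idx, names = self._ordered_md(300, rng)
        rank = md.data["stage"].map({n: i for i, n in enumerate(names)})
        step_cols = [f"stage:{n}" for n in names[1:]]
        estimates = []
        fits = []
        for _ in range(7):
            y = pd.Series(1.5 * (rank >= 1) + rng.normal(size=300), index=idx)
            fit = fit_abundance(y, ModelSpec(fixed_terms=["stage"], median_comparison=False), md)
            fits.append(fit)
            estimates.append([fit.params[c] for c in step_cols])
        medians = np.median(np.array(estimates), axis=0)
        for fit in fits:
            res = ordered_contrasts(fit, step_cols, rhs=medians)
            assert all(r.pval > 1e-4 for r in res)

    def test_two_level_ordered_equals_binary_wald(self):
        rng = np.random.default_rng(9)
        names = ["lo", "hi"]
        labels = rng.choice(names, size=200)
        idx = [f"s{i}" for i in range(200)]
        md = MetadataTable(
            pd.DataFrame({"stage": labels}, index=idx),
            roles={"stage": CovariateRole("ordered", levels=names)},
        )
        y = pd.Series(rng.normal(size=200) + (labels == "hi"), index=idx)
        fit = fit_abundance(y, ModelSpec(fixed_terms=["stage"], median_comparison=False), md)
        (res,) = ordered_contrasts(fit, ["stage:hi"])
        assert res.estimate == pytest.approx(fit.params["stage:hi"])
        assert res.pval == pytest.approx(fit.pvals["stage:hi"], rel=1e-10)


class TestContrastTest:
    def _fit(self, rng, n=400, delta=0.0):
        labels = np.repeat(["a", "b"], n // 2)
        idx = [f"s{i}" for i in range(n)]
        md = MetadataTable(
            pd.DataFrame({"grp": labels, "x": rng.normal(size=n)}, index=idx),
            roles={
                "grp": CovariateRole("categorical", reference="a", levels=["a", "b"]),
                "x": CovariateRole("continuous"),
            },
        )
        y = pd.Series(rng.normal(size=n) + delta * (labels == "b"), index=idx)
        return fit_abundance(y, ModelSpec(fixed_terms=["grp", "x"], median_comparison=False), md)

    def test_unit_vector_reproduces_wald_test(self):
        fit = self._fit(np.random.default_rng(10))
        spec = ContrastSpec(matrix=pd.DataFrame({"grp:b": [1.0], "x": [0.0]}, index=["c1"]))
        (res,) = contrast_test(fit, spec)
        assert res.estimate == pytest.approx(fit.params["grp:b"])
        assert res.stderr == pytest.approx(fit.stderr["grp:b"])
        assert res.pval == pytest.approx(fit.pvals["grp:b"], rel=1e-10)

    def test_difference_of_identical_coefficients_is_null(self):
        rng = np.random.default_rng(11)
        n = 600
        idx = [f"s{i}" for i in range(n)]
        x1 = rng.normal(size=n)
        md = MetadataTable(pd.DataFrame({"x1": x1, "x2": rng.normal(size=n)}, index=idx))
        y = pd.Series(2.0 * md.data["x1"] + 2.0 * md.data["x2"] + rng.normal(size=n), index=idx)
        fit = fit_abundance(y, ModelSpec(fixed_terms=["x1", "x2"], median_comparison=False), md)
        spec = ContrastSpec(matrix=pd.DataFrame({"x1": [1.0], "x2": [-1.0]}, index=["diff"]))
        (res,) = contrast_test(fit, spec)
        assert abs(res.estimate) < 3 * res.stderr

    def test_group_difference_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(12)
        fit = self._fit(rng, n=400, delta=3.0)
        spec = ContrastSpec(matrix=pd.DataFrame({"grp:b": [1.0], "x": [0.0]}, index=["c"]))
        (res,) = contrast_test(fit, spec)
        assert abs(res.estimate - 3.0) < 3 * res.stderr
        # closed-form OLS oracle for the group coefficient SE: sigma^2 (X'X)^-1
        assert res.stderr == pytest.approx(np.sqrt(fit.cov_params.loc["grp:b", "grp:b"]))

    def test_missing_coefficient_named_in_error(self):
        fit = self._fit(np.random.default_rng(13))
        spec = ContrastSpec(matrix=pd.DataFrame({"nope": [1.0]}, index=["c"]))
        with pytest.raises(KeyError, match="nope"):
            contrast_test(fit, spec)

    def test_contrast_file_round_trip(self, tmp_path):
        path = tmp_path / "contrasts.tsv"
        path.write_text("name\tgrp:b\tx\trhs\nc1\t1\t-1\t0.5\n")
        spec = read_contrasts(path)
        assert list(spec.matrix.columns) == ["grp:b", "x"]
        assert spec.rhs["c1"] == 0.5
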