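"""Per-feature hurdle fitting.

Abundance half: linear (optionally mixed) models on log2 non-zero
abundances, with an across-feature median-comparison test that corrects
relative-abundance coefficients for compositionality.  Prevalence half:
weighted logistic (optionally mixed) models on presence/absence, fit on a
data-augmented design that guards against complete separation, with a
heuristic flag for prevalence effects likely induced by abundance shifts
crossing the detection limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .design import INTERCEPT, DesignInfo, build_design, collinear_columns
from .glmm import fit_logistic_mixed
from .io_formats import MetadataTable

logger = logging.getLogger("hurdleda")

#: coefficients larger than this in log-odds are treated as diverging
_SEPARATION_BOUND = 50.0


@dataclass
class ModelSpec:
    """The fitting recipe shared by both model halves.

    ``fixed_terms`` are covariate names (or ``a:b`` interactions);
    ``random_intercepts`` lists random-grouping covariates; the median
    comparison only applies on the relative scale and is forced off for
    spike-in / total-load runs.
    """

    fixed_terms: list[str]
    random_intercepts: list[str] = field(default_factory=list)
    feature_specific_covariate: Optional[str] = None
    median_comparison: bool = True
    subtract_median: bool = False
    augment: bool = True
    flag_abundance_induced: bool = True
    scale_mode: Literal["relative", "spike_in", "total_load"] = "relative"

    def __post_init__(self) -> None:
        if self.scale_mode != "relative" and self.median_comparison:
            logger.info(
                "median comparison disabled: absolute-scale run (%s)", self.scale_mode
            )
            self.median_comparison = False
        if self.feature_specific_covariate in self.fixed_terms:
            raise ValueError("feature-specific covariate must not appear in fixed_terms")


@dataclass
class FitResult:
    """One fitted model half for one feature."""

    model: Literal["linear", "linear_mixed", "logistic", "logistic_mixed"]
    params: Optional[pd.Series] = None
    stderr: Optional[pd.Series] = None
    pvals: Optional[pd.Series] = None
    cov_params: Optional[pd.DataFrame] = None
    df_resid: Optional[float] = None  # None => normal-approximation Wald tests
    loglik: Optional[float] = None
    converged: bool = False
    n_obs: int = 0
    error: Optional[str] = None
    context: Optional[dict] = None  # fitting context enabling refits (LRT)

    @property
    def ok(self) -> bool:
        return self.error is None and self.converged


@dataclass
class AugmentedDesign:
    """The 3n-row augmented presence/absence regression problem.

    Rows 1..n are the observed responses with weight 1; rows n+1..2n are a
    copy of the design with response 1 and rows 2n+1..3n a copy with
    response 0, each weighted g/(2n) so the total augmented weight equals g
    pseudo-samples.
    """

    response: np.ndarray
    design: pd.DataFrame
    weights: np.ndarray
    grouping: Optional[np.ndarray] = None


def _wald_pvals(params: np.ndarray, bse: np.ndarray, df_resid: Optional[float]) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse
    if df_resid is not None:
        return 2 * stats.t.sf(np.abs(z), df_resid)
    return 2 * stats.norm.sf(np.abs(z))


def _complete_cases(
    pieces: list[pd.Series | pd.DataFrame | None],
) -> pd.Index:
    mask = None
    for piece in pieces:
        if piece is None:
            continue
        ok = piece.notna()
        if isinstance(ok, pd.DataFrame):
            ok = ok.all(axis=1)
        mask = ok if mask is None else (mask & ok)
    return mask[mask].index


def _assemble_design(
    design: DesignInfo, fc_column: Optional[pd.Series], fc_name: str
) -> pd.DataFrame:
    X = design.matrix
    if fc_column is not None:
        X = X.copy()
        X[fc_name] = fc_column
    return X


def fit_abundance(
    y: pd.Series,
    spec: ModelSpec,
    md: MetadataTable,
    fc_column: Optional[pd.Series] = None,
    design: Optional[DesignInfo] = None,
) -> FitResult:
    """Fit the abundance model for one feature.

    ``y`` holds log2 non-zero abundances indexed by sample, NaN where the
    feature is absent (those samples never enter this half).  OLS when no
    random intercepts are requested; a random-intercept linear mixed model
    otherwise.  Wald tests use the t distribution (residual df) for OLS and
    a normal approximation for mixed fits.
    """
    import statsmodels.api as sm

    if design is None:
        design = build_design(md, spec.fixed_terms)
    fc_name = spec.feature_specific_covariate or "feature_covariate"
    X_full = _assemble_design(design, fc_column, fc_name)
    groups = None
    if spec.random_intercepts:
        if len(spec.random_intercepts) > 1:
            return FitResult(model="linear_mixed", error="only one random-intercept grouping supported")
        groups = md.data[spec.random_intercepts[0]]

    rows = _complete_cases([y, X_full, groups])
    model_kind = "linear_mixed" if groups is not None else "linear"
    Xc = X_full.loc[rows]
    yc = y.loc[rows].astype(float)
    p = Xc.shape[1]
    if len(rows) < p + 2:
        return FitResult(
            model=model_kind,
            n_obs=len(rows),
            error=f"too few non-zero observations ({len(rows)}) for {p} parameters",
        )
    Xa = Xc.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xa) < p:
        bad = collinear_columns(Xa, list(Xc.columns))
        return FitResult(
            model=model_kind,
            n_obs=len(rows),
            error="rank-deficient design; collinear terms: " + ", ".join(bad),
        )
    names = list(Xc.columns)
    try:
        if groups is None:
            res = sm.OLS(yc.to_numpy(), Xa).fit()
            params = pd.Series(res.params, index=names)
            bse = pd.Series(res.bse, index=names)
            df_resid = float(res.df_resid)
            pvals = pd.Series(_wald_pvals(params.to_numpy(), bse.to_numpy(), df_resid), index=names)
            cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
            return FitResult(
                model="linear",
                params=params,
                stderr=bse,
                pvals=pvals,
                cov_params=cov,
                df_resid=df_resid,
                loglik=float(res.llf),
                converged=True,
                n_obs=len(rows),
                context={"y": yc, "X": Xc, "groups": None, "kind": "linear"},
            )
        gc = groups.loc[rows]
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM(yc.to_numpy(), Xa, groups=gc.to_numpy())
            try:
                res = mod.fit(reml=True, maxiter=200)
            except np.linalg.LinAlgError:
                res = mod.fit(reml=True, method="lbfgs", maxiter=200)
        if not np.all(np.isfinite(np.asarray(res.bse)[:p])):
            return FitResult(model="linear_mixed", n_obs=len(rows), error="mixed fit did not converge")
        params = pd.Series(np.asarray(res.params)[:p], index=names)
        bse = pd.Series(np.asarray(res.bse)[:p], index=names)
        pvals = pd.Series(_wald_pvals(params.to_numpy(), bse.to_numpy(), None), index=names)
        cov = pd.DataFrame(np.asarray(res.cov_params())[:p, :p], index=names, columns=names)
        return FitResult(
            model="linear_mixed",
            params=params,
            stderr=bse,
            pvals=pvals,
            cov_params=cov,
            df_resid=None,
            loglik=float(res.llf),
            converged=bool(res.converged),
            n_obs=len(rows),
            context={"y": yc, "X": Xc, "groups": gc, "kind": "linear_mixed"},
        )
    except (np.linalg.LinAlgError, ValueError) as exc:
        return FitResult(model=model_kind, n_obs=len(rows), error=f"fit failed: {exc}")


def augment_prevalence(
    B: pd.Series, X: pd.DataFrame, groups: Optional[pd.Series] = None
) -> AugmentedDesign:
    """Stack the observed rows with one all-present and one all-absent copy.

    With g fixed-effect covariates (non-intercept design columns), each of
    the 2n augmented rows gets weight g/(2n), so augmentation adds exactly
    g pseudo-samples of prior information — enough to keep every
    coefficient finite even under complete separation.
    """
    n = len(B)
    g = sum(1 for c in X.columns if c != INTERCEPT)
    if n < 1 or g < 1:
        raise ValueError("augmentation requires n >= 1 and g >= 1")
    response = np.concatenate([B.to_numpy(dtype=float), np.ones(n), np.zeros(n)])
    design = pd.concat([X, X, X], axis=0, ignore_index=True)
    weights = np.concatenate([np.ones(n), np.full(2 * n, g / (2 * n))])
    grouping = None
    if groups is not None:
        ga = groups.to_numpy()
        grouping = np.concatenate([ga, ga, ga])
    return AugmentedDesign(response=response, design=design, weights=weights, grouping=grouping)


def _fit_weighted_logistic(
    y: np.ndarray, X: np.ndarray, weights: Optional[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    import statsmodels.api as sm

    glm = sm.GLM(
        y,
        X,
        family=sm.families.Binomial(),
        freq_weights=None if weights is None else weights,
    )
    res = glm.fit(maxiter=200, tol=1e-10)
    return (
        np.asarray(res.params),
        np.asarray(res.bse),
        np.asarray(res.cov_params()),
        float(res.llf),
        bool(res.converged),
    )


def fit_prevalence(
    B: pd.Series,
    spec: ModelSpec,
    md: MetadataTable,
    fc_column: Optional[pd.Series] = None,
    design: Optional[DesignInfo] = None,
) -> FitResult:
    """Fit the prevalence model for one feature.

    ``B`` is the 0/1 presence vector (NaN cells are excluded observations).
    With ``spec.augment`` (default) the weighted logistic model is fit on
    the augmented design; without it, complete separation is reported as an
    error flagged "separable".
    """
    if design is None:
        design = build_design(md, spec.fixed_terms)
    fc_name = spec.feature_specific_covariate or "feature_covariate"
    X_full = _assemble_design(design, fc_column, fc_name)
    groups = None
    if spec.random_intercepts:
        if len(spec.random_intercepts) > 1:
            return FitResult(model="logistic_mixed", error="only one random-intercept grouping supported")
        groups = md.data[spec.random_intercepts[0]]

    rows = _complete_cases([B, X_full, groups])
    model_kind = "logistic_mixed" if groups is not None else "logistic"
    Xc = X_full.loc[rows]
    Bc = B.loc[rows].astype(float)
    names = list(Xc.columns)
    p = len(names)
    if len(rows) < 2:
        return FitResult(model=model_kind, n_obs=len(rows), error="too few observations")
    Xa = Xc.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xa) < p:
        bad = collinear_columns(Xa, names)
        return FitResult(
            model=model_kind,
            n_obs=len(rows),
            error="rank-deficient design; collinear terms: " + ", ".join(bad),
        )

    if spec.augment:
        aug = augment_prevalence(Bc, Xc, groups.loc[rows] if groups is not None else None)
        y_fit = aug.response
        X_fit = aug.design.to_numpy(dtype=float)
        w_fit = aug.weights
        g_fit = aug.grouping
    else:
        y_fit = Bc.to_numpy()
        X_fit = Xa
        w_fit = None
        g_fit = groups.loc[rows].to_numpy() if groups is not None else None

    try:
        if groups is None:
            params, bse, cov, llf, converged = _fit_weighted_logistic(y_fit, X_fit, w_fit)
            sigma = None
        else:
            mixed = fit_logistic_mixed(y_fit, X_fit, g_fit, weights=w_fit)
            params, bse, cov = mixed.params, mixed.bse, mixed.cov_params
            llf, converged, sigma = mixed.loglik, mixed.converged, mixed.sigma
    except Exception as exc:  # statsmodels raises several types on separation
        if not spec.augment:
            return FitResult(model=model_kind, n_obs=len(rows), error=f"separable: {exc}")
        return FitResult(model=model_kind, n_obs=len(rows), error=f"fit failed: {exc}")

    diverged = (not np.all(np.isfinite(params))) or np.max(np.abs(params)) > _SEPARATION_BOUND
    if diverged or not converged:
        msg = "separable: coefficients diverged" if diverged else "did not converge"
        if not spec.augment:
            return FitResult(model=model_kind, n_obs=len(rows), error=msg)
        if diverged:
            return FitResult(model=model_kind, n_obs=len(rows), error=msg)
    params_s = pd.Series(params, index=names)
    bse_s = pd.Series(bse, index=names)
    pvals = pd.Series(_wald_pvals(params, bse, None), index=names)
    return FitResult(
        model=model_kind,
        params=params_s,
        stderr=bse_s,
        pvals=pvals,
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        df_resid=None,
        loglik=llf,
        converged=True,
        n_obs=len(rows),
        context={
            "y": y_fit,
            "X": pd.DataFrame(X_fit, columns=names),
            "weights": w_fit,
            "groups": g_fit,
            "kind": model_kind,
            "sigma": sigma,
        },
    )


@dataclass
class MedianTestResult:
    median: float
    var_median: float
    statistic: pd.Series
    pval: pd.Series
    coef: pd.Series  # reported coefficients (median-subtracted if requested)


def median_variance_bootstrap(
    coefs: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> float:
    """Nonparametric bootstrap estimate of Var(median of the coefficients):
    resample the coefficient vector with replacement and take the variance
    of the bootstrap medians."""
    rng = np.random.default_rng(seed)
    m = coefs.size
    idx = rng.integers(0, m, size=(n_boot, m))
    meds = np.median(coefs[idx], axis=1)
    return float(np.var(meds, ddof=1))


def median_comparison_test(
    coefs: pd.Series,
    stderrs: pd.Series,
    subtract_median: bool = False,
    var_median: Optional[float] = None,
    df: Optional[pd.Series] = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MedianTestResult:
    """Test each feature's coefficient against the across-feature median.

    On the relative scale a common compositional shift moves every
    coefficient equally; if fewer than half the features truly change on
    the absolute scale, the median of the per-feature coefficients locates
    that shift, and testing each coefficient against the median recovers a
    test of the absolute-scale effect.  The statistic is

        z_i = (b_i - M) / sqrt(SE_i^2 + V_M)

    where M is the median coefficient and V_M its estimated variance
    (bootstrap over features; closed-form pi/(2m) * median(SE^2) fallback
    for m < 10).  The reference distribution is t with the feature's
    residual df when ``df`` is supplied (sparse features leave few non-zero
    observations, where a normal reference would be anti-conservative),
    normal otherwise.
    """
    finite = coefs.notna() & stderrs.notna() & np.isfinite(coefs) & np.isfinite(stderrs)
    cf = coefs[finite]
    se = stderrs[finite]
    m = len(cf)
    if m < 3:
        logger.warning(
            "median comparison: only %d finite coefficients; testing against zero", m
        )
        med, vm = 0.0, 0.0
    else:
        med = float(np.median(cf.to_numpy()))
        if var_median is not None:
            vm = var_median
        elif m < 10:
            vm = float(np.pi / (2 * m) * np.median(se.to_numpy() ** 2))
        else:
            vm = median_variance_bootstrap(cf.to_numpy(), n_boot=n_boot, seed=seed)
    denom = np.sqrt(se.to_numpy() ** 2 + vm)
    z = (cf.to_numpy() - med) / denom
    if df is not None:
        dfv = df[finite.index][finite].to_numpy(dtype=float)
        dfv = np.where(np.isfinite(dfv), dfv, np.inf)
        pv = 2 * stats.t.sf(np.abs(z), dfv)
    else:
        pv = 2 * stats.norm.sf(np.abs(z))
    stat = pd.Series(np.nan, index=coefs.index)
    pval = pd.Series(np.nan, index=coefs.index)
    stat[finite] = z
    pval[finite] = pv
    out_coef = coefs.copy()
    if subtract_median:
        out_coef[finite] = cf - med
    return MedianTestResult(median=med, var_median=vm, statistic=stat, pval=pval, coef=out_coef)


def flag_abundance_induced(
    prev: FitResult,
    abund_vs_zero: FitResult,
    qvals_abund_zero: pd.Series,
    fdr_threshold: float = 0.1,
) -> pd.Series:
    """Flag prevalence terms whose association is likely induced by an
    abundance shift crossing the detection limit.

    A term is flagged when (1) the abundance coefficient (tested against
    zero, not the median) has q <= threshold, (2) the abundance and
    prevalence coefficients agree in sign, and (3) the abundance
    coefficient has the larger magnitude.
    """
    if not prev.ok or not abund_vs_zero.ok:
        idx = prev.params.index if prev.ok else qvals_abund_zero.index
        return pd.Series(False, index=idx)
    flags = {}
    for term in prev.params.index:
        ba = abund_vs_zero.params.get(term, np.nan)
        bp = prev.params[term]
        q = qvals_abund_zero.get(term, np.nan)
        same_sign = np.sign(ba) == np.sign(bp) and np.sign(bp) != 0
        flags[term] = bool(
            np.isfinite(q)
            and q <= fdr_threshold
            and np.isfinite(ba)
            and same_sign
            and abs(ba) > abs(bp)
        )
    return pd.Series(flags)


def refit_loglik(fit: FitResult, drop_columns: list[str]) -> Optional[float]:
    """Log-likelihood of the model refit without ``drop_columns`` (for
    likelihood-ratio omnibus tests); None if the refit fails."""
    if fit.context is None:
        return None
    ctx = fit.context
    X = ctx["X"].drop(columns=drop_columns)
    kind = ctx["kind"]
    try:
        if kind == "logistic":
            _, _, _, llf, conv = _fit_weighted_logistic(
                np.asarray(ctx["y"], dtype=float), X.to_numpy(dtype=float), ctx.get("weights")
            )
            return llf if conv else None
        if kind == "logistic_mixed":
            mixed = fit_logistic_mixed(
                np.asarray(ctx["y"], dtype=float),
                X.to_numpy(dtype=float),
                ctx["groups"],
                weights=ctx.get("weights"),
            )
            return mixed.loglik if mixed.converged else None
        if kind == "linear":
            import statsmodels.api as sm

            res = sm.OLS(np.asarray(ctx["y"], dtype=float), X.to_numpy(dtype=float)).fit()
            return float(res.llf)
        if kind == "linear_mixed":
            import statsmodels.api as sm

            res = sm.MixedLM(
                np.asarray(ctx["y"], dtype=float),
                X.to_numpy(dtype=float),
                groups=np.asarray(ctx["groups"]),
            ).fit(reml=False, maxiter=200)
            return float(res.llf)
    except Exception:
        return None
    return None
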