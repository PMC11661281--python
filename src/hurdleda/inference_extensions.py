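"""Omnibus, ordered-level, and general contrast tests on fitted models.

All tests operate on a converged :class:`~hurdleda.hurdle_models.FitResult`
with its full coefficient covariance.  Linear models use F tests (residual
df when available); logistic models use likelihood-ratio tests for the
omnibus and normal-approximation Wald tests for contrasts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hurdle_models import FitResult, refit_loglik


@dataclass
class ContrastSpec:
    """User-specified linear combinations of coefficients.

    ``matrix`` is rows-of-weights over named coefficients; each row is
    tested against its ``rhs`` constant (default 0).
    """

    matrix: pd.DataFrame  # rows: contrast names, columns: coefficient names
    rhs: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.rhs is None:
            self.rhs = pd.Series(0.0, index=self.matrix.index)
        if not (self.matrix != 0).any(axis=1).all():
            raise ValueError("every contrast row needs at least one nonzero weight")


@dataclass
class TestResult:
    name: str
    estimate: Optional[float]
    stderr: Optional[float]
    statistic: float
    pval: float


def omnibus_test(fit: FitResult, term_group: Sequence[str]) -> TestResult:
    """ANOVA-style test that all level coefficients of a covariate are zero.

    Linear (and linear mixed) fits use an F test of joint nullity; logistic
    fits use a likelihood-ratio test against the refit model with the term
    removed.  No median comparison is applied to omnibus p-values.
    """
    if not fit.ok:
        raise ValueError(f"omnibus test on a failed fit: {fit.error}")
    terms = list(term_group)
    missing = [t for t in terms if t not in fit.params.index]
    if missing:
        raise KeyError(f"terms not in fit: {missing}")
    q = len(terms)
    if fit.model in ("linear", "linear_mixed"):
        beta = fit.params[terms].to_numpy()
        cov = fit.cov_params.loc[terms, terms].to_numpy()
        stat = float(beta @ np.linalg.solve(cov, beta)) / q
        if fit.df_resid is not None:
            pval = float(stats.f.sf(stat, q, fit.df_resid))
        else:
            # mixed fits: normal-approximation chi2 on q df, reported on F scale
            pval = float(stats.chi2.sf(stat * q, q))
        return TestResult("omnibus", None, None, stat, pval)
    ll_reduced = refit_loglik(fit, terms)
    if ll_reduced is None or fit.loglik is None:
        raise RuntimeError("likelihood-ratio refit failed")
    lr = max(0.0, 2 * (fit.loglik - ll_reduced))
    pval = float(stats.chi2.sf(lr, q))
    return TestResult("omnibus", None, None, lr, pval)


def contrast_test(fit: FitResult, spec: ContrastSpec) -> list[TestResult]:
    """Wald tests of c' beta = rhs for each contrast row."""
    if not fit.ok:
        raise ValueError(f"contrast test on a failed fit: {fit.error}")
    missing = [c for c in spec.matrix.columns if c not in fit.params.index]
    if missing:
        raise KeyError(f"contrast references missing coefficients: {missing}")
    out = []
    cov = fit.cov_params.loc[spec.matrix.columns, spec.matrix.columns].to_numpy()
    beta = fit.params[spec.matrix.columns].to_numpy()
    for name, row in spec.matrix.iterrows():
        c = row.to_numpy(dtype=float)
        est = float(c @ beta - spec.rhs[name])
        se = float(np.sqrt(c @ cov @ c))
        z = est / se if se > 0 else np.inf * np.sign(est)
        if fit.df_resid is not None:
            pval = float(2 * stats.t.sf(abs(z), fit.df_resid))
        else:
            pval = float(2 * stats.norm.sf(abs(z)))
        out.append(TestResult(str(name), est, se, z, pval))
    return out


def ordered_contrasts(
    fit: FitResult,
    step_columns: Sequence[str],
    rhs: Optional[Sequence[float]] = None,
) -> list[TestResult]:
    """Consecutive-level tests for a thermometer-coded ordered covariate.

    With thermometer coding each step coefficient directly measures the
    change between consecutive levels, so each test is a single-coefficient
    contrast against its ``rhs`` (zero, or the across-feature median step
    difference when correcting for compositionality — supply the medians
    via ``rhs``).
    """
    cols = list(step_columns)
    rhs_vec = pd.Series(0.0 if rhs is None else list(rhs), index=cols, dtype=float)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    return contrast_test(fit, ContrastSpec(matrix=mat, rhs=rhs_vec))


def read_contrasts(path: os.PathLike | str) -> ContrastSpec:
    """Read a contrast matrix: TSV with a row-label column, one weight
    column per coefficient, and an optional ``rhs`` column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    rhs = None
    if "rhs" in df.columns:
        rhs = df["rhs"].astype(float)
        df = df.drop(columns=["rhs"])
    return ContrastSpec(matrix=df.astype(float), rhs=rhs)
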