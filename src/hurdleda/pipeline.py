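"""End-to-end workflow: normalize -> filter -> split -> fit -> combine -> FDR.

This is the library entry point the CLI wraps.  Given an abundance table,
role-tagged metadata and a :class:`~hurdleda.hurdle_models.ModelSpec`, it
returns one :class:`~hurdleda.io_formats.AssociationRecord` per (feature,
term, model half), with individual, joint and FDR-adjusted significance.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .design import build_design
from .hurdle_models import (
    FitResult,
    ModelSpec,
    fit_abundance,
    fit_prevalence,
    median_comparison_test,
)
from .inference_extensions import ContrastSpec, contrast_test, omnibus_test
from .io_formats import AssociationRecord, FeatureTable, MetadataTable, align_tables
from .preprocessing import (
    AbsoluteScalingInfo,
    drop_empty_samples,
    filter_features,
    normalize_spikein,
    normalize_total,
    normalize_tss,
    split_hurdle,
)
from .results import adjust_fdr, combine_pvalues

logger = logging.getLogger("hurdleda")


def prepare_tables(
    ft: FeatureTable,
    md: MetadataTable,
    spec: ModelSpec,
    fc: Optional[FeatureTable] = None,
    scaling_info: Optional[AbsoluteScalingInfo] = None,
    normalization: str = "TSS",
    min_prevalence: float = 0.0,
    min_abundance: float = 0.0,
):
    """Normalize, scale, filter and split; returns (hurdle, md, fc)."""
    ft, md, fc = align_tables(ft, md, fc)
    ft = drop_empty_samples(ft)
    if len(ft.data) < len(md.data):
        md = MetadataTable(md.data.loc[ft.data.index], roles=dict(md.roles))
    if normalization == "TSS" and ft.scale != "relative":
        ft = normalize_tss(ft)
    if spec.scale_mode == "spike_in":
        if scaling_info is None:
            raise ValueError("spike_in scale mode requires scaling_info")
        ft = normalize_spikein(ft, scaling_info)
    elif spec.scale_mode == "total_load":
        if scaling_info is None:
            raise ValueError("total_load scale mode requires scaling_info")
        ft = normalize_total(ft, scaling_info)
    ft = filter_features(ft, min_prevalence=min_prevalence, min_abundance=min_abundance)
    hd = split_hurdle(ft)
    return hd, md, fc


def run_analysis(
    ft: FeatureTable,
    md: MetadataTable,
    spec: ModelSpec,
    fc: Optional[FeatureTable] = None,
    scaling_info: Optional[AbsoluteScalingInfo] = None,
    contrasts: Optional[ContrastSpec] = None,
    normalization: str = "TSS",
    min_prevalence: float = 0.0,
    min_abundance: float = 0.0,
    fdr_threshold: float = 0.1,
    seed: int = 0,
) -> list[AssociationRecord]:
    """Fit the full hurdle analysis and return association records.

    ``seed`` controls the bootstrap used to estimate the variance of the
    coefficient median in the compositionality correction.
    """
    hd, md, fc = prepare_tables(
        ft,
        md,
        spec,
        fc=fc,
        scaling_info=scaling_info,
        normalization=normalization,
        min_prevalence=min_prevalence,
        min_abundance=min_abundance,
    )
    design = build_design(md, spec.fixed_terms)
    features = list(hd.presence.columns)

    ab_fits: dict[str, FitResult] = {}
    pr_fits: dict[str, FitResult] = {}
    for feat in features:
        fc_col = fc.data[feat] if fc is not None else None
        ab_fits[feat] = fit_abundance(
            hd.log_abundance[feat], spec, md, fc_column=fc_col, design=design
        )
        pr_fits[feat] = fit_prevalence(
            hd.presence[feat], spec, md, fc_column=fc_col, design=design
        )

    term_cols = [t.column for t in design.terms]

    def series_over_features(fits, attr, col):
        vals = {}
        for feat, fit in fits.items():
            if fit.ok and col in getattr(fit, attr).index:
                vals[feat] = getattr(fit, attr)[col]
            else:
                vals[feat] = np.nan
        return pd.Series(vals)

    fc_term = spec.feature_specific_covariate
    all_terms = term_cols + ([fc_term] if fc_term else [])

    # per-term abundance statistics across features
    ab_coef: dict[str, pd.Series] = {}
    ab_se: dict[str, pd.Series] = {}
    ab_p_zero: dict[str, pd.Series] = {}
    ab_p_report: dict[str, pd.Series] = {}
    for col in all_terms:
        fit_col = col if col in term_cols else (fc_term or "feature_covariate")
        coefs = series_over_features(ab_fits, "params", fit_col)
        ses = series_over_features(ab_fits, "stderr", fit_col)
        pz = series_over_features(ab_fits, "pvals", fit_col)
        ab_coef[col], ab_se[col], ab_p_zero[col] = coefs, ses, pz
        if spec.median_comparison:
            dfs = pd.Series(
                {
                    feat: (fit.df_resid if fit.ok and fit.df_resid is not None else np.nan)
                    for feat, fit in ab_fits.items()
                }
            )
            mres = median_comparison_test(
                coefs, ses, subtract_median=spec.subtract_median, df=dfs, seed=seed
            )
            ab_p_report[col] = mres.pval
            ab_coef[col] = mres.coef
        else:
            ab_p_report[col] = pz

    # pooled q-values of the zero-tested abundance coefficients (flagging pool)
    pz_stack = pd.concat(ab_p_zero, names=["term", "feature"])
    qz_stack = adjust_fdr(pz_stack)

    records: list[AssociationRecord] = []
    for feat in features:
        afit, pfit = ab_fits[feat], pr_fits[feat]
        n_nonzero = int(hd.presence[feat].sum(skipna=True))
        for col in all_terms:
            if col in term_cols:
                tinfo = design.term_for(col)
                meta, value = tinfo.metadata, tinfo.value
                fit_col = col
            else:
                meta = value = fc_term
                fit_col = fc_term or "feature_covariate"
            pa = float(ab_p_report[col][feat]) if np.isfinite(ab_p_report[col][feat]) else None
            pp = (
                float(pfit.pvals[fit_col])
                if pfit.ok and fit_col in pfit.pvals.index and np.isfinite(pfit.pvals[fit_col])
                else None
            )
            p_joint = combine_pvalues(pa, pp)

            flag = False
            if spec.flag_abundance_induced and pfit.ok and afit.ok:
                q_zero = qz_stack.get((col, feat), np.nan)
                ba = afit.params.get(fit_col, np.nan)
                bp = pfit.params.get(fit_col, np.nan)
                flag = bool(
                    np.isfinite(q_zero)
                    and q_zero <= fdr_threshold
                    and np.isfinite(ba)
                    and np.isfinite(bp)
                    and np.sign(ba) == np.sign(bp)
                    and np.sign(bp) != 0
                    and abs(ba) > abs(bp)
                )

            records.append(
                AssociationRecord(
                    feature=feat,
                    metadata=meta,
                    value=value,
                    model="abundance",
                    coef=float(ab_coef[col][feat]) if np.isfinite(ab_coef[col][feat]) else None,
                    stderr=float(ab_se[col][feat]) if np.isfinite(ab_se[col][feat]) else None,
                    pval_individual=pa,
                    pval_joint=p_joint if afit.error is None else None,
                    n_obs=afit.n_obs,
                    n_nonzero=n_nonzero,
                    error=afit.error,
                )
            )
            records.append(
                AssociationRecord(
                    feature=feat,
                    metadata=meta,
                    value=value,
                    model="prevalence",
                    coef=float(pfit.params[fit_col]) if pp is not None else None,
                    stderr=float(pfit.stderr[fit_col]) if pp is not None else None,
                    pval_individual=pp,
                    pval_joint=p_joint if pfit.error is None else None,
                    n_obs=pfit.n_obs,
                    n_nonzero=n_nonzero,
                    error=pfit.error,
                    flag_abundance_induced=flag,
                )
            )

        # omnibus tests for multi-level group covariates
        for cov, cols in design.omnibus_groups.items():
            for model_name, fit in (("abundance", afit), ("prevalence", pfit)):
                if not fit.ok:
                    records.append(
                        AssociationRecord(
                            feature=feat,
                            metadata=cov,
                            value="omnibus",
                            model=model_name,
                            n_obs=fit.n_obs,
                            n_nonzero=n_nonzero,
                            error=fit.error or "fit unavailable",
                        )
                    )
                    continue
                try:
                    res = omnibus_test(fit, cols)
                    pv = res.pval
                    err = None
                except Exception as exc:
                    pv, err = None, f"omnibus failed: {exc}"
                records.append(
                    AssociationRecord(
                        feature=feat,
                        metadata=cov,
                        value="omnibus",
                        model=model_name,
                        pval_individual=pv,
                        n_obs=fit.n_obs,
                        n_nonzero=n_nonzero,
                        error=err,
                    )
                )
        # user contrasts
        if contrasts is not None:
            for model_name, fit in (("abundance", afit), ("prevalence", pfit)):
                if not fit.ok:
                    continue
                try:
                    for res in contrast_test(fit, contrasts):
                        records.append(
                            AssociationRecord(
                                feature=feat,
                                metadata=res.name,
                                value="contrast",
                                model=model_name,
                                coef=res.estimate,
                                stderr=res.stderr,
                                pval_individual=res.pval,
                                n_obs=fit.n_obs,
                                n_nonzero=n_nonzero,
                            )
                        )
                except KeyError as exc:
                    raise
                except Exception as exc:
                    logger.warning("contrast failed for %s (%s): %s", feat, model_name, exc)

    _attach_joint_omnibus(records)
    _apply_fdr(records)
    return records


def _attach_joint_omnibus(records: list[AssociationRecord]) -> None:
    """Combine abundance/prevalence omnibus and contrast p-values into joint
    p-values (regular terms already carry theirs)."""
    by_key: dict[tuple, dict[str, AssociationRecord]] = {}
    for r in records:
        if r.value in ("omnibus", "contrast"):
            by_key.setdefault((r.feature, r.metadata, r.value), {})[r.model] = r
    for pair in by_key.values():
        pa = pair.get("abundance")
        pp = pair.get("prevalence")
        joint = combine_pvalues(
            pa.pval_individual if pa else None, pp.pval_individual if pp else None
        )
        for r in pair.values():
            if r.error is None:
                r.pval_joint = joint


def _apply_fdr(records: list[AssociationRecord]) -> None:
    """Three BH pools: abundance p-values, prevalence p-values, and one
    joint pool over unique (feature, term) pairs."""
    for model_name in ("abundance", "prevalence"):
        subset = [r for r in records if r.model == model_name]
        p = pd.Series([r.pval_individual for r in subset], dtype=float)
        q = adjust_fdr(p)
        for r, qv in zip(subset, q):
            r.qval_individual = float(qv) if np.isfinite(qv) else None

    joint_keys: dict[tuple, float] = {}
    for r in records:
        if r.pval_joint is not None:
            joint_keys.setdefault((r.feature, r.metadata, r.value), r.pval_joint)
    keys = list(joint_keys)
    q = adjust_fdr(pd.Series([joint_keys[k] for k in keys], dtype=float))
    qmap = {k: (float(v) if np.isfinite(v) else None) for k, v in zip(keys, q)}
    for r in records:
        if r.pval_joint is not None:
            r.qval_joint = qmap.get((r.feature, r.metadata, r.value))
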