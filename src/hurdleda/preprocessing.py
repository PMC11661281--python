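"""Normalization, filtering, and the hurdle split.

The hurdle decomposition routes zeros to a presence/absence mask and keeps
log2-transformed values only where a feature was observed, so no
pseudo-count is ever added on the model path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .io_formats import FeatureTable, TableFormatError

logger = logging.getLogger("hurdleda")


@dataclass
class HurdleData:
    """The two views of an abundance table.

    ``presence`` is a 0/1 samples-by-features frame; ``log_abundance`` holds
    log2(normalized abundance) where present and NaN where absent (the NaN
    encodes "undefined", not a numeric value).
    """

    presence: pd.DataFrame
    log_abundance: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        defined = self.log_abundance.notna().to_numpy()
        present = self.presence.to_numpy().astype(bool)
        if not np.array_equal(defined, present):
            raise ValueError("log_abundance must be defined exactly where presence=1")
        vals = self.log_abundance.to_numpy()
        if not np.all(np.isfinite(vals[present])):
            raise ValueError("log_abundance must be finite where defined")


@dataclass
class AbsoluteScalingInfo:
    """Per-sample anchor for absolute-abundance normalization.

    ``spike_in`` mode carries the known absolute abundance of a reference
    feature in each sample; ``total_load`` mode carries an estimate of each
    sample's total absolute abundance.
    """

    mode: Literal["spike_in", "total_load"]
    reference_abs: pd.Series
    reference_feature: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode == "spike_in" and self.reference_feature is None:
            raise ValueError("spike_in mode requires a reference feature id")
        if (self.reference_abs <= 0).any():
            raise ValueError("reference abundances must be positive")


def normalize_tss(ft: FeatureTable) -> FeatureTable:
    """Total-sum scaling: divide each sample by its total, giving relative
    abundances."""
    values = ft.values()
    sums = values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise TableFormatError(
            "cannot TSS-normalize all-zero samples: "
            + ", ".join(map(str, ft.data.index[zero][:5]))
        )
    out = ft.data.div(sums, axis=0)
    return FeatureTable(out, scale="relative")


def normalize_spikein(rel: FeatureTable, info: AbsoluteScalingInfo) -> FeatureTable:
    """Anchor relative abundances to the absolute scale via a spike-in.

    With reference absolute abundance ``A_ref,k`` and relative abundance
    ``P_ref,k`` in sample k, each feature's absolute abundance is estimated
    as ``A_ik = A_ref,k * P_ik / P_ref,k``.  The reference feature is
    removed from the output: it carries no biological signal and would
    always produce a flat self-referential fit.
    """
    if rel.scale != "relative":
        raise ValueError("spike-in normalization expects a relative-scale table")
    if info.mode != "spike_in":
        raise ValueError("AbsoluteScalingInfo must have mode='spike_in'")
    ref = info.reference_feature
    if ref not in rel.data.columns:
        raise TableFormatError(f"spike-in reference feature {ref!r} not in table")
    p_ref = rel.data[ref]
    undetected = p_ref <= 0
    if undetected.any():
        raise TableFormatError(
            "spike-in not detected in samples: "
            + ", ".join(map(str, rel.data.index[undetected][:5]))
        )
    a_ref = info.reference_abs.reindex(rel.data.index)
    if a_ref.isna().any():
        raise TableFormatError("spike-in absolute abundance missing for some samples")
    scaling = a_ref / p_ref
    out = rel.data.drop(columns=[ref]).mul(scaling, axis=0)
    return FeatureTable(out, scale="absolute")


def normalize_total(rel: FeatureTable, info: AbsoluteScalingInfo) -> FeatureTable:
    """Scale relative abundances by per-sample total-load estimates:
    ``A_ik = P_ik * T_k``."""
    if rel.scale != "relative":
        raise ValueError("total-load normalization expects a relative-scale table")
    if info.mode != "total_load":
        raise ValueError("AbsoluteScalingInfo must have mode='total_load'")
    totals = info.reference_abs.reindex(rel.data.index)
    if totals.isna().any() or (totals <= 0).any():
        raise TableFormatError("total-load estimates must be positive for every sample")
    out = rel.data.mul(totals, axis=0)
    return FeatureTable(out, scale="absolute")


def filter_features(
    ft: FeatureTable,
    min_prevalence: float = 0.0,
    min_abundance: float = 0.0,
    require_nonidentical: bool = True,
    min_variance: Optional[float] = None,
) -> FeatureTable:
    """Drop features that cannot support an abundance regression.

    The default rule retains a feature iff it is non-zero in at least two
    samples and its non-zero values are not all identical.  Optional
    thresholds additionally require the fraction of samples with value
    >= ``min_abundance`` (counting only non-zero values) to reach
    ``min_prevalence``, and (off by default) the variance of the non-zero
    values to reach ``min_variance``.
    """
    values = ft.values()
    n = values.shape[0]
    keep = []
    for j, feat in enumerate(ft.feature_ids):
        col = values[:, j]
        nz = col[col > 0]
        if require_nonidentical:
            if nz.size < 2 or np.all(nz == nz[0]):
                continue
        if min_prevalence > 0 or min_abundance > 0:
            passing = np.count_nonzero(nz >= max(min_abundance, np.finfo(float).tiny))
            if passing / n < min_prevalence:
                continue
        if min_variance is not None and nz.size >= 2 and np.var(nz, ddof=1) < min_variance:
            continue
        keep.append(feat)
    if not keep:
        raise TableFormatError("no features survive filtering")
    dropped = ft.n_features - len(keep)
    if dropped:
        logger.info("filter_features: dropped %d of %d features", dropped, ft.n_features)
    return FeatureTable._unchecked(ft.data[keep], scale=ft.scale)


def drop_empty_samples(ft: FeatureTable) -> FeatureTable:
    """Drop samples whose total abundance is zero (e.g. after feature
    filtering), with a logged warning."""
    sums = ft.values().sum(axis=1)
    empty = sums <= 0
    if empty.any():
        logger.warning(
            "dropping %d all-zero samples: %s",
            int(empty.sum()),
            ", ".join(map(str, ft.data.index[empty][:5])),
        )
        return FeatureTable._unchecked(ft.data.loc[~empty], scale=ft.scale)
    return ft


def split_hurdle(ft: FeatureTable) -> HurdleData:
    """Split an abundance table into presence/absence and log2 non-zero
    abundance views."""
    if ft.scale == "counts":
        raise ValueError("normalize before splitting (scale must be relative or absolute)")
    values = ft.values()
    present = values > 0
    log_ab = np.where(present, np.log2(np.where(present, values, 1.0)), np.nan)
    return HurdleData(
        presence=pd.DataFrame(
            present.astype(int), index=ft.data.index, columns=ft.data.columns
        ),
        log_abundance=pd.DataFrame(log_ab, index=ft.data.index, columns=ft.data.columns),
        scale=ft.scale,
    )


def preprocess_mtx(
    rna: FeatureTable, dna: FeatureTable
) -> tuple[HurdleData, pd.DataFrame]:
    """Pair RNA abundances with per-feature DNA covariates for
    metatranscriptomics.

    Per (sample, feature) cell: if DNA > 0 the RNA value is kept and the
    covariate is log2(DNA); if DNA = 0 but RNA > 0 the covariate is the
    log2 of half the dataset-wide minimum non-zero DNA relative abundance;
    if both are 0 the observation is excluded (treated as missing in both
    views, not as an observed absence).
    """
    if rna.scale != "relative" or dna.scale != "relative":
        raise ValueError("preprocess_mtx expects relative-scale RNA and DNA tables")
    if list(rna.data.index) != list(dna.data.index) or list(rna.data.columns) != list(
        dna.data.columns
    ):
        raise ValueError("RNA and DNA tables must be aligned on samples and features")
    rna_v = rna.values()
    dna_v = dna.values()
    nz = dna_v[dna_v > 0]
    if nz.size == 0:
        raise TableFormatError("DNA table has no non-zero entries")
    fill = np.log2(nz.min() / 2.0)

    both_zero = (dna_v == 0) & (rna_v == 0)
    covariate = np.where(dna_v > 0, np.log2(np.where(dna_v > 0, dna_v, 1.0)), fill)
    covariate = np.where(both_zero, np.nan, covariate)

    present = (rna_v > 0) & ~both_zero
    log_ab = np.where(present, np.log2(np.where(present, rna_v, 1.0)), np.nan)
    presence = np.where(both_zero, np.nan, present.astype(float))

    idx, cols = rna.data.index, rna.data.columns
    hd = HurdleData.__new__(HurdleData)  # bypass strict check: NaN presence = excluded
    hd.presence = pd.DataFrame(presence, index=idx, columns=cols)
    hd.log_abundance = pd.DataFrame(log_ab, index=idx, columns=cols)
    hd.scale = "relative"
    return hd, pd.DataFrame(covariate, index=idx, columns=cols)
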