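"""Tabular interchange formats: feature tables, metadata tables, result tables.

All on-disk formats are tab-separated UTF-8 text with a header row and a
first column of row identifiers.  Feature tables are numeric throughout
(missing values are an error there); metadata cells may be missing
(``NA``/``NaN``/empty all parse as missing).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hurdleda")

Scale = Literal["counts", "relative", "absolute"]

#: column order of the results schema
RESULT_COLUMNS = [
    "feature",
    "metadata",
    "value",
    "model",
    "coef",
    "stderr",
    "pval_individual",
    "qval_individual",
    "pval_joint",
    "qval_joint",
    "n_obs",
    "n_nonzero",
    "error",
    "flag_abundance_induced",
]


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class FeatureTable:
    """A samples-by-features abundance matrix with a scale tag.

    Parameters
    ----------
    data:
        DataFrame with sample identifiers as the index and feature
        identifiers as columns; non-negative numeric values.
    scale:
        ``"counts"`` (raw reads), ``"relative"`` (rows sum to 1) or
        ``"absolute"`` (anchored abundances, e.g. from a spike-in).
    """

    data: pd.DataFrame
    scale: Scale

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            raise TableFormatError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise TableFormatError("duplicate feature identifiers")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise TableFormatError("feature table contains missing values")
        if (values < 0).any():
            raise TableFormatError("feature table contains negative values")
        if self.scale == "relative":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-8
            if bad.any():
                raise TableFormatError(
                    "relative-scale rows must sum to 1; offending samples: "
                    + ", ".join(map(str, self.data.index[bad][:5]))
                )

    @classmethod
    def _unchecked(cls, data: pd.DataFrame, scale: Scale) -> "FeatureTable":
        """Construct a subset view without re-validating row sums (feature
        filtering legitimately leaves relative rows summing below 1)."""
        obj = object.__new__(cls)
        obj.data = data
        obj.scale = scale
        return obj

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


#: covariate roles understood by the model layer
ROLE_KINDS = ("continuous", "categorical", "ordered", "group", "random_grouping")


@dataclass
class CovariateRole:
    """Role declaration for one metadata column.

    ``categorical`` columns carry a reference level; ``ordered`` columns a
    level sequence (fit with thermometer coding so each coefficient is a
    consecutive-level step); ``group`` columns are multi-level categoricals
    tested with an omnibus test; ``random_grouping`` columns only ever enter
    as random-intercept groups.
    """

    kind: str
    reference: Optional[str] = None
    levels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.kind not in ROLE_KINDS:
            raise ValueError(f"unknown covariate role: {self.kind!r}")


@dataclass
class MetadataTable:
    """A samples-by-covariates table with per-covariate role declarations."""

    data: pd.DataFrame
    roles: dict[str, CovariateRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise TableFormatError("duplicate sample identifiers in metadata")
        for name in self.data.columns:
            if name not in self.roles:
                self.roles[name] = infer_role(self.data[name])
        self.validate()

    def validate(self) -> None:
        for name, role in self.roles.items():
            if name not in self.data.columns:
                raise TableFormatError(f"role declared for unknown covariate {name!r}")
            if role.kind in ("categorical", "ordered", "group"):
                observed = set(self.data[name].dropna().astype(str))
                declared = set(role.levels or [])
                if role.kind == "categorical" and role.reference is not None:
                    declared.add(role.reference)
                if declared and not observed <= declared:
                    raise TableFormatError(
                        f"covariate {name!r}: observed levels {sorted(observed - declared)} "
                        "not among declared levels"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def fixed_effect_covariates(self) -> list[str]:
        return [c for c in self.data.columns if self.roles[c].kind != "random_grouping"]


def infer_role(column: pd.Series) -> CovariateRole:
    """Infer a default role: numeric columns are continuous, text columns
    categorical with the lexicographically first level as reference."""
    if pd.api.types.is_numeric_dtype(column):
        return CovariateRole("continuous")
    levels = sorted(column.dropna().astype(str).unique())
    return CovariateRole("categorical", reference=levels[0] if levels else None, levels=levels)


@dataclass
class AssociationRecord:
    """One (feature, covariate term, model half) association.

    ``coef`` is in log2 units for the abundance model and log-odds units for
    the prevalence model.  If ``error`` is set, every statistical field is
    absent (``None``).
    """

    feature: str
    metadata: str
    value: str
    model: Literal["abundance", "prevalence"]
    coef: Optional[float] = None
    stderr: Optional[float] = None
    pval_individual: Optional[float] = None
    qval_individual: Optional[float] = None
    pval_joint: Optional[float] = None
    qval_joint: Optional[float] = None
    n_obs: Optional[int] = None
    n_nonzero: Optional[int] = None
    error: Optional[str] = None
    flag_abundance_induced: bool = False

    @property
    def term(self) -> str:
        """Flat term label (covariate or covariate:level)."""
        return self.metadata if self.value == self.metadata else f"{self.metadata}:{self.value}"


def _read_tsv(path: os.PathLike | str) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise TableFormatError(f"{path}: duplicate column identifiers: {dupes[:5]}")
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)


def read_feature_table(
    path: os.PathLike | str,
    orientation: Literal["auto", "samples_rows", "features_rows"] = "auto",
    sample_ids: Optional[Iterable[str]] = None,
) -> FeatureTable:
    """Read a tab-separated abundance table and infer its scale.

    The scale is inferred as ``counts`` if every entry is an integer,
    ``relative`` if every row sums to 1 within 1e-6, else ``absolute``.
    ``orientation="auto"`` picks the layout whose row identifiers overlap
    ``sample_ids`` (typically the metadata's samples) more; ties and absent
    ``sample_ids`` default to samples-in-rows.
    """
    raw = _read_tsv(path)
    if raw.index.has_duplicates or raw.columns.has_duplicates:
        raise TableFormatError(f"{path}: duplicate row or column identifiers")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (raw == "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise TableFormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    numeric = numeric.astype(float)

    if orientation == "auto":
        if sample_ids is not None:
            ids = set(sample_ids)
            rows_hit = len(ids & set(numeric.index))
            cols_hit = len(ids & set(numeric.columns))
            orientation = "features_rows" if cols_hit > rows_hit else "samples_rows"
        else:
            orientation = "samples_rows"
    if orientation == "features_rows":
        numeric = numeric.T

    values = numeric.to_numpy()
    if np.allclose(values, np.round(values), atol=0, rtol=0) and np.array_equal(
        values, np.floor(values)
    ):
        scale: Scale = "counts"
    else:
        sums = values.sum(axis=1)
        scale = "relative" if np.all(np.abs(sums - 1.0) <= 1e-6) else "absolute"
    return FeatureTable(numeric, scale=scale)


def read_metadata_table(
    path: os.PathLike | str, roles: Optional[dict[str, CovariateRole]] = None
) -> MetadataTable:
    """Read a tab-separated metadata table; ``NA``/``NaN``/empty are missing."""
    raw = _read_tsv(path)
    parsed = {}
    for col in raw.columns:
        s = raw[col].replace({"NA": np.nan, "NaN": np.nan, "nan": np.nan, "": np.nan})
        numeric = pd.to_numeric(s, errors="coerce")
        parsed[col] = numeric if numeric.notna().equals(s.notna()) else s
    df = pd.DataFrame(parsed, index=raw.index)
    return MetadataTable(df, roles=dict(roles) if roles else {})


def align_tables(
    ft: FeatureTable,
    md: MetadataTable,
    fc: Optional[FeatureTable] = None,
) -> tuple[FeatureTable, MetadataTable, Optional[FeatureTable]]:
    """Restrict all tables to their shared samples, identically ordered.

    A warning is logged listing dropped samples.  The optional
    feature-specific covariate table ``fc`` must cover every feature of
    ``ft``.
    """
    shared = [s for s in ft.sample_ids if s in set(md.sample_ids)]
    if fc is not None:
        fc_samples = set(fc.sample_ids)
        shared = [s for s in shared if s in fc_samples]
    if len(shared) < 2:
        raise TableFormatError(
            f"only {len(shared)} samples shared between tables; at least 2 required"
        )
    dropped = (set(ft.sample_ids) | set(md.sample_ids)) - set(shared)
    if dropped:
        logger.warning(
            "align_tables: dropping %d samples absent from some table: %s",
            len(dropped),
            ", ".join(sorted(map(str, dropped))[:10]),
        )
    ft_out = FeatureTable._unchecked(ft.data.loc[shared], scale=ft.scale)
    md_out = MetadataTable(md.data.loc[shared], roles=dict(md.roles))
    fc_out = None
    if fc is not None:
        missing = [f for f in ft.feature_ids if f not in set(fc.feature_ids)]
        if missing:
            raise TableFormatError(
                f"feature-specific covariate table missing features: {missing[:5]}"
            )
        fc_out = FeatureTable(fc.data.loc[shared, ft.feature_ids], scale=fc.scale)
    return ft_out, md_out, fc_out


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Association records as a results-schema DataFrame, deterministically
    ordered by (feature, metadata, value, model)."""
    rows = []
    for r in records:
        rows.append(
            {
                "feature": r.feature,
                "metadata": r.metadata,
                "value": r.value,
                "model": r.model,
                "coef": r.coef,
                "stderr": r.stderr,
                "pval_individual": r.pval_individual,
                "qval_individual": r.qval_individual,
                "pval_joint": r.pval_joint,
                "qval_joint": r.qval_joint,
                "n_obs": r.n_obs,
                "n_nonzero": r.n_nonzero,
                "error": r.error,
                "flag_abundance_induced": r.flag_abundance_induced,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        df = df.sort_values(["feature", "metadata", "value", "model"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def frame_to_records(df: pd.DataFrame) -> list[AssociationRecord]:
    records = []
    for _, row in df.iterrows():
        kw = {}
        for col in RESULT_COLUMNS:
            v = row[col]
            if isinstance(v, float) and np.isnan(v):
                v = None
            kw[col] = v
        for col in ("n_obs", "n_nonzero"):
            if kw[col] is not None:
                kw[col] = int(kw[col])
        kw["flag_abundance_induced"] = bool(kw["flag_abundance_induced"])
        records.append(AssociationRecord(**kw))
    return records


def write_results(
    records: Sequence[AssociationRecord],
    out_dir: os.PathLike | str,
    q_threshold: float = 0.1,
    effect_threshold: float = 1.0,
    use_joint: bool = True,
) -> tuple[str, str]:
    """Write ``all_results.tsv`` and ``significant_results.tsv``.

    Absent values are encoded as ``NA``; floats are written at 10
    significant digits so write/read round-trips are stable.
    """
    from .results import significance_filter

    os.makedirs(out_dir, exist_ok=True)
    df = records_to_frame(records)
    all_path = os.path.join(out_dir, "all_results.tsv")
    sig_path = os.path.join(out_dir, "significant_results.tsv")
    df.to_csv(all_path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    sig = significance_filter(
        list(records),
        q_threshold=q_threshold,
        effect_threshold=effect_threshold,
        use_joint=use_joint,
    )
    records_to_frame(sig).to_csv(
        sig_path, sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )
    return all_path, sig_path


def read_results(path: os.PathLike | str) -> list[AssociationRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    df["flag_abundance_induced"] = df["flag_abundance_induced"].astype(bool)
    for col in ("feature", "metadata", "value", "model", "error"):
        if col in df:
            df[col] = df[col].where(df[col].notna(), None)
    return frame_to_records(df)
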