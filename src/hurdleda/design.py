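"""Fixed-effects design matrices from role-tagged metadata.

Categorical covariates are expanded to treatment (reference-level) dummies;
ordered covariates use thermometer (cumulative) coding, so that each
indicator's coefficient is the step between two consecutive levels;
``group`` covariates expand like categoricals but are additionally tracked
for omnibus testing.  Interactions (``a:b``) multiply the expanded columns
of their parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CovariateRole, MetadataTable

INTERCEPT = "(Intercept)"


@dataclass
class TermColumn:
    """Bookkeeping for one design column: which covariate and level (or the
    covariate itself, for continuous terms) it encodes."""

    column: str
    metadata: str
    value: str


@dataclass
class DesignInfo:
    """A fixed-effects design matrix plus term bookkeeping.

    ``matrix`` includes an intercept column; NaNs propagate from missing
    metadata cells and are dropped per-fit (complete-case analysis).
    """

    matrix: pd.DataFrame
    terms: list[TermColumn]
    omnibus_groups: dict[str, list[str]] = field(default_factory=dict)
    ordered_steps: dict[str, list[str]] = field(default_factory=dict)

    @property
    def term_columns(self) -> list[str]:
        return [t.column for t in self.terms]

    def term_for(self, column: str) -> TermColumn:
        for t in self.terms:
            if t.column == column:
                return t
        raise KeyError(column)


def _expand_covariate(
    md: MetadataTable, name: str
) -> tuple[pd.DataFrame, list[TermColumn], str]:
    """Expand one covariate into design columns; returns (columns, terms, kind)."""
    if name not in md.data.columns:
        raise KeyError(f"unknown covariate {name!r}")
    role = md.roles[name]
    col = md.data[name]
    if role.kind == "random_grouping":
        raise ValueError(f"random-grouping covariate {name!r} cannot be a fixed effect")
    if role.kind == "continuous":
        out = pd.DataFrame({name: pd.to_numeric(col)})
        return out, [TermColumn(name, name, name)], "continuous"

    values = col.astype("object").where(col.notna(), np.nan)
    str_vals = values.astype(str).where(col.notna(), np.nan)
    if role.kind in ("categorical", "group"):
        levels = role.levels or sorted(str_vals.dropna().unique())
        reference = role.reference or levels[0]
        others = [l for l in levels if l != reference]
        cols, terms = {}, []
        for level in others:
            cname = f"{name}:{level}"
            cols[cname] = (str_vals == level).astype(float).where(col.notna(), np.nan)
            terms.append(TermColumn(cname, name, level))
        return pd.DataFrame(cols, index=md.data.index), terms, role.kind
    if role.kind == "ordered":
        levels = role.levels
        if not levels:
            raise ValueError(f"ordered covariate {name!r} declares no level sequence")
        rank = str_vals.map({l: i for i, l in enumerate(levels)})
        cols, terms = {}, []
        for t in range(1, len(levels)):
            cname = f"{name}:{levels[t]}"
            cols[cname] = (rank >= t).astype(float).where(col.notna(), np.nan)
            terms.append(TermColumn(cname, name, levels[t]))
        return pd.DataFrame(cols, index=md.data.index), terms, "ordered"
    raise ValueError(f"unsupported role {role.kind!r}")


def build_design(md: MetadataTable, fixed_terms: list[str]) -> DesignInfo:
    """Build the n x (g+1) fixed-effects design matrix for the given terms.

    ``fixed_terms`` entries are covariate names or ``a:b`` interactions of
    two covariates.
    """
    pieces = [pd.DataFrame({INTERCEPT: np.ones(len(md.data))}, index=md.data.index)]
    terms: list[TermColumn] = []
    omnibus: dict[str, list[str]] = {}
    ordered: dict[str, list[str]] = {}
    expanded: dict[str, tuple[pd.DataFrame, list[TermColumn], str]] = {}

    def expand(name: str):
        if name not in expanded:
            expanded[name] = _expand_covariate(md, name)
        return expanded[name]

    for spec_term in fixed_terms:
        parts = [p.strip() for p in spec_term.replace("*", ":").split(":")]
        if len(parts) == 1:
            cols, tinfo, kind = expand(parts[0])
            pieces.append(cols)
            terms.extend(tinfo)
            if kind == "group":
                omnibus[parts[0]] = [t.column for t in tinfo]
            if kind == "ordered":
                ordered[parts[0]] = [t.column for t in tinfo]
        elif len(parts) == 2:
            cols_a, terms_a, _ = expand(parts[0])
            cols_b, terms_b, _ = expand(parts[1])
            inter = {}
            for ta in terms_a:
                for tb in terms_b:
                    cname = f"{ta.column}*{tb.column}"
                    inter[cname] = cols_a[ta.column] * cols_b[tb.column]
                    terms.append(
                        TermColumn(
                            cname,
                            f"{ta.metadata}:{tb.metadata}",
                            f"{ta.value}:{tb.value}",
                        )
                    )
            pieces.append(pd.DataFrame(inter, index=md.data.index))
        else:
            raise ValueError(f"only two-way interactions supported: {spec_term!r}")

    matrix = pd.concat(pieces, axis=1)
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate design columns (covariate listed twice?)")
    return DesignInfo(matrix=matrix, terms=terms, omnibus_groups=omnibus, ordered_steps=ordered)


def collinear_columns(X: np.ndarray, names: list[str], tol: float = 1e-8) -> list[str]:
    """Identify columns past the numerical rank via pivoted QR."""
    from scipy.linalg import qr

    if X.shape[0] < X.shape[1]:
        return list(names)
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0:
        return list(names)
    rank = int(np.sum(diag > tol * diag[0]))
    return [names[i] for i in sorted(piv[rank:])]
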