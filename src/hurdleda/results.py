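"""Joint significance, FDR control, and the significance filter.

The two model halves test disjoint aspects of the data (presence, and
abundance given presence), so their p-values are independent under the
joint null; the minimum of two independent Unif(0,1) variables follows a
Beta(1,2) law, whose CDF turns the smaller p-value into a calibrated joint
p-value.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import AssociationRecord


def combine_pvalues(
    p_abund: Optional[float], p_prev: Optional[float]
) -> Optional[float]:
    """Joint p-value: Beta(1,2) CDF of the smaller of the two halves,
    ``2 p_min - p_min^2``; with one half absent, that half's p passes
    through unchanged."""
    pa = None if p_abund is None or (isinstance(p_abund, float) and np.isnan(p_abund)) else p_abund
    pp = None if p_prev is None or (isinstance(p_prev, float) and np.isnan(p_prev)) else p_prev
    if pa is None and pp is None:
        return None
    if pa is None:
        return float(pp)
    if pp is None:
        return float(pa)
    p_min = min(pa, pp)
    return float(2 * p_min - p_min * p_min)


def adjust_fdr(pvals: pd.Series | Sequence[float]) -> pd.Series:
    """Benjamini-Hochberg step-up over the finite entries; absent entries
    stay absent."""
    s = pd.Series(pvals, dtype=float)
    finite = s.notna()
    q = pd.Series(np.nan, index=s.index)
    if finite.sum() == 0:
        return q
    from statsmodels.stats.multitest import multipletests

    _, qv, _, _ = multipletests(s[finite].to_numpy(), method="fdr_bh")
    q[finite] = qv
    return q


def significance_filter(
    records: Sequence[AssociationRecord],
    q_threshold: float = 0.1,
    effect_threshold: float = 0.0,
    exclude_flagged: bool = False,
    use_joint: bool = False,
) -> list[AssociationRecord]:
    """Keep records that are significant and interpretable.

    A record passes if its q-value (individual by default, joint when
    ``use_joint``) is at most ``q_threshold``, its coefficient magnitude
    exceeds ``effect_threshold``, and it carries no model-fitting error.
    ``exclude_flagged`` additionally drops prevalence associations flagged
    as likely abundance-induced.
    """
    out = []
    for r in records:
        if r.error is not None:
            continue
        q = r.qval_joint if use_joint else r.qval_individual
        if q is None or not np.isfinite(q) or q > q_threshold:
            continue
        if effect_threshold > 0:
            if r.coef is None or not np.isfinite(r.coef) or abs(r.coef) <= effect_threshold:
                continue
        if exclude_flagged and r.flag_abundance_induced:
            continue
        out.append(r)
    return out
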