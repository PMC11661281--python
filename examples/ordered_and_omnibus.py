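"""Ordered covariates (consecutive-level steps) and group omnibus tests.

An ordered covariate (e.g. disease stage) is fit with thermometer coding:
indicator t is on for every level >= t, so each coefficient IS the change
between consecutive levels.  A multi-level `group` covariate instead gets
an ANOVA-style omnibus test of all its level coefficients at once
(F-test for the linear half, likelihood-ratio test for the logistic half).
"""

import logging

import numpy as np
import pandas as pd

from hurdleda import (
    CovariateRole,
    MetadataTable,
    ModelSpec,
    fit_abundance,
    omnibus_test,
    ordered_contrasts,
)

logging.basicConfig(level=logging.WARNING)
rng = np.random.default_rng(5)

n = 400
stages = ["healthy", "mild", "moderate", "severe"]
stage = rng.choice(stages, size=n)
site = rng.choice(["siteA", "siteB", "siteC"], size=n)
idx = [f"s{i}" for i in range(n)]
metadata = MetadataTable(
    pd.DataFrame({"stage": stage, "site": site}, index=idx),
    roles={
        "stage": CovariateRole("ordered", levels=stages),
        "site": CovariateRole("group", reference="siteA", levels=["siteA", "siteB", "siteC"]),
    },
)

# true effect: a +1.5 log2 jump between mild and moderate, nothing else;
# site has no effect at all
rank = pd.Series(stage).map({s: i for i, s in enumerate(stages)}).to_numpy()
y = pd.Series(1.5 * (rank >= 2) + rng.normal(0, 1, n), index=idx)

spec = ModelSpec(fixed_terms=["stage", "site"], median_comparison=False)
fit = fit_abundance(y, spec, metadata)

print("consecutive-level step tests (thermometer coding):")
steps = ordered_contrasts(fit, [f"stage:{s}" for s in stages[1:]])
for r in steps:
    print(f"  {r.name:<18} step={r.estimate:+.2f}  p={r.pval:.2g}")
print("only the mild->moderate step should be significant.\n")

res = omnibus_test(fit, ["site:siteB", "site:siteC"])
print(f"site omnibus F-test: statistic={res.statistic:.2f} p={res.pval:.2f}")
print("(site carries no effect, so this p-value should be unremarkable)")
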