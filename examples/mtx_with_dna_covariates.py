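"""Metatranscriptomics: model RNA abundance with paired DNA as a
feature-specific covariate.

For each (sample, feature) cell the matched DNA relative abundance enters
the RNA model as its own covariate: where DNA > 0 the covariate is
log2(DNA); where DNA = 0 but RNA > 0 it is log2 of half the dataset-wide
minimum non-zero DNA abundance; where both are zero the observation is
excluded (absence of the gene is not evidence about its expression).
"""

import numpy as np
import pandas as pd

from hurdleda import FeatureTable, preprocess_mtx

rng = np.random.default_rng(3)
n, m = 6, 4
samples = [f"s{i}" for i in range(n)]
features = [f"pathway_{j}" for j in range(m)]

dna_raw = rng.dirichlet(np.ones(m), size=n)
dna_raw[dna_raw < 0.05] = 0.0  # some pathways undetected in DNA
dna = FeatureTable(
    pd.DataFrame(dna_raw / dna_raw.sum(1, keepdims=True), index=samples, columns=features),
    scale="relative",
)
rna_raw = rng.dirichlet(np.ones(m), size=n)
rna_raw[0, 0] = 0.0
rna = FeatureTable(
    pd.DataFrame(rna_raw / rna_raw.sum(1, keepdims=True), index=samples, columns=features),
    scale="relative",
)

hurdle, dna_covariate = preprocess_mtx(rna, dna)

n_excluded = int(hurdle.presence.isna().sum().sum())
n_filled = int((dna.values() == 0).sum() - n_excluded)
print(f"cells excluded (DNA=0 and RNA=0): {n_excluded}")
print(f"cells with DNA=0 but RNA>0 (covariate set to half the min non-zero DNA): {n_filled}")
print("\nper-feature DNA covariate (log2 relative abundance), first feature:")
print(dna_covariate.iloc[:, 0].round(2).to_string())
print("\nfeed `hurdle` and one covariate column per feature into fit_abundance /")
print("fit_prevalence via ModelSpec(feature_specific_covariate=...), so each")
print("pathway's expression is tested while adjusting for its gene copy number.")
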