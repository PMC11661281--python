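"""Absolute-abundance inference from a spike-in experiment.

A reference feature of known absolute abundance (1-10% of each sample's
total) anchors the relative abundances: A_ik = A_ref,k * P_ik / P_ref,k.
On the absolute scale the median comparison is unnecessary and is switched
off automatically, and fitted abundance coefficients estimate the true
absolute-scale effects directly rather than compositional differences.
"""

import logging

import numpy as np

from hurdleda import ModelSpec, run_analysis, score_run
from hurdleda.simulator import (
    NullTemplate,
    simulate_community,
    simulate_metadata,
    simulate_truth,
)

logging.basicConfig(level=logging.WARNING)

rng = np.random.default_rng(11)
template = NullTemplate.draw(100, seed=rng)
metadata = simulate_metadata(200, 5, seed=rng)
truth = simulate_truth(template.feature_ids, list(metadata.data.columns), seed=rng)
dataset = simulate_community(template, metadata, truth, spike_in=True, seed=rng)

print(f"spike-in absolute abundance recorded for {len(dataset.spike_in.reference_abs)} samples")

spec = ModelSpec(fixed_terms=list(metadata.data.columns), scale_mode="spike_in")
print(f"median comparison active: {spec.median_comparison} (disabled on the absolute scale)")

records = run_analysis(
    dataset.counts, dataset.metadata, spec, scaling_info=dataset.spike_in, seed=11
)
metrics = score_run(records, dataset.truth)
print(f"precision={metrics.precision:.2f} recall={metrics.recall:.2f}")

# coefficient accuracy for the spiked abundance effects
truth_ab = {
    (t.feature, t.covariate): t.coefficient
    for t in dataset.truth.itertuples()
    if t.type == "abundance"
}
errs = [
    r.coef - truth_ab[(r.feature, r.metadata)]
    for r in records
    if r.model == "abundance" and r.error is None and (r.feature, r.metadata) in truth_ab
]
print(f"mean error of fitted vs true log2 abundance coefficients: {np.mean(errs):+.2f}")
print("(near zero: spike-in anchoring removes the compositional bias entirely)")
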