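"""Reproducible benchmark runs on simulated communities.

Each helper generates data under one of the standard study designs, runs
the full analysis pipeline with default settings, and scores the result
against the simulation's ground truth.  Sample sizes and replicate counts
are parameters so the same machinery serves both quick checks and fuller
replications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .hurdle_models import ModelSpec
from .pipeline import run_analysis
from .simulator import (
    BenchmarkMetrics,
    NullTemplate,
    score_run,
    simulate_community,
    simulate_metadata,
    simulate_truth,
)

#: the standard log-normal benchmark design
DEFAULT_N_FEATURES = 100
DEFAULT_N_METADATA = 5
DEFAULT_SPIKED_FRACTION = 0.10
DEFAULT_EFFECT_RANGE = (2.5, 5.0)
DEFAULT_DEPTH_MEAN = 50_000.0


@dataclass
class BenchmarkRun:
    metrics: BenchmarkMetrics
    n_samples: int
    seed: int


def run_lognormal_replicate(
    n_samples: int,
    seed: int,
    n_features: int = DEFAULT_N_FEATURES,
    n_metadata: int = DEFAULT_N_METADATA,
    spiked_fraction: float = DEFAULT_SPIKED_FRACTION,
    effect_range: tuple[float, float] = DEFAULT_EFFECT_RANGE,
    depth_mean: float = DEFAULT_DEPTH_MEAN,
    n_subjects: Optional[int] = None,
    spike_in: bool = False,
    match_type: bool = False,
    q_threshold: float = 0.1,
) -> BenchmarkRun:
    """One replicate of the zero-inflated log-normal benchmark.

    Draws a fresh template, metadata, truth table and community from
    ``seed``; fits the default pipeline (per-subject random intercepts when
    ``n_subjects`` is given, spike-in normalization when ``spike_in``); and
    scores discoveries at the joint q threshold.
    """
    rng = np.random.default_rng(seed)
    template = NullTemplate.draw(n_features, seed=rng)
    md = simulate_metadata(n_samples, n_metadata, n_subjects=n_subjects, seed=rng)
    covariates = [c for c in md.data.columns if c != "subject"]
    truth = simulate_truth(
        template.feature_ids,
        covariates,
        spiked_fraction=spiked_fraction,
        effect_range=effect_range,
        seed=rng,
    )
    ds = simulate_community(
        template, md, truth, depth_mean=depth_mean, spike_in=spike_in, seed=rng
    )
    spec = ModelSpec(
        fixed_terms=covariates,
        random_intercepts=["subject"] if n_subjects is not None else [],
        scale_mode="spike_in" if spike_in else "relative",
    )
    records = run_analysis(
        ds.counts,
        ds.metadata,
        spec,
        scaling_info=ds.spike_in if spike_in else None,
        seed=seed,
    )
    metrics = score_run(
        records, ds.truth, q_threshold=q_threshold, match_type=match_type
    )
    return BenchmarkRun(metrics=metrics, n_samples=n_samples, seed=seed)


def average_metric(runs: list[BenchmarkRun], name: str) -> float:
    """Mean of one metric over replicates, skipping undefined values
    (e.g. precision with zero discoveries)."""
    vals = [getattr(r.metrics, name) for r in runs]
    vals = [v for v in vals if v is not None and np.isfinite(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def replicate_seeds(seed: int, count: int) -> list[int]:
    """Independent per-replicate seeds derived from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(count) % (2**31)]
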