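import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd
import pytest

from hurdleda import (
    CovariateRole,
    FeatureTable,
    MetadataTable,
    ModelSpec,
    simulate_community,
    simulate_metadata,
    simulate_truth,
)
from hurdleda.simulator import NullTemplate

logging.getLogger("hurdleda").setLevel(logging.ERROR)


@pytest.fixture
def counts_table() -> FeatureTable:
    data = pd.DataFrame(
        {
            "taxonA": [10.0, 0.0, 5.0, 3.0],
            "taxonB": [0.0, 20.0, 5.0, 7.0],
            "taxonC": [30.0, 20.0, 0.0, 0.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return FeatureTable(data, scale="counts")


@pytest.fixture
def metadata_table() -> MetadataTable:
    data = pd.DataFrame(
        {
            "age": [1.0, 2.0, 3.0, 4.0],
            "diagnosis": ["healthy", "ibd", "ibd", "healthy"],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    roles = {
        "age": CovariateRole("continuous"),
        "diagnosis": CovariateRole(
            "categorical", reference="healthy", levels=["healthy", "ibd"]
        ),
    }
    return MetadataTable(data, roles=roles)


@pytest.fixture(scope="session")
def small_simulated_dataset():
    """One seeded 80-sample, 60-feature community with spiked associations."""
    rng = np.random.default_rng(42)
    template = NullTemplate.draw(60, seed=rng)
    md = simulate_metadata(80, 4, seed=rng)
    truth = simulate_truth(template.feature_ids, list(md.data.columns), 0.10, seed=rng)
    return simulate_community(template, md, truth, seed=rng)


@pytest.fixture
def default_spec(small_simulated_dataset) -> ModelSpec:
    return ModelSpec(fixed_terms=list(small_simulated_dataset.metadata.data.columns))
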