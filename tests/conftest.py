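import warnings

import numpy as np
import pytest

from rnascout.pipeline import PipelineConfig, run_pipeline
from rnascout.synthetic_data import DatasetSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic locus set for fast pipeline-level tests."""
    spec = DatasetSpec(
        n_contigs=8,
        n_operons=5,
        n_structured_families=2,
        n_decoy_families=1,
        family_instances_range=(6, 8),
        n_arrays=4,
        seed=42,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(
            PipelineConfig(seed=42),
            small_dataset.contigs,
            small_dataset.genes,
            small_dataset.arrays,
        )
    return result


@pytest.fixture(scope="session")
def standard_runs():
    """The standard synthetic scenario over five seeds (the recovery surface)."""
    runs = []
    for seed in (1, 2, 3, 4, 5):
        ds = generate_dataset(DatasetSpec(seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_pipeline(PipelineConfig(seed=seed), ds.contigs, ds.genes, ds.arrays)
        runs.append((ds, res))
    return runs
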