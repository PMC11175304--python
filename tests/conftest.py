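import dataclasses

import pytest

from etongue import classify, default_config, default_spec, evaluate
from etongue.preprocess import prepare_dataset
from etongue.syndata import GeneratorConfig, generate_dataset

# Seeds fixed once for the whole suite.
GEN_SEED = 1
SPLIT_SEED = 100


def scaled_config(points=(700, 665, 630), scans=4, electrodes=2, seed=7,
                  **overrides) -> GeneratorConfig:
    """The default campaign with shorter scans and fewer acquisitions."""
    base = GeneratorConfig()
    sensors = [
        dataclasses.replace(s, n_points=n) for s, n in zip(base.sensors, points)
    ]
    return dataclasses.replace(
        base, sensors=sensors, scans_per_electrode=scans,
        electrodes_per_condition=electrodes, seed=seed, **overrides,
    )


@pytest.fixture(scope="session")
def small_config():
    return scaled_config()


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_prep(small_dataset):
    return prepare_dataset(small_dataset, k=35)


@pytest.fixture(scope="session")
def full_dataset():
    """The default acquisition campaign: 1080 scans, 54 measurements."""
    return generate_dataset(default_config(seed=GEN_SEED))


@pytest.fixture(scope="session")
def full_prep(full_dataset):
    return prepare_dataset(full_dataset, k=35)


@pytest.fixture(scope="session")
def lda_report(full_prep):
    """LDA+KMeans over 100 random 70/30 splits of the default dataset."""
    spec = default_spec("LDA_KMEANS", seed=SPLIT_SEED)
    return evaluate.repeated_evaluation(
        full_prep, spec, n_runs=100, test_fraction=0.3, base_seed=SPLIT_SEED
    )
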