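import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mginfeval import (
    AbundanceTable,
    FeatureAnnotation,
    GeneratorConfig,
    ReferenceModel,
    SampleFrame,
    generate_paired_dataset,
)
from mginfeval.simulate import _DEFAULT_ANI, TAXON_CRISPATUS, TAXON_INERS

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The study-design default: 72 samples, 500 KOs, seed 7."""
    return generate_paired_dataset(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 15-sample, 60-KO dataset for structural tests."""
    config = GeneratorConfig(
        seed=11,
        n_samples_per_cluster={"crispatus": 5, "iners": 6, "mixed": 4},
        n_cases_per_cluster={"crispatus": 3, "iners": 3, "mixed": 2},
        n_kos=60,
    )
    return generate_paired_dataset(config)


def differential_error_config(seed: int) -> GeneratorConfig:
    """Discard-mode reference with iners ani 0.90 and crispatus ani 1.0."""
    ani = dict(_DEFAULT_ANI)
    ani[TAXON_INERS] = 0.90
    ani[TAXON_CRISPATUS] = 1.0
    return GeneratorConfig(
        seed=seed,
        reference={"discard": ReferenceModel(ani=ani, mode="discard_renormalize")},
    )


def perfect_reference_config(seed: int = 5) -> GeneratorConfig:
    """Noise-free generator with a perfect reference for every taxon."""
    ani = {t: 1.0 for t in _DEFAULT_ANI}
    return GeneratorConfig(
        seed=seed,
        noise_sd=0.0,
        reference={
            "blend": ReferenceModel(ani=ani, mode="retain_blend"),
            "discard": ReferenceModel(ani=ani, mode="discard_renormalize"),
        },
    )


@pytest.fixture
def toy_table():
    df = pd.DataFrame(
        [[0.6, 0.4], [0.5, 0.5]],
        index=["s1", "s2"],
        columns=["f1", "f2"],
    )
    return AbundanceTable(df, "relative")


@pytest.fixture
def toy_frame():
    return SampleFrame(
        pd.DataFrame(
            {"outcome": ["case", "control"], "cluster": ["a", "a"]},
            index=["s1", "s2"],
        )
    )
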