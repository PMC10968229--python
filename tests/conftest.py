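import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from linkerbench import SyntheticConfig, default_predictor_suite, generate_corpus

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A scaled-down corpus recipe used across the suite.

    Keeps the default class fractions but shortens proteins and DL segments
    proportionally, so the rebalancing sampler stays feasible inside 50%
    protein subsamples.
    """
    kw = dict(
        n_proteins=100,
        protein_length_log_mu=5.4,
        protein_length_log_sigma=0.5,
        protein_length_min=50,
        protein_length_max=600,
        dl_length_min=8,
        dl_length_median=14,
        dl_length_max=40,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_corpus():
    """One deterministic small corpus with the default predictor panel."""
    return generate_corpus(small_config(seed=11), default_predictor_suite(noise_seed=42))
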