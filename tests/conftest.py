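import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_count_study(counts: pd.DataFrame, lengths=None, meta=None):
    """Wrap a raw count matrix in a CountStudy with minimal metadata."""
    from pleiokit.preprocessing import CountStudy

    if lengths is None:
        lengths = pd.Series(1000, index=counts.index)
    if meta is None:
        meta = pd.DataFrame(
            {
                "background": "BY",
                "genotype": "WT",
                "replicate": np.arange(1, counts.shape[1] + 1),
                "batch": "b1",
            },
            index=counts.columns,
        )
    return CountStudy(counts=counts, gene_lengths=lengths, samples=meta)


@pytest.fixture(scope="session")
def expression_study():
    """Default desk-scale two-background knockout study (seed 1)."""
    from pleiokit.synthetic_data import SimulationConfig, generate_expression_study

    return generate_expression_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def morphology_study():
    from pleiokit.synthetic_data import SimulationConfig, generate_morphology_study

    return generate_morphology_study(
        SimulationConfig(n_traits=40, n_trait_clusters=8, n_tfs=3, seed=1)
    )
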