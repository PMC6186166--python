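import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sigdepth as sd

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at default conditions, shared across tests."""
    config = sd.SimConfig(seed=11)
    counts, truth = sd.generate_counts(config)
    library, truth = sd.generate_reference_library(truth, config)
    return config, counts, library, truth


@pytest.fixture()
def tiny_counts():
    """3 genes x 4 samples, groups A/A/B/B."""
    return sd.CountMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        counts=np.array([[10, 12, 30, 28], [5, 4, 5, 6], [100, 90, 40, 50]]),
        groups=["A", "A", "B", "B"],
    )


@pytest.fixture()
def four_gene_library():
    """Universe {g1..g4} with one profile z = (3, -1, 2, -2)."""
    return sd.ReferenceLibrary(
        gene_universe=["g1", "g2", "g3", "g4"],
        scores=np.array([[3.0], [-1.0], [2.0], [-2.0]]),
        perturbagens=["pertA"],
        cell_lines=["CL1"],
    )
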