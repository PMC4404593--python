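import numpy as np
import pandas as pd
import pytest

from cuporigin import CohortConfig, generate_cohort, generate_gene_sets


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A quick three-class cohort with every sample group present."""
    return CohortConfig(
        n_classes=3,
        n_probes=300,
        probes_per_class_signature=10,
        n_primary_per_class=12,
        n_metastasis_per_class=12,
        n_cup=10,
        n_normal=6,
        instability_signature_size=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_gene_sets(small_cohort):
    _, _, truth = small_cohort
    return generate_gene_sets(truth, n_decoys=5, decoy_size=20, seed=4)


@pytest.fixture()
def toy_matrix() -> pd.DataFrame:
    """A fixed 3-probe x 4-sample matrix for hand-checkable arithmetic."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 9.0], [2.0, 2.0, 2.0, 2.0]],
        index=["pA", "pB", "pC"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
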