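import numpy as np
import pandas as pd
import pytest

from mmresp import synthetic


@pytest.fixture(scope="session")
def study93():
    """The default study-scale fixture (93 patients, 42 CB, 29/29/21)."""
    return synthetic.study_93(seed=11)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config for fast unit tests."""
    return synthetic.SimConfig(
        n_patients=24, n_genes=300, n_signal_genes=20, n_tracked_variants=6,
        n_controls=6, seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.simulate_cohort(
        small_config, cohort_sizes=(8, 8, 8), exact_n_cb=12
    )


@pytest.fixture(scope="session")
def small_expression(small_cohort, small_config):
    return synthetic.simulate_expression(small_cohort, small_config)


@pytest.fixture(scope="session")
def small_assay(small_cohort, small_config):
    return synthetic.simulate_ctdna_assay(small_cohort, small_config)
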