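import numpy as np
import pandas as pd
import pytest

from frailtybrain import CohortConfig, GroupSpec, generate_frailty_scores


@pytest.fixture(scope="session")
def table1_config() -> CohortConfig:
    """Cohort config at the published group parameters."""
    return CohortConfig(seed=7)


@pytest.fixture(scope="session")
def table1_scores(table1_config):
    """One draw of frailty scores at the published group parameters."""
    return generate_frailty_scores(table1_config)


@pytest.fixture()
def small_groups():
    return (GroupSpec("CU", 120, 0.14, 0.065),
            GroupSpec("AD", 90, 0.24, 0.075),
            GroupSpec("FTLD", 60, 0.27, 0.10))


@pytest.fixture()
def two_group_frame(table1_scores):
    """CU/AD rows with binary label (AD = 1)."""
    frailty, group = table1_scores
    mask = group != "FTLD"
    return pd.DataFrame({
        "frailty": frailty[mask],
        "label": (group[mask] == "AD").astype(int),
    }).reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
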