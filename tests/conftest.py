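import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import savor

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference() -> pd.DataFrame:
    return savor.load_reference()


@pytest.fixture(scope="session")
def panel_summary() -> pd.DataFrame:
    return savor.load_panel_summary()


@pytest.fixture(scope="session")
def mean_records(panel_summary) -> pd.DataFrame:
    """Published group means as a concentration table (no replicates)."""
    return panel_summary.rename(columns={"mean": "concentration"})[
        ["compound", "group", "concentration"]
    ]


@pytest.fixture(scope="session")
def group_means(panel_summary):
    """(compound, group) -> published mean concentration in mg/100 g."""
    return panel_summary.set_index(["compound", "group"])["mean"]
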