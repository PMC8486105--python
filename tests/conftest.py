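import pandas as pd
import pytest

from rootpue.cli_report import make_fixture
from rootpue.trait_io import summarize_panel


@pytest.fixture(scope="session")
def mini_fixture():
    """10 genotypes × 2 regimes × 3 reps, full 27-trait set, seed 0."""
    return make_fixture("mini", seed=0)


@pytest.fixture(scope="session")
def mini_panel(mini_fixture):
    return mini_fixture.panel


@pytest.fixture(scope="session")
def mini_summary(mini_panel):
    return summarize_panel(mini_panel, method="raw_mean")


def long_panel(records):
    """Build a panel frame from (genotype, regime, replicate, trait, value)."""
    return pd.DataFrame(
        records, columns=["genotype", "regime", "replicate", "trait", "value"]
    )
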