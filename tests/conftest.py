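import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fibromr import (
    SimConfig,
    compute_allele_score,
    panel_to_variants,
    simulate_cohort,
    simulate_summary_stats,
    variant_panel,
)
from fibromr.synthetic_data import CohortData

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def cohort(config):
    """A default simulated cohort (read-only across tests)."""
    return simulate_cohort(config, 0)


@pytest.fixture(scope="session")
def summary_pairs(config):
    return simulate_summary_stats(config)


@pytest.fixture
def variants(config):
    """Fresh instrument list per test (filters mutate qc_flags)."""
    return panel_to_variants(variant_panel(config))


@pytest.fixture
def score(cohort, variants):
    return compute_allele_score(cohort.dosages, variants)


def make_minimal_cohort(dosages: pd.DataFrame, label: str = "toy") -> CohortData:
    """Wrap a dosage frame in a valid CohortData with inert phenotypes/outcomes."""
    n = len(dosages)
    rng = np.random.default_rng(0)
    pheno = pd.DataFrame(
        {
            "age": np.linspace(40, 70, n),
            "sex": (np.arange(n) % 2).astype(float),
            "fibrinogen": rng.normal(3.0, 0.5, n),
            "bmi": rng.normal(27, 4, n),
            "ldl": rng.normal(127, 30, n),
            "hdl": rng.normal(53, 15, n),
            "hypertension": rng.binomial(1, 0.3, n).astype(float),
            "diabetes": rng.binomial(1, 0.1, n).astype(float),
            "smoking": rng.choice(3, n).astype(float),
        }
    )
    outcomes = pd.DataFrame(
        {"event": rng.binomial(1, 0.2, n), "time": rng.exponential(8.0, n)}
    )
    return CohortData(dosages=dosages, phenotypes=pheno, outcomes=outcomes, label=label)
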