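import numpy as np
import pytest

from gradedcat import (
    StoppingRule,
    aaq_bank,
    compare_versions,
    generate_cohort,
)
from gradedcat.bank import GradedItem, ItemBank

COHORT_SEED = 20260  # documented seed of the reference synthetic cohort


@pytest.fixture(scope="session")
def bank():
    return aaq_bank()


@pytest.fixture(scope="session")
def toy_bank():
    """Small mixed-category bank for enumeration-scale checks."""
    return ItemBank(
        (
            GradedItem(id="T1", a=2.0, b=(-0.5, 0.7)),
            GradedItem(id="T2", a=1.5, b=(0.2,)),
            GradedItem(id="T3", a=2.5, b=(-1.0, 0.3, 1.4)),
        )
    )


@pytest.fixture(scope="session")
def cohort(bank):
    """Reference synthetic cohort: n = 1408, theta ~ N(0,1)."""
    return generate_cohort(bank, n=1408, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cat_report(bank, cohort):
    """Three post-hoc CAT versions (caps 17/10/5) on the reference cohort."""
    rules = [StoppingRule(se_threshold=0.3, max_items=c) for c in (17, 10, 5)]
    return compare_versions(cohort, bank, rules)


@pytest.fixture()
def rng():
    return np.random.default_rng(97)
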