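import numpy as np
import pytest

from itqnet.constants import IMPAIRMENT_ITEMS, SYMPTOM_ITEMS
from itqnet.datagen import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-config cohort, n=1000 — shared across read-only tests."""
    return generate_cohort(default_config(n_subjects=1000, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """Default-config cohort, n=2000 — for reliability / CFA checks."""
    return generate_cohort(default_config(n_subjects=2000, seed=7))


def blank_record(**overrides):
    """All-zero ITQ record (trauma exposed); override individual items."""
    rec = {item: 0 for item in SYMPTOM_ITEMS + IMPAIRMENT_ITEMS}
    rec["trauma_exposed"] = True
    rec.update(overrides)
    return rec


@pytest.fixture
def make_record():
    return blank_record
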