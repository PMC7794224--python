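import numpy as np
import pandas as pd
import pytest

from pvscreen import default_spec, generate_cohort


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def small_cohort(spec):
    """A 5,000-record cohort shared by tests that only need plausible data."""
    return generate_cohort(spec.replace(n=5000), seed=42)


def make_record(**kw) -> pd.Series:
    """A single plausible blood-count record with overridable fields."""
    base = dict(id="S000000", sex="male", age=60.0, hb=14.0, htc=42.0,
                wbc=7.0, neutrophils=4.0, platelets=230.0, mcv=90.0,
                rdw=13.0, mch=30.0, mchc=33.0, jak2_positive=False,
                known_mpn=False, dna_ok=True)
    base.update(kw)
    return pd.Series(base)


@pytest.fixture
def record():
    return make_record
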