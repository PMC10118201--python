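import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import glycassoc as ga
from glycassoc.tables_io import PanelSchema, PeakTable

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_schema():
    return PanelSchema(panel_id="plasma", peak_ids=("GP1", "GP2", "GP3"))


@pytest.fixture(scope="session")
def toy_percent_table(toy_schema):
    data = pd.DataFrame([[20.0, 30.0, 50.0], [10.0, 40.0, 50.0]],
                        index=["s1", "s2"], columns=list(toy_schema.peak_ids))
    return PeakTable(data=data, unit="percent", schema=toy_schema)


@pytest.fixture(scope="session")
def null_cohort():
    """All-null synthetic cohort at the study's group sizes (48/41)."""
    return ga.generate_cohort(ga.SynthConfig(seed=1000))


@pytest.fixture(scope="session")
def null_bundle(null_cohort):
    peaks, clinical, _ = null_cohort
    return ga.analyze_cohort(peaks, clinical)


def rng(seed=0):
    return np.random.default_rng(seed)
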