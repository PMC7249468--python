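import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hyp_settings

from bbbflux.synthetic import CohortConfig, SamplingSchedule, make_study_like_cohort

# property tests must behave identically on every run
_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_s100b_cohort():
    """16-subject barrier-mediated cohort used by several test modules."""
    return make_study_like_cohort("s100b_like", n=16, seed=1)


@pytest.fixture(scope="session")
def small_nse_cohort():
    return make_study_like_cohort("nse_like", n=16, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20200527)


@pytest.fixture()
def tiny_long_frame():
    """Hand-written long table: 2 subjects, 2 analytes, irregular times."""
    rows = [
        ("P1", "S100B_CSF", 0.0, 1.0), ("P1", "S100B_CSF", 12.0, 3.0),
        ("P1", "S100B_CSF", 24.0, 2.0),
        ("P1", "S100B_BLOOD", 0.0, 0.5), ("P1", "S100B_BLOOD", 24.0, 1.5),
        ("P2", "S100B_CSF", 0.0, 4.0), ("P2", "S100B_CSF", 24.0, 1.0),
        ("P2", "S100B_BLOOD", 12.0, 2.0), ("P2", "S100B_BLOOD", 24.0, 1.0),
    ]
    df = pd.DataFrame(rows, columns=["subject_id", "analyte", "time_h", "value"])
    df["unit"] = "ug/L"
    return df
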