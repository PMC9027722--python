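import numpy as np
import pytest

from cuspcat import SyntheticStudyConfig, generate_study
from cuspcat.study_data import frame_to_records


@pytest.fixture(scope="session")
def default_study():
    """Default two-arm synthetic study (50 normative + 49 outcome, seed 0)."""
    df, truth = generate_study(SyntheticStudyConfig())
    return df, truth


@pytest.fixture(scope="session")
def default_records(default_study):
    df, _ = default_study
    return frame_to_records(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
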