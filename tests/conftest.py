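import pytest

from ubandit.cohort import generate_cohort
from ubandit.designs import make_main_design, make_validation_design


@pytest.fixture(scope="session")
def main_design():
    return make_main_design()


@pytest.fixture(scope="session")
def validation_design():
    return make_validation_design("interleaved")


@pytest.fixture(scope="session")
def small_cohort(main_design):
    """Six Kalman:QU virtual subjects on the main design."""
    return generate_cohort(6, "kalman:qu", main_design, seed=42)
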