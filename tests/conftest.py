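from pathlib import Path

import pytest

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture30_path() -> Path:
    return DATA_DIR / "fixture30.csv"


@pytest.fixture(scope="session")
def fixture30_expected_path() -> Path:
    return DATA_DIR / "fixture30_expected.csv"


@pytest.fixture(scope="session")
def small_generated():
    """A modest synthetic cohort shared across tests (seed fixed)."""
    from bckpi.synth import generate_cohort, paper_marginals_preset

    return generate_cohort(paper_marginals_preset(seed=11, n_patients=1000))
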