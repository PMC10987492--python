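import numpy as np
import pytest

from arrestscreen.pipeline import screen_records
from arrestscreen.synthetic import SyntheticConfig, generate_cohort

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def default_cohort():
    """The standard 20-genome synthetic cohort (seed 1) with its manifest."""
    records, manifest = generate_cohort(SyntheticConfig.default_cohort(seed=1))
    return records, manifest


@pytest.fixture(scope="session")
def default_report(default_cohort):
    records, _ = default_cohort
    return screen_records(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_protein(rng, length, alphabet=AMINO_ACIDS):
    return "".join(rng.choice(list(alphabet), size=length))
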