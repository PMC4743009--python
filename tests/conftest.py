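import numpy as np
import pytest

from bpshift import diffsplice, event_classification
from bpshift.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Desk-scale cohort at the default study conditions (seeded)."""
    return generate_cohort(seed=11)


@pytest.fixture(scope="session")
def default_diff(default_cohort):
    return diffsplice.run_diffsplice(
        default_cohort.junctions, default_cohort.sample_sheet
    )


@pytest.fixture(scope="session")
def default_events(default_cohort, default_diff):
    selected = list(default_diff.loc[default_diff["selected"], "id"])
    return event_classification.build_pairs(
        selected, default_cohort.junctions, default_cohort.annotation
    )


@pytest.fixture(scope="session")
def alt3_events(default_events):
    return [e for e in default_events if e.event_class == "alt3"]


@pytest.fixture()
def toy_genome():
    """Two tiny contigs with known sequence for window-extraction checks."""
    return {
        "chrA": "ACGTACGTTTTCAGGCCAATTGGCCAATT",
        "chrB": "TTTTTTTTTTCAGATATATATATATATAT",
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
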