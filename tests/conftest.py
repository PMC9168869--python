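import numpy as np
import pytest

from circahrv import synthetic
from circahrv.types import IbiSeries


@pytest.fixture(scope="session")
def normative_table():
    return synthetic.generate_normative_table(seed=0)


@pytest.fixture(scope="session")
def small_subject():
    """One simulated subject, 3 recorded days, moderate artifact rate."""
    truth = synthetic.SubjectTruth("s001", artifact_rate=4.0)
    return synthetic.generate_ibi_series(truth, days=3, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 + 4 subjects, 2 days, no injected effects."""
    cfg = synthetic.CohortConfig(n_per_group=4, days=2, seed=7)
    return synthetic.generate_cohort(cfg)


def make_series(ibis, flags=None, subject_id="t") -> IbiSeries:
    s = IbiSeries.from_ibis(subject_id, np.asarray(ibis, dtype=float))
    if flags is not None:
        s.flags = np.asarray(flags, dtype=np.uint8)
    return s


@pytest.fixture
def series_factory():
    return make_series
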