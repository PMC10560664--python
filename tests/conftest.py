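import numpy as np
import pytest

from gazeload.aoi import default_aoi_set
from gazeload.core import TrialSchedule
from gazeload.pipeline import compute_cohort_metrics
from gazeload.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def aoi_set():
    return default_aoi_set()


@pytest.fixture(scope="session")
def schedule():
    return TrialSchedule()


@pytest.fixture(scope="session")
def default_cohort(schedule, aoi_set):
    """Full study-scale cohort (52 participants, 20 x 30 s trials)."""
    return simulate_cohort(CohortConfig(seed=1), schedule, aoi_set)


@pytest.fixture(scope="session")
def default_metrics(default_cohort, aoi_set, schedule):
    metrics, _ = compute_cohort_metrics(default_cohort.recordings, aoi_set, schedule)
    return metrics


@pytest.fixture(scope="session")
def small_cohort(aoi_set):
    """A fast cohort for structural tests: full trial count, short trials."""
    sched = TrialSchedule(trial_duration_s=5.0)
    cfg = CohortConfig(group_sizes={"control": 3, "manic": 3, "depression": 2}, seed=7)
    return simulate_cohort(cfg, sched, aoi_set), sched


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
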