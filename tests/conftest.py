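import pytest

from avsync.cohort import default_cohort_config, generate_behavioral_scores, sample_cohort
from avsync.design import StudyDesign
from avsync.io import aggregate_order_errors, aggregate_synchrony, scores_to_frame
from avsync.psychometric import FitConfig, fit_cohort


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def fit_config():
    return FitConfig()


@pytest.fixture(scope="session")
def cohort():
    """One full default cohort at seed 1, shared across the suite."""
    config = default_cohort_config(1)
    observers, trials, truth = sample_cohort(config)
    return {"config": config, "observers": observers, "trials": trials, "truth": truth}


@pytest.fixture(scope="session")
def profiles(cohort):
    return aggregate_synchrony([t for t in cohort["trials"] if t.task == "SJ"])


@pytest.fixture(scope="session")
def order_errors(cohort):
    return aggregate_order_errors([t for t in cohort["trials"] if t.task == "TOJ"])


@pytest.fixture(scope="session")
def windows(profiles, fit_config):
    return fit_cohort(profiles, fit_config)


@pytest.fixture(scope="session")
def scores(cohort):
    recs = generate_behavioral_scores(
        cohort["truth"], cohort["config"].score_model, cohort["config"].seed
    )
    return scores_to_frame(recs)
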