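import numpy as np
import pandas as pd
import pytest

from recalldcb.inference import MCMCConfig
from recalldcb.synth import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def light_mcmc():
    """Small sampler settings for unit tests."""
    return MCMCConfig(chains=2, iterations=700, burn_in=350, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-participant cohort under default study conditions."""
    return generate_cohort(CohortConfig(n_participants=80, rng_seed=21))


@pytest.fixture(scope="session")
def truth_records(small_cohort):
    """Analysis records using the generator's true scores as predictors
    (no MCMC), for regression/classification tests."""
    from recalldcb.analysis import build_records
    from recalldcb.scoring import score_table

    recall_df, parts_df, truth_df = small_cohort
    scores = score_table(recall_df)
    dcb = truth_df[["participant_id", "N_avg", "R_avg", "M_avg"]]
    return build_records(parts_df, dcb, scores)
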