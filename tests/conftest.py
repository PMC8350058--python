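import numpy as np
import pytest

import cogstage as cs
from cogstage.pipeline import robust_norms_auto


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-parameter cohort: ~2600 visits, 600 participants."""
    cfg = cs.SimConfig(n_participants=600, seed=123)
    return cs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_visits(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_pet(small_cohort):
    return small_cohort[1]


@pytest.fixture(scope="session")
def default_cohort():
    """The default calibrated cohort at full size (n = 5000 participants)."""
    return cs.generate_cohort(cs.SimConfig(n_participants=5000, seed=1))


@pytest.fixture(scope="session")
def default_visits(default_cohort):
    return default_cohort[0]


@pytest.fixture(scope="session")
def default_oracle_norms(default_visits):
    mask = (default_visits["latent_state"] == "CU_S").to_numpy()
    return cs.fit_robust_norms(default_visits, mask)


@pytest.fixture(scope="session")
def oracle_norms(small_visits):
    """Norms fitted on the generator's true stable visits (latent CU_S)."""
    mask = (small_visits["latent_state"] == "CU_S").to_numpy()
    return cs.fit_robust_norms(small_visits, mask)


@pytest.fixture(scope="session")
def robust_model(small_visits):
    model, mask = robust_norms_auto(small_visits)
    return model, mask


@pytest.fixture(scope="session")
def staged_small(small_visits, robust_model):
    model, _ = robust_model
    return cs.stage_cohort(small_visits, model)


def make_record(**over):
    """A fully unremarkable visit record; override fields to probe rules."""
    rec = dict(
        participant_id="P1",
        visit_index=1,
        age=64.0,
        sex=0,
        wrat3_std=106.0,
        cdr_global=0.0,
        qdrs_global=0.0,
        iadl=16,
        iqcode=48,
        self_memory_problem="no",
        self_memory_likert=6,
        mmse=29.0,
        clock_draw=9.0,
        avlt_delay=10.5,
        lm_ii=26.0,
    )
    rec.update(over)
    return rec


@pytest.fixture
def normal_record():
    return make_record()
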