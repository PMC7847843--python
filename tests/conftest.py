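"""Shared fixtures: small synthetic datasets and the packaged reference set."""

import warnings

import numpy as np
import pytest

from gcvpk.data import DoseEvent, Observation, PKDataset, Subject
from gcvpk.nlme import final_model_spec
from gcvpk.simulate import GeneratorConfig, generate_cohort, generate_dataset, reference_dataset

warnings.filterwarnings("ignore", category=RuntimeWarning)
np.seterr(all="ignore")


@pytest.fixture(scope="session")
def final_spec():
    return final_model_spec()


@pytest.fixture(scope="session")
def reference():
    """The packaged deterministic reference fixture (104 subjects, 138 obs)."""
    return reference_dataset()


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-subject dataset with known truth for fast estimation tests."""
    config = GeneratorConfig(n_subjects=30, target_n_obs=80)
    cohort = generate_cohort(config, seed=7)
    return generate_dataset(cohort, config=config, seed=8)


@pytest.fixture
def one_subject():
    """A minimal hand-built subject with a q12h infusion history."""
    subject = Subject(id="A", wt=12.0, height=90.0, age=2.5, sex="M",
                      scr=26.0, egfr=110.0)
    doses = [DoseEvent(i * 12.0, 60.0, 1.0) for i in range(6)]
    obs = [Observation(1.0, 4.2), Observation(25.5, 2.0), Observation(61.0, 1.1)]
    return PKDataset(subjects=[subject], doses={"A": doses}, observations={"A": obs})
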