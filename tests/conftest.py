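"""Shared fixtures: one default synthetic imaging cohort per session.

The default cohort is the study condition used by the end-to-end checks:
20 subjects (10 responders, 10 non-responders), 64^3 phantoms at 0.15 mm,
default generator parameters, fixed seed.
"""

import logging

import numpy as np
import pandas as pd
import pytest

from deltarad.features import extract_all
from deltarad.selection import delta_table
from deltarad.synthetic import PhantomSpec, simulate_imaging_cohort

logging.getLogger("deltarad").setLevel(logging.ERROR)

COHORT_SEED = 7


@pytest.fixture(scope="session")
def imaging_cohort():
    subjects, truth = simulate_imaging_cohort(
        n_subjects=20, responder_fraction=0.5, base_spec=PhantomSpec(), seed=COHORT_SEED
    )
    return subjects, truth


@pytest.fixture(scope="session")
def cohort_features(imaging_cohort):
    subjects, truth = imaging_cohort
    pre = pd.DataFrame(
        {r["subject_id"]: extract_all(r["pre"], r["mask"]).values for r in subjects}
    ).T
    post = pd.DataFrame(
        {r["subject_id"]: extract_all(r["post"], r["mask"]).values for r in subjects}
    ).T
    return pre, post, truth


@pytest.fixture(scope="session")
def cohort_delta(cohort_features):
    pre, post, truth = cohort_features
    return delta_table(pre, post), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
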