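import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import priortime as pt

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard_conditions():
    return pt.standard_conditions()


@pytest.fixture(scope="session")
def small_cohort_trials():
    """12 simulated subjects, 2 reps/bin/block (324 trials each), gamma linked to CAPS."""
    hyper = pt.PopulationHyper(gamma_max=0.1)
    profiles = pt.generate_population(12, hyper, seed=1)
    conds = pt.standard_conditions(reps_per_bin_per_block=2)
    rng = np.random.default_rng(9)
    frames = []
    for prof in profiles:
        plan = pt.plan_session(rng)
        frames.append(pt.simulate_session(prof, plan, rng, conditions=conds))
    trials = pd.concat(frames, ignore_index=True)
    covariates = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "wf": [p.observer.wm for p in profiles],
            "caps": [p.caps_score for p in profiles],
        }
    )
    return trials, covariates, profiles


@pytest.fixture(scope="session")
def single_session():
    """One full-scale session (972 trials) from a typical observer."""
    prof = pt.SubjectProfile(
        subject_id="S0", observer=pt.ObserverParams(wm=0.12, wp=0.1)
    )
    plan = pt.plan_session(3)
    return pt.simulate_session(prof, plan, seed=7), prof
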