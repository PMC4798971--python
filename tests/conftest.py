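import numpy as np
import pytest

from racemind import (BeliefMap, ConfidenceCriterion, RaceParams,
                      RevisionParams, SessionDesign, build_belief_map,
                      simulate_trials)

# Fitted parameter sets used throughout: four observers of the reaching
# version of the random-dot task (initial-stage kappa, bound, mean
# non-decision time, confidence criterion; post-initiation time and shifts).
SUBJECT_PARAMS = {
    1: dict(kappa=13.64, bound=0.74, tnd_mean=0.461, theta=0.89,
            t_pip=0.395, d1=0.77, d2=0.24, d3=-0.36),
    2: dict(kappa=12.86, bound=0.73, tnd_mean=0.421, theta=1.26,
            t_pip=0.235, d1=1.32, d2=0.32, d3=-0.57),
    3: dict(kappa=8.69, bound=1.07, tnd_mean=0.409, theta=0.87,
            t_pip=0.390, d1=1.16, d2=0.44, d3=-0.26),
    4: dict(kappa=19.50, bound=0.74, tnd_mean=0.427, theta=1.12,
            t_pip=0.285, d1=0.79, d2=0.06, d3=-0.69),
}


def subject_race_params(subject: int) -> RaceParams:
    s = SUBJECT_PARAMS[subject]
    return RaceParams(kappa=s["kappa"], bound=s["bound"],
                      tnd_mean=s["tnd_mean"], tnd_sd=0.06)


@pytest.fixture(scope="session")
def s1_params() -> RaceParams:
    return subject_race_params(1)


@pytest.fixture(scope="session")
def s1_crit() -> ConfidenceCriterion:
    return ConfidenceCriterion(SUBJECT_PARAMS[1]["theta"])


@pytest.fixture(scope="session")
def s1_rev() -> RevisionParams:
    s = SUBJECT_PARAMS[1]
    return RevisionParams(t_pip=s["t_pip"], d1=s["d1"], d2=s["d2"], d3=s["d3"])


@pytest.fixture(scope="session")
def coherence_set() -> np.ndarray:
    return np.asarray(SessionDesign().coherences)


@pytest.fixture(scope="session")
def s1_belief_map(s1_params, coherence_set) -> BeliefMap:
    return build_belief_map(s1_params, coherence_set)


@pytest.fixture(scope="session")
def s1_session(s1_params, s1_crit, s1_rev, s1_belief_map):
    """One full simulated session at the Subject-1 parameter set."""
    return simulate_trials(s1_params, s1_crit, s1_rev, SessionDesign(),
                           seed=11, bmap=s1_belief_map)
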