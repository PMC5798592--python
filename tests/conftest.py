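import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from actinf.discrete_model import DiscreteModel, normalize_columns

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def random_small_model(rng, n_states=None, T=None, n_policies=None,
                       n_outcomes=None, n_actions=2):
    """A random single-factor model in the |S|<=4, T<=4, <=3 policy regime."""
    n_states = n_states or int(rng.integers(2, 5))
    T = T or int(rng.integers(2, 5))
    n_policies = n_policies or int(rng.integers(1, 4))
    n_outcomes = n_outcomes or int(rng.integers(2, 5))
    A = [normalize_columns(rng.random((n_outcomes, n_states)) + 0.05)]
    B = [normalize_columns(rng.random((n_states, n_states, n_actions)) + 0.05)]
    D = [normalize_columns(rng.random(n_states) + 0.05)]
    policies = rng.integers(0, n_actions, size=(max(T - 1, 1), n_policies, 1))
    return DiscreteModel(A=A, B=B, D=D, policies=policies, T=T,
                         control_factors=(0,))


def random_observations(rng, model, p_observed=0.7):
    obs = []
    for _ in range(model.T):
        if rng.random() < p_observed:
            obs.append(tuple(int(rng.integers(0, a.shape[0]))
                             for a in model.A))
        else:
            obs.append(None)
    return obs


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
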