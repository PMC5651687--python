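import numpy as np
import pytest

from eqsim import CountingRNG, ModelParameters, NetworkState, TrialSpec, run_trial


@pytest.fixture
def params():
    return ModelParameters()


@pytest.fixture
def small_state():
    """Seven units: one trained class (A1,B1,C1) plus distractors."""
    return NetworkState(["A1", "B1", "C1", "B2", "B3", "C2", "C3"])


def solo_train(beta: float, n_trials: int, phase: str = "train", theta: float = 0.7):
    """Train one isolated pair with the correct comparison always chosen.

    A two-unit network with a single comparison option: coactivation is
    always 1 and every response is correct, so the engine should follow
    the recursion W <- W + beta_eff * (1 - W).
    """
    params = ModelParameters(beta=beta, theta=theta)
    state = NetworkState(["A", "B"])
    trial = TrialSpec(sample="A", comparisons=("B",), correct="B", phase=phase)
    rng = CountingRNG.from_seed(0)
    for _ in range(n_trials):
        state, _ = run_trial(state, trial, params, rng)
    return state


@pytest.fixture
def rng():
    return CountingRNG.from_seed(12345)
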