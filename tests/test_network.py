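"""Unit activation, spreading, and the threshold/metaplasticity update."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqsim import (
    ContractViolationError,
    ModelParameters,
    NetworkState,
    UnknownUnitError,
    apply_updates,
    gated_sigmoid,
    net_inputs,
    pair_update,
    spread_activation,
)

from conftest import solo_train


def sigmoid(x):
    # independent of the package's own implementation
    return 1.0 / (1.0 + math.exp(-x))


class TestGatedSigmoid:
    @pytest.mark.parametrize(
        "net, expected",
        [
            (0.0, 0.0),  # below the gate: silent
            (0.85, 0.0),  # gate boundary excluded (strict inequality)
            (1.0, 0.7310585786300049),  # 1/(1+e^-1)
            (0.8500001, sigmoid(0.8500001)),
            (-3.0, 0.0),
        ],
    )
    def test_values(self, net, expected, params):
        assert gated_sigmoid(net, params) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-10, 10))
    @settings(derandomize=True)
    def test_range(self, net):
        a = gated_sigmoid(net, ModelParameters())
        assert 0.0 <= a < 1.0


class TestNetInputs:
    def test_zero_weights_give_zero(self, small_state):
        small_state.activations[small_state.index("A1")] = 1.0
        assert all(v == 0.0 for v in net_inputs(small_state, {"A1"}).values())

    def test_single_source(self, small_state):
        small_state.set_weight("A1", "B1", 0.9)
        small_state.activations[small_state.index("A1")] = 1.0
        out = net_inputs(small_state, {"A1"})
        assert out["B1"] == pytest.approx(0.9)
        assert "A1" not in out

    def test_two_sources_sum(self, small_state):
        # summation across sources is what lets transitive weights climb
        # past the asymptote of a single link
        small_state.set_weight("A1", "B1", 0.95)
        small_state.set_weight("C1", "B1", 0.75)
        for u in ("A1", "C1"):
            small_state.activations[small_state.index(u)] = 1.0
        out = net_inputs(small_state, ["A1", "C1"])
        assert out["B1"] == pytest.approx(1.70)

    def test_unknown_unit(self, small_state):
        with pytest.raises(UnknownUnitError):
            net_inputs(small_state, {"Z9"})


class TestSpreadActivation:
    def test_zero_weights_spread_nothing(self, small_state, params):
        spread_activation(small_state, {"A1", "B1"}, set(), params)
        for u in ("C1", "B2", "B3", "C2", "C3"):
            assert small_state.activation(u) == 0.0
        assert small_state.activation("A1") == 1.0

    def test_single_wave_transitive_activation(self, small_state, params):
        # the mechanism behind derived-relation emergence: a trained
        # connection above the gate re-activates the absent stimulus
        small_state.set_weight("B1", "A1", 0.893)
        spread_activation(small_state, {"B1", "C1"}, {"C2", "C3"}, params)
        assert small_state.activation("A1") == pytest.approx(sigmoid(0.893))
        assert small_state.activation("C2") == 0.0
        assert small_state.activation("B2") == 0.0

    def test_gate_not_exceeded(self, small_state, params):
        small_state.set_weight("B1", "A1", 0.80)
        spread_activation(small_state, {"B1", "C1"}, set(), params)
        assert small_state.activation("A1") == 0.0

    def test_overlapping_sets_rejected(self, small_state, params):
        with pytest.raises(ContractViolationError):
            spread_activation(small_state, {"A1"}, {"A1"}, params)

    def test_fixpoint_reaches_second_hop(self, params):
        # under fixpoint propagation a newly active unit becomes a source
        state = NetworkState(["A", "B", "C"])
        state.set_weight("A", "B", 0.95)
        # chain A -> B -> C; C receives input only via B's activation
        state.set_weight("B", "C", 0.99)
        fx = params.replace(propagation="fixpoint")
        spread_activation(state, {"A"}, set(), fx)
        x_b = state.activation("B")
        assert x_b > 0.0
        # B's activation (~0.72) times 0.99 is below the gate, so C stays 0
        assert state.activation("C") == 0.0
        # single wave never activates C either, and matches on B
        state2 = NetworkState(state.labels, state.weights)
        spread_activation(state2, {"A"}, set(), params)
        assert state2.activation("B") == pytest.approx(sigmoid(0.95))

    def test_clamped_not_overwritten_by_fixpoint(self, params):
        state = NetworkState(["A", "B"])
        state.set_weight("A", "B", -0.5)
        fx = params.replace(propagation="fixpoint")
        spread_activation(state, {"A", "B"}, set(), fx)
        assert state.activation("A") == 1.0
        assert state.activation("B") == 1.0


class TestPairUpdate:
    def test_first_correct_trial_from_naive(self, params):
        pu = pair_update(0.0, 1.0, +1, "train", params)
        assert pu.lambda_value == pytest.approx(1.0)
        assert pu.delta_w == pytest.approx(0.2)

    def test_subthreshold_decay(self, params):
        pu = pair_update(0.5, 0.6, +1, "train", params)
        assert pu.lambda_value == pytest.approx(-0.5)
        assert pu.delta_w == pytest.approx(-0.025)  # 0.25 * 0.2 * (-0.5)

    def test_incorrect_feedback_pushes_negative(self, params):
        pu = pair_update(0.0, 1.0, -1, "train", params)
        assert pu.delta_w == pytest.approx(-0.2)

    def test_decay_sign_independent_of_feedback(self, params):
        # weakening below threshold is a decay toward zero either way
        assert pair_update(0.5, 0.1, -1, "train", params).delta_w == pytest.approx(
            pair_update(0.5, 0.1, +1, "train", params).delta_w
        )

    def test_test_phase_quarter_rate(self, params):
        pu = pair_update(0.9, 1.0, +1, "test", params)
        assert pu.delta_w == pytest.approx(0.05 * (1.0 - 0.9))

    def test_threshold_boundary_strengthens(self, params):
        # coactivation exactly at theta takes the strengthening branch
        pu = pair_update(0.0, 0.7, +1, "train", params)
        assert pu.lambda_value == pytest.approx(0.7)

    def test_coactivation_contract(self, params):
        with pytest.raises(ContractViolationError):
            pair_update(0.0, 1.2, +1, "train", params)


class TestApplyUpdates:
    def test_no_activity_no_change(self, small_state, params):
        before = small_state.weights.copy()
        _, updates = apply_updates(small_state, +1, "train", params)
        assert updates == []
        assert np.array_equal(small_state.weights, before)

    def test_single_clamped_pair(self, small_state, params):
        for u in ("A1", "B1"):
            small_state.activations[small_state.index(u)] = 1.0
        _, updates = apply_updates(small_state, +1, "train", params)
        assert len(updates) == 1
        assert small_state.weight("A1", "B1") == pytest.approx(0.2)

    def test_transitive_strengthening_event(self, small_state, params):
        # B1-C1 trial after A1B1 training: three pairs update at once
        small_state.set_weight("B1", "A1", 0.893)
        spread_activation(small_state, {"B1", "C1"}, {"C2", "C3"}, params)
        x_a1 = sigmoid(0.893)
        _, updates = apply_updates(small_state, +1, "train", params)
        assert {frozenset((u.unit_i, u.unit_j)) for u in updates} == {
            frozenset(("B1", "C1")),
            frozenset(("A1", "B1")),
            frozenset(("A1", "C1")),
        }
        assert small_state.weight("B1", "C1") == pytest.approx(0.2)
        assert small_state.weight("A1", "C1") == pytest.approx(0.2 * x_a1)
        assert small_state.weight("A1", "B1") == pytest.approx(
            0.893 + 0.2 * (x_a1 - 0.893)
        )

    def test_one_active_variant_decays_half_active_pairs(self, small_state):
        p = ModelParameters(pair_eligibility="one_active")
        small_state.set_weight("A1", "C1", 0.4)
        small_state.activations[small_state.index("A1")] = 1.0
        apply_updates(small_state, +1, "train", p)
        # C1 inactive: coactivation 0 < theta, so the pair decays
        assert small_state.weight("A1", "C1") == pytest.approx(0.4 - 0.25 * 0.2 * 0.4)

    def test_synchronous_from_pretrial_weights(self, params):
        # all deltas must derive from W(t), not from partially updated rows
        state = NetworkState(["A", "B", "C"])
        state.set_weight("A", "B", 0.4)
        state.set_weight("A", "C", 0.4)
        state.set_weight("B", "C", 0.4)
        state.activations[:] = 1.0
        apply_updates(state, +1, "train", params)
        for pair in (("A", "B"), ("A", "C"), ("B", "C")):
            assert state.weight(*pair) == pytest.approx(0.4 + 0.2 * (1 - 0.4))


class TestClosedFormOracle:
    @given(
        beta=st.floats(0.01, 1.0, exclude_max=False),
        t=st.integers(1, 200),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_engine_matches_recursion(self, beta, t):
        # solo correct training: W_t = 1 - (1-beta)^t, exactly
        state = solo_train(beta, t)
        expected = 1.0 - (1.0 - beta) ** t
        assert state.weight("A", "B") == pytest.approx(expected, abs=1e-12)

    def test_learning_disability_rate_45_trials(self):
        state = solo_train(0.1, 45, theta=0.72)
        w = state.weight("A", "B")
        assert w == pytest.approx(1.0 - 0.9**45, abs=1e-12)
        assert round(w, 2) == 0.99

    def test_monotone_and_bounded(self):
        prev = 0.0
        for t in range(1, 120):
            w = solo_train(0.2, t).weight("A", "B")
            assert prev < w < 1.0
            prev = w


class TestBetaZeroFreeze:
    def test_no_weight_ever_changes(self):
        for phase in ("train", "test"):
            state = solo_train(0.0, 30, phase=phase)
            assert np.all(state.weights == 0.0)


class TestDecayFixedPoint:
    def test_geometric_convergence_to_zero(self, params):
        ratio = 1.0 - params.decay_multiplier * params.beta
        w = 0.8
        for k in range(1, 200):
            w += pair_update(w, 0.3, +1, "train", params).delta_w
            assert w == pytest.approx(0.8 * ratio**k, abs=1e-12)
        assert abs(w) < 1e-4


class TestStateSerialization:
    def _state(self):
        state = NetworkState(["A1", "B1", "C1"])
        state.set_weight("A1", "B1", 1 / 3)
        state.set_weight("B1", "C1", -0.123456789012345)
        return state

    def test_csv_roundtrip_lossless(self):
        state = self._state()
        back = NetworkState.from_csv(state.to_csv())
        assert back.labels == state.labels
        assert np.max(np.abs(back.weights - state.weights)) < 1e-12

    def test_json_roundtrip_lossless(self):
        state = self._state()
        back = NetworkState.from_json(state.to_json())
        assert np.array_equal(back.weights, state.weights)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ContractViolationError):
            NetworkState(["A", "B"], np.array([[0.0, 0.5], [0.4, 0.0]]))
        with pytest.raises(ContractViolationError):
            NetworkState(["A", "B"], np.array([[0.1, 0.5], [0.5, 0.0]]))
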