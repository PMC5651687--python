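"""Core Hebbian network: gated activation, spreading, and weight updates.

The model is a single layer of fully interconnected localist units, one per
stimulus.  A symmetric weight matrix W holds the learned relatedness
(associative strength) between every pair of stimuli, bounded in
[weight_min, weight_max] and starting at zero (no prior experience).

Learning is a supervised Hebbian rule with two regimes split by the
coactivation threshold ``theta``:

* coactivation X_i*X_j >= theta  ->  LTP-like strengthening.  A
  self-adapting term lambda = X_i*X_j - W_ij scales the update, so weights
  stabilise at the coactivation level they experience (a simple form of
  metaplasticity).  Reinforcement enters as the sign of the learning rate:
  positive after correct responses, negative after errors.
* coactivation < theta  ->  LTD-like decay.  lambda = -W_ij and the update
  uses a reduced rate (``decay_multiplier`` * beta), shrinking the weight
  toward zero regardless of feedback.

Units that are not presented on a trial can still become active through
spreading activation: they sum the weighted input from the clamped units
and pass it through a sigmoid gated at ``activation_gate`` — below the gate
the unit stays silent.  Coactivation between a clamped unit and a unit that
lit up by spreading is what lets never-co-presented stimuli (transitive
relations) acquire positive weights.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ContractViolationError, UnknownUnitError

Phase = Literal["train", "test"]

#: Whether coactivation exactly equal to theta selects the strengthening
#: branch.  The update rule is stated once with ">=" and once with ">" in
#: the literature this model follows; the inclusive form governs here.
THRESHOLD_INCLUSIVE: bool = True

#: Convergence tolerance for fixpoint spreading activation.
FIXPOINT_TOL: float = 1e-9


@dataclass(frozen=True)
class ModelParameters:
    """Learning-rule and propagation parameters.

    Parameters
    ----------
    beta
        Learning rate in (0, 1]; also accepts 0 for "no plasticity"
        control runs.  Default 0.2.
    theta
        Coactivation threshold separating strengthening from decay
        (functional analogue of an LTP threshold).  Default 0.7.
    activation_gate
        Net-input cutoff of the spreading sigmoid; a unit with net input
        at or below the gate stays at 0.  Default 0.85.
    decay_multiplier
        Fraction of beta applied on the sub-threshold (decay) branch.
        Default 0.25.
    test_beta_fraction
        Multiplier on beta during test phases, where no feedback signal
        exists and only minimal weight adaptation occurs.  Default 0.25.
    weight_min, weight_max
        Hard bounds on connection values.  Defaults -1 and +1.
    pair_eligibility
        Which unit pairs receive an update on a trial: ``"both_active"``
        (strictly positive coactivation, the default) or ``"one_active"``
        (at least one unit active).
    propagation
        ``"single_wave"`` (default): one synchronous spreading wave from
        the clamped units.  ``"fixpoint"``: waves repeat, newly active
        units becoming sources, until activations stop changing.
    max_stage_repeats
        Cap on criterion-failure repetitions of a training stage.
    """

    beta: float = 0.2
    theta: float = 0.7
    activation_gate: float = 0.85
    decay_multiplier: float = 0.25
    test_beta_fraction: float = 0.25
    weight_min: float = -1.0
    weight_max: float = 1.0
    pair_eligibility: Literal["both_active", "one_active"] = "both_active"
    propagation: Literal["single_wave", "fixpoint"] = "single_wave"
    max_stage_repeats: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ContractViolationError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 < self.theta < 1.0:
            raise ContractViolationError(f"theta must be in (0, 1), got {self.theta}")
        if not 0.0 < self.decay_multiplier <= 1.0:
            raise ContractViolationError("decay_multiplier must be in (0, 1]")
        if not 0.0 < self.test_beta_fraction <= 1.0:
            raise ContractViolationError("test_beta_fraction must be in (0, 1]")
        if not self.weight_min < 0.0 < self.weight_max:
            raise ContractViolationError("weight bounds must straddle 0")
        if self.pair_eligibility not in ("both_active", "one_active"):
            raise ContractViolationError(
                f"unknown pair_eligibility {self.pair_eligibility!r}"
            )
        if self.propagation not in ("single_wave", "fixpoint"):
            raise ContractViolationError(f"unknown propagation {self.propagation!r}")
        if self.max_stage_repeats < 1:
            raise ContractViolationError("max_stage_repeats must be >= 1")

    def effective_beta(self, phase: Phase) -> float:
        """Learning rate in effect for the given phase."""
        if phase == "test":
            return self.beta * self.test_beta_fraction
        return self.beta

    def replace(self, **overrides) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class PairUpdate:
    """Audit record of one pairwise weight update."""

    unit_i: str
    unit_j: str
    coactivation: float
    lambda_value: float
    delta_w: float


class NetworkState:
    """Unit labels, symmetric weight matrix and per-trial activations.

    Weights are stored as a dense symmetric ``numpy`` array with a zero
    diagonal (a unit has no connection to itself); bidirectional
    connections carry a single value.  Activations live in [0, 1] and are
    transient trial state.
    """

    __slots__ = ("labels", "_index", "weights", "activations")

    def __init__(
        self,
        labels: Sequence[str],
        weights: np.ndarray | None = None,
        activations: np.ndarray | None = None,
    ):
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            raise ContractViolationError("unit labels must be unique")
        n = len(labels)
        if weights is None:
            weights = np.zeros((n, n), dtype=float)
        else:
            weights = np.asarray(weights, dtype=float).copy()
            if weights.shape != (n, n):
                raise ContractViolationError("weight matrix shape mismatch")
            if not np.allclose(weights, weights.T, atol=0.0):
                raise ContractViolationError("weight matrix must be symmetric")
            if np.any(np.diagonal(weights) != 0.0):
                raise ContractViolationError("weight diagonal must be zero")
        if activations is None:
            activations = np.zeros(n, dtype=float)
        else:
            activations = np.asarray(activations, dtype=float).copy()
            if activations.shape != (n,):
                raise ContractViolationError("activation vector shape mismatch")
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}
        self.weights = weights
        self.activations = activations

    # -- basic accessors ---------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise UnknownUnitError(f"unknown unit {label!r}") from None

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index(a), self.index(b)])

    def set_weight(self, a: str, b: str, value: float) -> None:
        i, j = self.index(a), self.index(b)
        if i == j:
            raise ContractViolationError("self-connections are fixed at zero")
        self.weights[i, j] = value
        self.weights[j, i] = value

    def activation(self, label: str) -> float:
        return float(self.activations[self.index(label)])

    def reset_activations(self) -> None:
        """Clear all activations to 0 (no carry-over between trials)."""
        self.activations[:] = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.labels, self.weights, self.activations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkState):
            return NotImplemented
        return (
            self.labels == other.labels
            and np.array_equal(self.weights, other.weights)
            and np.array_equal(self.activations, other.activations)
        )

    def __repr__(self) -> str:
        return f"NetworkState({len(self.labels)} units)"

    # -- serialization -----------------------------------------------------

    def to_csv(self) -> str:
        """Full symmetric weight matrix as CSV, labels as header row/column."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["", *self.labels])
        for lab, row in zip(self.labels, self.weights):
            writer.writerow([lab, *(repr(float(v)) for v in row)])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "NetworkState":
        rows = list(csv.reader(io.StringIO(text)))
        labels = rows[0][1:]
        matrix = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
        return cls(labels, matrix)

    def to_json(self) -> str:
        return json.dumps({"labels": list(self.labels), "matrix": self.weights.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "NetworkState":
        payload = json.loads(text)
        return cls(payload["labels"], np.asarray(payload["matrix"], dtype=float))


# -- operations ------------------------------------------------------------


def gated_sigmoid(net_input: float, params: ModelParameters) -> float:
    """Activation of a non-clamped unit from its net input.

    Returns ``1 / (1 + exp(-net_input))`` when the net input strictly
    exceeds ``params.activation_gate`` and 0 otherwise.  Never applied to
    clamped units (those are held at 1 directly).
    """
    if net_input > params.activation_gate:
        return 1.0 / (1.0 + math.exp(-net_input))
    return 0.0


def net_inputs(state: NetworkState, source_units: Iterable[str]) -> dict[str, float]:
    """Weighted sum of input each non-source unit receives from the sources.

    For each unit ``j`` not in ``source_units`` returns
    ``sum_i W_ij * X_i`` over the source units ``i``, using the sources'
    current activations.  Source units are excluded from the output.
    """
    src = [state.index(u) for u in source_units]
    src_set = set(src)
    contrib = state.weights[src, :].T @ state.activations[src]
    return {
        lab: float(contrib[j])
        for j, lab in enumerate(state.labels)
        if j not in src_set
    }


def spread_activation(
    state: NetworkState,
    clamped_units: Iterable[str],
    excluded_units: Iterable[str],
    params: ModelParameters,
) -> NetworkState:
    """Propagate activation from the clamped units to the rest of the layer.

    Clamped units are held at 1, excluded units (losing comparisons,
    silenced by lateral inhibition) at 0 for the whole trial.  Every other
    unit receives ``gated_sigmoid`` of its net input.  Under
    ``single_wave`` propagation exactly one synchronous wave is computed
    from the clamped units; under ``fixpoint``, waves repeat with all
    currently active units as sources until no activation changes by more
    than ``FIXPOINT_TOL``.
    """
    clamped = {state.index(u) for u in clamped_units}
    excluded = {state.index(u) for u in excluded_units}
    if clamped & excluded:
        raise ContractViolationError("clamped and excluded unit sets overlap")

    for i in clamped:
        state.activations[i] = 1.0
    for i in excluded:
        state.activations[i] = 0.0
    free = [j for j in range(state.n_units) if j not in clamped and j not in excluded]

    if params.propagation == "single_wave":
        src = sorted(clamped)
        net = state.weights[src, :].T @ state.activations[src]
        for j in free:
            state.activations[j] = gated_sigmoid(float(net[j]), params)
        return state

    # fixpoint: iterate synchronous waves over the free units
    for j in free:
        state.activations[j] = 0.0
    for _ in range(10_000):
        net = state.weights.T @ state.activations
        new = np.array([gated_sigmoid(float(net[j]), params) for j in free])
        delta = np.max(np.abs(new - state.activations[free])) if free else 0.0
        state.activations[free] = new
        if delta <= FIXPOINT_TOL:
            break
    return state


def pair_update(
    w: float,
    coactivation: float,
    feedback_sign: int,
    phase: Phase,
    params: ModelParameters,
    unit_i: str = "",
    unit_j: str = "",
) -> PairUpdate:
    """Weight change for one unit pair from its coactivation and feedback.

    Above threshold the self-adapting term ``lambda = coactivation - w``
    is scaled by the signed effective learning rate (sign from feedback
    during training, always positive during tests).  Below threshold
    ``lambda = -w`` and the change is a feedback-independent decay at
    ``decay_multiplier`` times the effective rate.
    """
    if not 0.0 <= coactivation <= 1.0:
        raise ContractViolationError(
            f"coactivation must be in [0, 1], got {coactivation}"
        )
    beta_eff = params.effective_beta(phase)
    above = (
        coactivation >= params.theta
        if THRESHOLD_INCLUSIVE
        else coactivation > params.theta
    )
    if above:
        lam = coactivation - w
        delta = feedback_sign * beta_eff * lam
    else:
        lam = -w
        delta = params.decay_multiplier * beta_eff * lam
    return PairUpdate(unit_i, unit_j, coactivation, lam, delta)


def apply_updates(
    state: NetworkState,
    feedback_sign: int,
    phase: Phase,
    params: ModelParameters,
) -> tuple[NetworkState, list[PairUpdate]]:
    """Apply the Hebbian update to every eligible unit pair, synchronously.

    Eligibility follows ``params.pair_eligibility``: under ``both_active``
    a pair updates only if both activations are strictly positive; under
    ``one_active`` one suffices.  All deltas are computed from the
    pre-trial weight matrix, then applied at once, clipped into the weight
    bounds, with symmetry restored.  Returns the state and the audit list
    of :class:`PairUpdate` records.
    """
    x = state.activations
    w0 = state.weights.copy()
    active = x > 0.0
    updates: list[PairUpdate] = []
    n = state.n_units
    for i in range(n):
        for j in range(i + 1, n):
            if params.pair_eligibility == "both_active":
                eligible = active[i] and active[j]
            else:
                eligible = active[i] or active[j]
            if not eligible:
                continue
            pu = pair_update(
                float(w0[i, j]),
                float(x[i] * x[j]),
                feedback_sign,
                phase,
                params,
                state.labels[i],
                state.labels[j],
            )
            new = float(
                np.clip(w0[i, j] + pu.delta_w, params.weight_min, params.weight_max)
            )
            state.weights[i, j] = new
            state.weights[j, i] = new
            updates.append(pu)
    return state, updates
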