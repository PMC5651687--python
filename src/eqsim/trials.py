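"""Matching-to-sample trial mechanics.

One trial: the sample unit is clamped to 1; comparison units compete on
the raw weight they receive from the sample (lateral inhibition: the
winner is clamped to 1, the losers are silenced for the whole trial);
activation spreads to the remaining layer; a feedback sign is determined
(+1 for a correct choice, -1 for an error; during test phases the model
receives no feedback, so the sign is +1 with a reduced learning rate);
and all eligible pairs update their weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractViolationError
from .network import (
    ModelParameters,
    NetworkState,
    PairUpdate,
    Phase,
    apply_updates,
    spread_activation,
)
from .rng import CountingRNG


@dataclass(frozen=True)
class TrialSpec:
    """One matching-to-sample presentation."""

    sample: str
    comparisons: tuple[str, ...]
    correct: str
    phase: Phase = "train"
    relation_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "comparisons", tuple(self.comparisons))
        if len(set(self.comparisons)) != len(self.comparisons):
            raise ContractViolationError("comparisons must be distinct")
        if self.sample in self.comparisons:
            raise ContractViolationError("sample may not appear among comparisons")
        if self.correct not in self.comparisons:
            raise ContractViolationError("correct unit must be a comparison")
        if self.phase not in ("train", "test"):
            raise ContractViolationError(f"unknown phase {self.phase!r}")


@dataclass
class TrialOutcome:
    """Result and audit trail of one executed trial."""

    chosen: str
    is_correct: bool
    active_units: dict[str, float]
    updates: list[PairUpdate] = field(default_factory=list)
    rng_draws: int = 0


def select_comparison(
    state: NetworkState,
    sample: str,
    comparisons: tuple[str, ...],
    rng: CountingRNG,
) -> str:
    """Winner of the comparison competition.

    Each comparison's score is the raw (ungated) weight it receives from
    the sample alone; the argmax wins.  Ties — including the all-zero
    naive network — are broken uniformly at random.
    """
    if not comparisons:
        raise ContractViolationError("empty comparison list")
    scores = [state.weight(sample, c) for c in comparisons]
    best = max(scores)
    winners = [c for c, s in zip(comparisons, scores) if s == best]
    if len(winners) == 1:
        return winners[0]
    return rng.choice(winners)


def run_trial(
    state: NetworkState,
    trial: TrialSpec,
    params: ModelParameters,
    rng: CountingRNG,
) -> tuple[NetworkState, TrialOutcome]:
    """Execute one full trial iteration, mutating and returning the state.

    Sequence: clear activations; clamp the sample; run the comparison
    competition; clamp the winner, silence the losers; spread activation
    over the remaining units; derive the feedback sign; apply the weight
    updates.  During test phases correctness is still logged — it is the
    experimenter's bookkeeping, not an input to the model.
    """
    draws_before = rng.draws
    state.reset_activations()
    state.activations[state.index(trial.sample)] = 1.0
    chosen = select_comparison(state, trial.sample, trial.comparisons, rng)
    losers = [c for c in trial.comparisons if c != chosen]
    spread_activation(
        state,
        clamped_units=(trial.sample, chosen),
        excluded_units=losers,
        params=params,
    )
    is_correct = chosen == trial.correct
    if trial.phase == "test":
        feedback_sign = 1  # no feedback signal reaches the model during tests
    else:
        feedback_sign = 1 if is_correct else -1
    state, updates = apply_updates(state, feedback_sign, trial.phase, params)
    outcome = TrialOutcome(
        chosen=chosen,
        is_correct=is_correct,
        active_units={
            lab: float(a)
            for lab, a in zip(state.labels, state.activations)
            if a > 0.0
        },
        updates=updates,
        rng_draws=rng.draws - draws_before,
    )
    return state, outcome
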