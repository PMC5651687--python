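"""Staged training/testing protocols: blocks, mastery criteria, repetition.

A protocol is an ordered list of stages run over a single evolving
network.  A training stage presents shuffled blocks of matching-to-sample
trials until its mastery criterion passes (weights persist across
repeated blocks — criterion failures do not roll learning back); a test
stage runs a fixed number of blocks without a criterion.  The full weight
matrix is snapshotted after every block, which is what per-epoch weight
trajectories are read from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, StageNonConvergenceError
from .network import ModelParameters, NetworkState, Phase
from .rng import CountingRNG, stage_rng
from .structures import ClassStructure, parse_relation_key
from .trials import TrialOutcome, TrialSpec, run_trial


@dataclass(frozen=True)
class StageSpec:
    """One stage: a block composition, phase, and optional pass criterion.

    ``trial_counts`` maps relation keys to repetitions within one block.
    Keys are either class-specific (``"A1B1"``) or relation-set keys
    (``"AB"``) whose count is split as evenly as possible across classes,
    remainders assigned by a seeded draw.  ``criterion`` is
    ``(min_correct, out_of)`` or ``None``; with ``consecutive=True`` the
    criterion asks for a run of consecutive correct trials instead of a
    block total.  Stages without a criterion run exactly ``blocks``
    blocks (default 1).
    """

    name: str
    trial_counts: dict[str, int]
    phase: Phase = "train"
    criterion: tuple[int, int] | None = None
    consecutive: bool = False
    shuffle: bool = True
    blocks: int = 1

    def __post_init__(self) -> None:
        if not self.trial_counts:
            raise ConfigurationError(f"stage {self.name!r} has no trials")
        for key, count in self.trial_counts.items():
            parse_relation_key(key)
            if count < 1:
                raise ConfigurationError(f"stage {self.name!r}: count for {key} < 1")
        if self.phase not in ("train", "test"):
            raise ConfigurationError(f"stage {self.name!r}: unknown phase")
        if self.criterion is not None:
            min_correct, out_of = self.criterion
            if not 0 < min_correct <= out_of:
                raise ConfigurationError(
                    f"stage {self.name!r}: criterion {min_correct}/{out_of} invalid"
                )
            if not self.consecutive and out_of != self.block_size:
                raise ConfigurationError(
                    f"stage {self.name!r}: criterion denominator {out_of} "
                    f"!= block size {self.block_size}"
                )
            if self.blocks != 1:
                raise ConfigurationError(
                    f"stage {self.name!r}: fixed block count requires no criterion"
                )
        if self.blocks < 1:
            raise ConfigurationError(f"stage {self.name!r}: blocks must be >= 1")

    @property
    def block_size(self) -> int:
        return sum(self.trial_counts.values())


@dataclass(frozen=True)
class ProtocolSpec:
    """A complete experiment: structure, parameters, stages and seed."""

    name: str
    structure: ClassStructure
    stages: tuple[StageSpec, ...]
    parameters: ModelParameters = ModelParameters()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        for stage in self.stages:
            for key in stage.trial_counts:
                parsed = parse_relation_key(key)
                if parsed[0] == "specific":
                    _, src, tgt, class_index = parsed
                    self.structure.member(src, class_index)
                    self.structure.member(tgt, class_index)
                else:
                    _, src, tgt = parsed
                    self.structure.member(src, 0)
                    self.structure.member(tgt, 0)


@dataclass
class BlockRecord:
    """Accuracy bookkeeping for one executed block."""

    stage: str
    block_index: int
    n_trials: int
    n_correct: int
    passed: bool

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials


@dataclass
class StageRecord:
    name: str
    phase: Phase
    blocks: list[BlockRecord] = field(default_factory=list)

    @property
    def blocks_attempted(self) -> int:
        return len(self.blocks)


@dataclass
class RunResult:
    """Everything a finished protocol run produced.

    ``snapshots`` holds one full weight-matrix copy per completed block,
    in execution order — for single-stage, fixed-block protocols this is
    the per-epoch weight trajectory.  ``trial_log`` is flat per-trial
    bookkeeping suitable for a DataFrame.
    """

    protocol: ProtocolSpec
    seed: int
    final_state: NetworkState
    snapshots: list[tuple[str, int, np.ndarray]]
    stage_records: list[StageRecord]
    trial_log: list[dict[str, Any]]
    outcomes: list[TrialOutcome]

    def trajectory(self, unit_a: str, unit_b: str) -> np.ndarray:
        """Weight of one pair after every completed block."""
        i = self.final_state.index(unit_a)
        j = self.final_state.index(unit_b)
        return np.array([w[i, j] for _, _, w in self.snapshots])

    def trial_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.trial_log)
        if not frame.empty:
            frame["seed"] = self.seed
        return frame

    def stage_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": rec.name,
                "phase": rec.phase,
                "block": blk.block_index,
                "n_trials": blk.n_trials,
                "n_correct": blk.n_correct,
                "accuracy": blk.accuracy,
                "passed": blk.passed,
            }
            for rec in self.stage_records
            for blk in rec.blocks
        ]
        return pd.DataFrame(rows)


# -- block construction ----------------------------------------------------


def build_block(
    stage: StageSpec, structure: ClassStructure, rng: CountingRNG
) -> list[TrialSpec]:
    """Expand a stage's trial table into one block of concrete trials.

    Relation-set keys are split as evenly as possible across classes with
    remainder classes drawn by the stage RNG; the block is shuffled
    uniformly when the stage asks for mixing.
    """
    trials: list[TrialSpec] = []
    for key, count in stage.trial_counts.items():
        parsed = parse_relation_key(key)
        if parsed[0] == "specific":
            _, src, tgt, class_index = parsed
            per_class = {class_index: count}
        else:
            _, src, tgt = parsed
            k = structure.n_classes
            per_class = {c: count // k for c in range(k)}
            remainder = count % k
            if remainder:
                for c in rng.choose_indices(k, remainder):
                    per_class[c] += 1
        for class_index, n in per_class.items():
            if n == 0:
                continue
            sample, comparisons, correct = structure.build_comparisons(
                (src, tgt), class_index
            )
            label = f"{src}{class_index + 1}{tgt}{class_index + 1}"
            trials.extend(
                TrialSpec(
                    sample=sample,
                    comparisons=comparisons,
                    correct=correct,
                    phase=stage.phase,
                    relation_label=label,
                )
                for _ in range(n)
            )
    if stage.shuffle:
        rng.shuffle(trials)
    return trials


def evaluate_criterion(
    outcomes: list[TrialOutcome],
    criterion: tuple[int, int] | None,
    consecutive: bool = False,
) -> bool:
    """Mastery check over one block.

    Per-block mode: at least ``min_correct`` correct in the block.
    Consecutive mode: some run of at least ``min_correct`` consecutive
    correct outcomes exists within the block.
    """
    if criterion is None:
        return True
    min_correct, _ = criterion
    if not consecutive:
        return sum(o.is_correct for o in outcomes) >= min_correct
    run = best = 0
    for o in outcomes:
        run = run + 1 if o.is_correct else 0
        best = max(best, run)
    return best >= min_correct


# -- execution -------------------------------------------------------------


def run_stage(
    state: NetworkState,
    stage: StageSpec,
    structure: ClassStructure,
    params: ModelParameters,
    rng: CountingRNG,
    *,
    _sink: "_RunSink | None" = None,
) -> tuple[NetworkState, StageRecord]:
    """Run one stage to completion, repeating blocks until criterion.

    Weights persist across repeated blocks.  Raises
    :class:`StageNonConvergenceError` when the criterion is still unmet
    after ``params.max_stage_repeats`` blocks.
    """
    record = StageRecord(name=stage.name, phase=stage.phase)
    sink = _sink or _RunSink()
    attempts = 0
    while True:
        attempts += 1
        block = build_block(stage, structure, rng)
        outcomes = []
        for trial in block:
            state, outcome = run_trial(state, trial, params, rng)
            outcomes.append(outcome)
            sink.log_trial(stage, attempts, trial, outcome)
        passed = evaluate_criterion(outcomes, stage.criterion, stage.consecutive)
        record.blocks.append(
            BlockRecord(
                stage=stage.name,
                block_index=attempts,
                n_trials=len(outcomes),
                n_correct=sum(o.is_correct for o in outcomes),
                passed=passed,
            )
        )
        sink.snapshot(stage.name, attempts, state)
        if stage.criterion is None:
            if attempts >= stage.blocks:
                break
        elif passed:
            break
        elif attempts >= params.max_stage_repeats:
            raise StageNonConvergenceError(stage.name, attempts)
    return state, record


class _RunSink:
    """Collects trial logs and weight snapshots across stages."""

    def __init__(self) -> None:
        self.trial_log: list[dict[str, Any]] = []
        self.outcomes: list[TrialOutcome] = []
        self.snapshots: list[tuple[str, int, np.ndarray]] = []

    def log_trial(
        self, stage: StageSpec, block: int, trial: TrialSpec, outcome: TrialOutcome
    ) -> None:
        self.trial_log.append(
            {
                "trial_index": len(self.trial_log),
                "stage": stage.name,
                "block": block,
                "phase": trial.phase,
                "sample": trial.sample,
                "comparisons": "|".join(trial.comparisons),
                "chosen": outcome.chosen,
                "correct": trial.correct,
                "correct_flag": outcome.is_correct,
                "relation_label": trial.relation_label,
                "rng_draws": outcome.rng_draws,
            }
        )
        self.outcomes.append(outcome)

    def snapshot(self, stage_name: str, block: int, state: NetworkState) -> None:
        self.snapshots.append((stage_name, block, state.weights.copy()))


def run_protocol(spec: ProtocolSpec, seed: int | None = None) -> RunResult:
    """Run every stage in order over a single evolving network state.

    Fully reproducible: the master seed spawns an independent stream per
    stage, so two runs with the same spec and seed produce bitwise
    identical results.
    """
    master_seed = spec.seed if seed is None else seed
    state = NetworkState(spec.structure.unit_labels)
    sink = _RunSink()
    stage_records = []
    for index, stage in enumerate(spec.stages):
        rng = stage_rng(master_seed, index, stage.name)
        state, record = run_stage(
            state, stage, spec.structure, spec.parameters, rng, _sink=sink
        )
        stage_records.append(record)
    return RunResult(
        protocol=spec,
        seed=master_seed,
        final_state=state,
        snapshots=sink.snapshots,
        stage_records=stage_records,
        trial_log=sink.trial_log,
        outcomes=sink.outcomes,
    )


# -- YAML serialization ----------------------------------------------------


def _criterion_to_str(stage: StageSpec) -> str | None:
    if stage.criterion is None:
        return None
    return f"{stage.criterion[0]}/{stage.criterion[1]}"


def _criterion_from_str(text: str | None) -> tuple[int, int] | None:
    if text is None:
        return None
    try:
        num, den = str(text).split("/")
        return int(num), int(den)
    except ValueError:
        raise ConfigurationError(f"cannot parse criterion {text!r}") from None


_PARAM_FIELDS = (
    "beta",
    "theta",
    "activation_gate",
    "decay_multiplier",
    "test_beta_fraction",
    "weight_min",
    "weight_max",
    "pair_eligibility",
    "propagation",
    "max_stage_repeats",
)


def protocol_to_dict(spec: ProtocolSpec) -> dict:
    return {
        "name": spec.name,
        "seed": spec.seed,
        "structure": {
            "roles": list(spec.structure.roles),
            "n_classes": spec.structure.n_classes,
            "trained_relations": [
                f"{a}{b}" for a, b in spec.structure.trained_relations
            ],
        },
        "parameters": {f: getattr(spec.parameters, f) for f in _PARAM_FIELDS},
        "stages": [
            {
                "name": s.name,
                "phase": s.phase,
                "trials": dict(s.trial_counts),
                "criterion": _criterion_to_str(s),
                "consecutive": s.consecutive,
                "shuffle": s.shuffle,
                "blocks": s.blocks,
            }
            for s in spec.stages
        ],
    }


def protocol_from_dict(payload: dict) -> ProtocolSpec:
    try:
        raw_structure = payload["structure"]
        relations = []
        for rel in raw_structure["trained_relations"]:
            if len(rel) != 2:
                raise ConfigurationError(f"bad trained relation {rel!r}")
            relations.append((rel[0], rel[1]))
        structure = ClassStructure(
            roles=tuple(raw_structure["roles"]),
            n_classes=int(raw_structure["n_classes"]),
            trained_relations=tuple(relations),
        )
        parameters = ModelParameters(**payload.get("parameters", {}))
        stages = tuple(
            StageSpec(
                name=s["name"],
                trial_counts={str(k): int(v) for k, v in s["trials"].items()},
                phase=s.get("phase", "train"),
                criterion=_criterion_from_str(s.get("criterion")),
                consecutive=bool(s.get("consecutive", False)),
                shuffle=bool(s.get("shuffle", True)),
                blocks=int(s.get("blocks", 1)),
            )
            for s in payload["stages"]
        )
        return ProtocolSpec(
            name=str(payload["name"]),
            structure=structure,
            stages=stages,
            parameters=parameters,
            seed=int(payload.get("seed", 0)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid protocol definition: {exc}") from exc


def protocol_to_yaml(spec: ProtocolSpec) -> str:
    return yaml.safe_dump(protocol_to_dict(spec), sort_keys=False)


def protocol_from_yaml(text: str) -> ProtocolSpec:
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ConfigurationError("protocol YAML must be a mapping")
    return protocol_from_dict(payload)
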