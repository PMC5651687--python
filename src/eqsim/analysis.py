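"""Summaries of finished runs: relatedness tables, nodal profiles, accuracy.

Connection weights are read as the relatedness (associative strength)
between two class members.  Because connections are bidirectional, a
symmetry relation (e.g. BA) carries the same number as its baseline
counterpart (AB), and a combined relation (CA) the same as its
transitivity counterpart (AC); tables therefore partition the undirected
within-class pairs into baseline and k-node transitivity categories and
annotate which directional categories each row also answers for.
"""

from __future__ import annotations

from typing import Iterable, Literal

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ContractViolationError
from .protocol import RunResult
from .structures import ClassStructure, parse_relation_key


def _check_structure(result: RunResult, structure: ClassStructure) -> None:
    if tuple(structure.unit_labels) != tuple(result.final_state.labels):
        raise ContractViolationError("structure does not match the run's units")


def relatedness_by_category(
    result: RunResult, structure: ClassStructure
) -> pd.DataFrame:
    """Final weight of every within-class pair, categorised by nodal distance.

    One row per unordered within-class pair: ``category`` is ``baseline``
    for directly trained pairs (nodal distance 0) and ``"{k}-node
    transitivity"`` otherwise; ``also_reported_as`` names the directional
    test category that shares the same undirected weight (symmetry for
    baseline pairs, combined for transitive ones).
    """
    _check_structure(result, structure)
    rows = []
    for class_index in range(structure.n_classes):
        for role_i, role_j in structure.within_class_role_pairs():
            a = structure.member(role_i, class_index)
            b = structure.member(role_j, class_index)
            distance = structure.nodal_distance(role_i, role_j)
            if structure.is_trained(role_i, role_j):
                category = "baseline"
                also = "symmetry"
            else:
                category = f"{distance}-node transitivity"
                also = "combined"
            rows.append(
                {
                    "category": category,
                    "distance": distance,
                    "class_index": class_index + 1,
                    "pair": f"{a}{b}",
                    "weight": result.final_state.weight(a, b),
                    "also_reported_as": also,
                }
            )
    return pd.DataFrame(rows)


def category_means(table: pd.DataFrame) -> pd.Series:
    """Mean relatedness per category, pooled across classes."""
    return table.groupby("category", sort=False)["weight"].mean()


def nodal_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Mean relatedness by nodal distance, distances ascending from 0."""
    profile = (
        table.groupby("distance", as_index=False)["weight"]
        .mean()
        .sort_values("distance", ignore_index=True)
        .rename(columns={"weight": "mean_relatedness"})
    )
    return profile


def emergence_epoch(
    result: RunResult,
    pair: tuple[str, str],
    threshold: float = 0.0,
) -> int | None:
    """First epoch (1-based block index) where a pair's weight exceeds
    ``threshold`` strictly; ``None`` if it never does."""
    trajectory = result.trajectory(*pair)
    above = np.nonzero(trajectory > threshold)[0]
    return int(above[0]) + 1 if above.size else None


def _relation_category(structure: ClassStructure, relation_label: str) -> str:
    kind, src, tgt, *_ = parse_relation_key(relation_label)
    if structure.is_trained(src, tgt):
        return (
            "baseline" if (src, tgt) in structure.trained_relations else "symmetry"
        )
    directed = nx.DiGraph(list(structure.trained_relations))
    directed.add_nodes_from(structure.roles)
    if nx.has_path(directed, src, tgt):
        return "transitivity"
    if nx.has_path(directed, tgt, src):
        return "combined"
    # no directed path either way (e.g. B-C after one-to-many AB/AC
    # training): both directions are transitivity-style tests
    return "transitivity"


def accuracy_summary(
    result: RunResult,
    grouping: Literal["stage", "relation_category"] = "stage",
    structure: ClassStructure | None = None,
) -> pd.DataFrame:
    """Percent correct per stage or per relation category.

    Correctness during test phases is judged against class membership —
    the experimenter's scoring, not a signal the model received.
    Percentages are rounded to one decimal; the raw fraction is kept in
    ``fraction_correct``.
    """
    frame = result.trial_frame()
    if frame.empty:
        return pd.DataFrame(
            columns=["group", "n_trials", "fraction_correct", "percent_correct"]
        )
    if grouping == "stage":
        frame = frame.assign(group=frame["stage"])
    elif grouping == "relation_category":
        structure = structure if structure is not None else result.protocol.structure
        frame = frame.assign(
            group=[
                _relation_category(structure, label)
                for label in frame["relation_label"]
            ]
        )
    else:
        raise ContractViolationError(f"unknown grouping {grouping!r}")
    grouped = frame.groupby("group", sort=False)["correct_flag"]
    out = grouped.agg(n_trials="size", fraction_correct="mean").reset_index()
    out["percent_correct"] = (100.0 * out["fraction_correct"]).round(1)
    return out


# -- multi-seed aggregation ------------------------------------------------


def pooled_nodal_profile(
    results: Iterable[RunResult], structure: ClassStructure
) -> pd.DataFrame:
    """Seed-mean (and sd) nodal profile over several runs of one protocol."""
    per_run = []
    for result in results:
        profile = nodal_profile(relatedness_by_category(result, structure))
        per_run.append(profile.set_index("distance")["mean_relatedness"])
    stacked = pd.concat(per_run, axis=1)
    out = pd.DataFrame(
        {
            "distance": stacked.index,
            "mean_relatedness": stacked.mean(axis=1),
            "sd_relatedness": stacked.std(axis=1, ddof=1),
            "n_runs": stacked.shape[1],
        }
    ).reset_index(drop=True)
    return out


# -- plotting (optional outputs) -------------------------------------------


def plot_trajectory(
    result: RunResult, pairs: Iterable[tuple[str, str]], path: str
) -> None:
    """Line plot of per-block weight trajectories for the given pairs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for a, b in pairs:
        ax.plot(
            np.arange(1, len(result.snapshots) + 1),
            result.trajectory(a, b),
            label=f"{a}{b}",
        )
    ax.set_xlabel("block (epoch)")
    ax.set_ylabel("connection value / relatedness")
    ax.set_ylim(-0.1, 1.0)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_nodal_profile(profile: pd.DataFrame, path: str) -> None:
    """Bar chart of mean relatedness against nodal distance."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    labels = [
        "baseline" if d == 0 else f"{d}-node" for d in profile["distance"]
    ]
    ax.bar(labels, profile["mean_relatedness"])
    ax.set_ylabel("mean relatedness")
    ax.set_ylim(0, 1.0)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
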