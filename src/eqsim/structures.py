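"""Stimulus-class algebra: members, roles, nodal distance, comparison sets.

A :class:`ClassStructure` describes parallel stimulus classes (class 1,
class 2, ...), each with one member per *role* (A, B, C, ...).  The
trained relations form a graph over roles — e.g. linear series training
A->B->C->... or one-to-many (cluster) training A->B, A->C, ... — and the
nodal distance of a pair is the number of intermediate nodal stimuli on
the shortest trained path between its roles.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from typing import Iterator, Literal

import networkx as nx

from .errors import ConfigurationError, ContractViolationError

_SPECIFIC_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])(\d+)$")
_SET_RE = re.compile(r"^([A-Za-z])([A-Za-z])$")


@dataclass(frozen=True)
class ClassStructure:
    """Parallel stimulus classes over a shared role alphabet.

    Parameters
    ----------
    roles
        Ordered role names, one stimulus per role per class.
    n_classes
        Number of parallel classes; class ``c`` contributes members
        ``f"{role}{c+1}"``.  Also the number of comparison options on a
        trial (the correct member plus same-role distractors from the
        other classes).
    trained_relations
        Ordered role pairs directly reinforced during training (the
        baseline graph).  The graph must connect every role, otherwise
        derived relations are undefined.
    """

    roles: tuple[str, ...]
    n_classes: int
    trained_relations: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "roles", tuple(self.roles))
        object.__setattr__(
            self,
            "trained_relations",
            tuple((a, b) for a, b in self.trained_relations),
        )
        if len(set(self.roles)) != len(self.roles):
            raise ConfigurationError("roles must be unique within a class")
        if self.n_classes < 1:
            raise ConfigurationError("need at least one class")
        for a, b in self.trained_relations:
            if a not in self.roles or b not in self.roles:
                raise ConfigurationError(f"trained relation {a}{b} uses unknown roles")
            if a == b:
                raise ConfigurationError("a relation needs two distinct roles")
        if len(self.roles) > 1 and not nx.is_connected(self.role_graph()):
            raise ConfigurationError(
                "trained-relation graph must connect every role"
            )

    # -- membership --------------------------------------------------------

    @property
    def n_comparisons(self) -> int:
        return self.n_classes

    def member(self, role: str, class_index: int) -> str:
        if role not in self.roles:
            raise ConfigurationError(f"unknown role {role!r}")
        if not 0 <= class_index < self.n_classes:
            raise ConfigurationError(f"class index {class_index} out of range")
        return f"{role}{class_index + 1}"

    @property
    def classes(self) -> list[list[str]]:
        return [
            [self.member(r, c) for r in self.roles] for c in range(self.n_classes)
        ]

    @property
    def unit_labels(self) -> list[str]:
        """All stimulus units, class-major (A1, B1, ..., A2, B2, ...)."""
        return [m for cls in self.classes for m in cls]

    def role_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.roles)
        g.add_edges_from(self.trained_relations)
        return g

    def is_trained(self, role_i: str, role_j: str) -> bool:
        return (role_i, role_j) in self.trained_relations or (
            role_j,
            role_i,
        ) in self.trained_relations

    def within_class_role_pairs(self) -> Iterator[tuple[str, str]]:
        """Unordered role pairs (i < j in role order) within one class."""
        for i, a in enumerate(self.roles):
            for b in self.roles[i + 1 :]:
                yield a, b

    # -- operations --------------------------------------------------------

    def nodal_distance(self, role_i: str, role_j: str) -> int:
        """Number of intermediate nodal stimuli between two roles.

        Shortest-path length in the undirected trained-relation graph
        minus one: 0 for directly trained pairs, k for k-node transitive
        pairs.
        """
        if role_i not in self.roles or role_j not in self.roles:
            raise ConfigurationError(f"unknown roles {role_i!r}, {role_j!r}")
        if role_i == role_j:
            raise ContractViolationError("nodal distance needs two distinct roles")
        try:
            length = nx.shortest_path_length(self.role_graph(), role_i, role_j)
        except nx.NetworkXNoPath:
            raise ContractViolationError(
                f"roles {role_i} and {role_j} are not connected by training"
            ) from None
        return length - 1

    def build_comparisons(
        self, relation: tuple[str, str], class_index: int
    ) -> tuple[str, tuple[str, ...], str]:
        """Sample, comparison set and correct answer for one relation.

        The sample is the source-role member of the given class; the
        comparisons are the target-role members of every class (the
        correct one plus same-role distractors); the correct answer is
        the target-role member of the same class.
        """
        src, tgt = relation
        if self.n_classes < 2:
            raise ConfigurationError(
                "need at least two classes to provide distractor comparisons"
            )
        sample = self.member(src, class_index)
        comparisons = tuple(self.member(tgt, c) for c in range(self.n_classes))
        correct = self.member(tgt, class_index)
        return sample, comparisons, correct


def parse_relation_key(key: str) -> tuple:
    """Parse a relation key from a stage's trial table.

    ``"A1B1"`` names one class-specific relation (sample role A of class
    1 to comparison role B of class 1); ``"AB"`` names the relation set
    across all classes, whose trial count is split between them.
    """
    m = _SPECIFIC_RE.match(key)
    if m:
        src, sc, tgt, tc = m.groups()
        if sc != tc:
            raise ConfigurationError(
                f"relation {key!r} crosses classes; within-class relations only"
            )
        return ("specific", src, tgt, int(sc) - 1)
    m = _SET_RE.match(key)
    if m:
        return ("set", m.group(1), m.group(2))
    raise ConfigurationError(f"cannot parse relation key {key!r}")


def generate_structure(
    topology: Literal["linear_series", "one_to_many"],
    n_classes: int,
    n_members: int,
) -> ClassStructure:
    """Canonical training structure for protocol exploration.

    ``linear_series`` trains A->B, B->C, ...; ``one_to_many`` (cluster
    training) trains A->B, A->C, ... from the single node A.
    """
    if n_classes < 2:
        raise ConfigurationError("need at least two classes (degenerate size)")
    if n_members < 2:
        raise ConfigurationError("need at least two members per class")
    if n_members > len(string.ascii_uppercase):
        raise ConfigurationError("at most 26 members per class supported")
    roles = tuple(string.ascii_uppercase[:n_members])
    if topology == "linear_series":
        trained = tuple((roles[i], roles[i + 1]) for i in range(n_members - 1))
    elif topology == "one_to_many":
        trained = tuple((roles[0], r) for r in roles[1:])
    else:
        raise ConfigurationError(f"unknown topology {topology!r}")
    return ClassStructure(roles=roles, n_classes=n_classes, trained_relations=trained)
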