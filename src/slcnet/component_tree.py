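"""Component tree: nested connected components under a threshold sweep.

Starting from a high score threshold (default 3.0) the threshold is lowered
in fixed steps (default 0.1, 27 levels, ending at 0.4).  At each level the
connected components of the subgraph induced by nodes with score >= the
threshold are recorded.  Because nodes only ever enter as the threshold
drops, components are nested: every component at a higher threshold lies
inside exactly one component at any lower threshold.  The resulting
hierarchy is the component tree; a *branch* is the chain of containing
components from a top-level seed (a component born entirely from fresh
nodes) down to the lowest level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx

from .scoring import ScoredNetwork

__all__ = [
    "Component",
    "Branch",
    "ComponentTree",
    "build_component_tree",
    "enumerate_branches",
    "DEFAULT_START",
    "DEFAULT_STEP",
    "DEFAULT_N_LEVELS",
]

DEFAULT_START = 3.0
DEFAULT_STEP = 0.1
DEFAULT_N_LEVELS = 27  # thresholds 3.0, 2.9, ..., 0.4


@dataclass
class Component:
    """A maximal connected set of above-threshold nodes.

    A node set persisting unchanged across consecutive levels is represented
    by a single Component whose ``levels`` records every threshold at which
    it appears; ``birth_threshold`` is the highest of these.
    """

    id: int
    node_ids: frozenset[str]
    birth_threshold: float
    levels: list[float] = field(default_factory=list)
    parent: int | None = None
    children: list[int] = field(default_factory=list)

    @property
    def is_seed(self) -> bool:
        """True when born from nodes none of which were in an earlier component."""
        return not self.children

    def __len__(self) -> int:
        return len(self.node_ids)


@dataclass
class Branch:
    """Chain of nested components from a seed down to the bottom level.

    ``components`` has one entry per level from the seed's birth level to the
    last level (a persisting component appears once per level it spans), with
    the matching thresholds in ``thresholds``.
    """

    seed: Component
    components: list[Component]
    thresholds: list[float]

    def distinct_components(self) -> list[Component]:
        out: list[Component] = []
        for comp in self.components:
            if not out or comp.id != out[-1].id:
                out.append(comp)
        return out


class ComponentTree:
    def __init__(
        self,
        scored: ScoredNetwork,
        thresholds: Sequence[float],
        components: list[Component],
        level_members: list[list[int]],
    ):
        self.scored = scored
        self.thresholds: list[float] = list(thresholds)
        self.components: dict[int, Component] = {c.id: c for c in components}
        # component ids present at each level index
        self._level_members = level_members

    @property
    def components_by_level(self) -> dict[float, list[Component]]:
        return {
            theta: [self.components[i] for i in ids]
            for theta, ids in zip(self.thresholds, self._level_members)
        }

    def components_at(self, level_index: int) -> list[Component]:
        return [self.components[i] for i in self._level_members[level_index]]

    def seeds(self) -> list[Component]:
        return [c for c in self.components.values() if c.is_seed]

    def __iter__(self) -> Iterator[Component]:
        return iter(self.components.values())

    def __len__(self) -> int:
        return len(self.components)


def build_component_tree(
    scored: ScoredNetwork,
    start: float = DEFAULT_START,
    step: float = DEFAULT_STEP,
    n_levels: int = DEFAULT_N_LEVELS,
) -> ComponentTree:
    """Sweep the threshold downward and record the component hierarchy.

    At level n the threshold is ``start - n*step``; components are the
    connected components of the subgraph induced by nodes scoring at or
    above it.  Nodes scoring below the final threshold appear nowhere.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    for node_id, score in scored.node_scores.items():
        if math.isnan(score):
            raise ValueError(f"NaN score for node {node_id!r}")

    thresholds = [start - n * step for n in range(n_levels)]
    graph = scored.network.graph
    components: list[Component] = []
    level_members: list[list[int]] = []
    node_comp: dict[str, int] = {}  # membership at the previous level

    for theta in thresholds:
        active = [i for i, e in scored.node_scores.items() if e >= theta]
        sub = graph.subgraph(active)
        new_node_comp: dict[str, int] = {}
        member_ids: list[int] = []
        for node_set in nx.connected_components(sub):
            node_set = frozenset(node_set)
            prev_ids = sorted({node_comp[n] for n in node_set if n in node_comp})
            if len(prev_ids) == 1 and components[prev_ids[0]].node_ids == node_set:
                comp = components[prev_ids[0]]  # unchanged: extend level range
                comp.levels.append(theta)
            else:
                comp = Component(
                    id=len(components),
                    node_ids=node_set,
                    birth_threshold=theta,
                    levels=[theta],
                    children=prev_ids,
                )
                components.append(comp)
                for child_id in prev_ids:
                    components[child_id].parent = comp.id
            member_ids.append(comp.id)
            for n in node_set:
                new_node_comp[n] = comp.id
        node_comp = new_node_comp
        level_members.append(sorted(member_ids))

    return ComponentTree(scored, thresholds, components, level_members)


def enumerate_branches(tree: ComponentTree) -> list[Branch]:
    """One branch per top-level seed, from its birth level to the bottom.

    Branches from seeds that later merge share their lower segments.  The
    chain has one entry per level, so a component spanning several levels is
    reported once per level (faithful traceback semantics).
    """
    if not tree.components:
        return []
    # node -> containing component id, per level
    per_level_membership: list[dict[str, int]] = []
    for idx in range(len(tree.thresholds)):
        membership: dict[str, int] = {}
        for comp in tree.components_at(idx):
            for n in comp.node_ids:
                membership[n] = comp.id
        per_level_membership.append(membership)

    level_of = {round(t, 9): i for i, t in enumerate(tree.thresholds)}
    branches: list[Branch] = []
    for seed in sorted(tree.seeds(), key=lambda c: c.id):
        rep = next(iter(seed.node_ids))
        start_idx = level_of[round(seed.birth_threshold, 9)]
        chain = [
            tree.components[per_level_membership[idx][rep]]
            for idx in range(start_idx, len(tree.thresholds))
        ]
        branches.append(
            Branch(seed=seed, components=chain,
                   thresholds=tree.thresholds[start_idx:])
        )
    return branches
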