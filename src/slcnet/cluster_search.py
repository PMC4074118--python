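"""Branch-optimal cluster selection with the F = sum(e)/sqrt(N) score.

Each component G of the tree is scored by F(G) = (sum of member node
scores) / sqrt(|G|), the subnetwork score used in differential network
analysis: it rewards total signal while penalising size.  Walking each
branch of the component tree top-down, the component with the largest F
(and F > 0) is the branch optimum; the optima pooled over branches, with
exact duplicates merged and strict subsets of another optimum dropped,
form the tissue-specific cluster set for the organ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Set

from .component_tree import Component, ComponentTree, enumerate_branches
from .scoring import ScoredNetwork

__all__ = [
    "TissueClusterSet",
    "PredefinedGroup",
    "component_score",
    "select_optimal_clusters",
    "score_predefined_group",
]


def component_score(node_ids: Set[str], scored: ScoredNetwork) -> float:
    """F(G) = sum of node scores / sqrt(number of nodes)."""
    if not node_ids:
        raise ValueError("F is undefined for an empty node set")
    missing = set(node_ids) - set(scored.node_scores)
    if missing:
        raise KeyError(f"unknown node id(s): {sorted(missing)[:5]}")
    total = sum(scored.node_scores[i] for i in node_ids)
    return total / math.sqrt(len(node_ids))


@dataclass
class TissueClusterSet:
    """Selected branch-optimal clusters for one organ."""

    organ: str
    clusters: list[Component] = field(default_factory=list)
    #: cluster id -> branch seed ids whose optimum it was
    provenance: dict[int, list[int]] = field(default_factory=dict)

    def node_sets(self) -> list[frozenset[str]]:
        return [c.node_ids for c in self.clusters]

    def largest(self) -> Component | None:
        if not self.clusters:
            return None
        return max(self.clusters, key=len)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


@dataclass(frozen=True)
class PredefinedGroup:
    """A curated reaction sequence (e.g. glycolysis) used for validation."""

    name: str
    description: str = ""
    reaction_ids: frozenset[str] = frozenset()
    summary: str = ""


def select_optimal_clusters(
    tree: ComponentTree, scored: ScoredNetwork
) -> TissueClusterSet:
    """Pick the F-maximal component of every branch and pool the optima.

    Ties along a branch break toward the smaller (higher-threshold)
    component, the more organ-specific choice.  Only components with F > 0
    qualify; a branch whose best F <= 0 contributes nothing.  In the pooled
    set, exact duplicates are merged; when two branches' optima are nested,
    the one with the larger F is kept (a low-score absorbing component never
    displaces a higher-scoring cluster inside it — consistent with the
    F-optimality that drives the per-branch search, where an absorbing
    component replaces its sub-cluster exactly when its F is larger).
    """
    selected: dict[int, Component] = {}
    provenance: dict[int, list[int]] = {}
    for branch in enumerate_branches(tree):
        best: Component | None = None
        best_f = 0.0  # only F > 0 can be selected
        for comp in branch.distinct_components():  # top-down: ties keep smaller
            f = component_score(comp.node_ids, scored)
            if f > best_f:
                best, best_f = comp, f
        if best is None:
            continue
        selected[best.id] = best
        provenance.setdefault(best.id, []).append(branch.seed.id)

    # resolve nested branch optima: highest F wins; at equal F the smaller
    # (more specific) set wins
    order = sorted(
        selected.values(),
        key=lambda c: (-component_score(c.node_ids, scored), len(c), c.id),
    )
    kept: dict[int, Component] = {}
    for comp in order:
        if any(
            comp.node_ids < other.node_ids or other.node_ids < comp.node_ids
            for other in kept.values()
        ):
            continue
        kept[comp.id] = comp
    clusters = sorted(kept.values(), key=lambda c: c.id)
    return TissueClusterSet(
        organ=scored.organ,
        clusters=clusters,
        provenance={cid: provenance[cid] for cid in kept},
    )


def score_predefined_group(
    group: PredefinedGroup, scored: ScoredNetwork
) -> float:
    """F of a curated reaction group (no connectivity requirement)."""
    unknown = set(group.reaction_ids) - set(scored.node_scores)
    if unknown:
        raise KeyError(
            f"group {group.name!r}: unresolvable reaction id(s) "
            f"{sorted(unknown)}"
        )
    return component_score(group.reaction_ids, scored)


def resolve_groups(
    groups: Iterable[PredefinedGroup], scored: ScoredNetwork
) -> dict[str, float]:
    """Score every predefined group, keyed by group name."""
    return {g.name: score_predefined_group(g, scored) for g in groups}
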