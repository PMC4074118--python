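"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's code paths: edges come
from an O(n^2) pairwise set-intersection check, per-threshold components
from a hand-rolled BFS flood fill, and branch optima from an exhaustive
walk over the flood-fill output.  They define correctness for the
efficient implementations under test.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from slcnet.network import (
    ENZYMATIC,
    TRANSPORT,
    ReactionNode,
    ReferenceNetwork,
)
from slcnet.scoring import ScoredNetwork

# ------------------------------------------------------------------ oracles


def oracle_edges(
    nodes: list[ReactionNode], currency: set[str] = frozenset()
) -> set[frozenset[str]]:
    """Brute-force pairwise shared-metabolite edge check."""
    edges = set()
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if (a.metabolites & b.metabolites) - set(currency):
                edges.add(frozenset({a.id, b.id}))
    return edges


def oracle_adjacency(
    nodes: list[ReactionNode], currency: set[str] = frozenset()
) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n.id: set() for n in nodes}
    for e in oracle_edges(nodes, currency):
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    return adj


def flood_fill_components(
    scored: ScoredNetwork, threshold: float
) -> set[frozenset[str]]:
    """Connected components of {score >= threshold} by BFS flood fill."""
    nodes = list(scored.network.nodes.values())
    adj = oracle_adjacency(nodes, set(scored.network.currency))
    active = {i for i, e in scored.node_scores.items() if e >= threshold}
    seen: set[str] = set()
    comps: set[frozenset[str]] = set()
    for start in active:
        if start in seen:
            continue
        queue, comp = [start], {start}
        seen.add(start)
        while queue:
            cur = queue.pop()
            for nb in adj[cur]:
                if nb in active and nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.add(frozenset(comp))
    return comps


def oracle_f(node_ids, scored: ScoredNetwork) -> float:
    return sum(scored.node_scores[i] for i in node_ids) / math.sqrt(len(node_ids))


def oracle_branch_optima(
    scored: ScoredNetwork,
    thresholds: list[float],
) -> list[frozenset[str]]:
    """Exhaustive per-branch F-argmax from flood-fill levels.

    Seeds are components born entirely from fresh nodes; each branch walks
    the unique containing component per level; the F-argmax (F > 0, ties to
    the higher threshold / smaller set) is the branch optimum.  Nested or
    duplicate optima resolve toward the larger F (ties toward the smaller
    set).
    """
    levels = [flood_fill_components(scored, t) for t in thresholds]
    seen_nodes: set[str] = set()
    seeds: list[tuple[int, frozenset[str]]] = []
    for li, comps in enumerate(levels):
        for comp in comps:
            if not (comp & seen_nodes):
                seeds.append((li, comp))
        for comp in comps:
            seen_nodes |= comp
    optima: list[frozenset[str]] = []
    for li, seed in seeds:
        rep = next(iter(seed))
        best, best_f = None, 0.0
        prev = None
        for comps in levels[li:]:
            comp = next(c for c in comps if rep in c)
            if comp == prev:
                continue
            prev = comp
            f = oracle_f(comp, scored)
            if f > best_f:
                best, best_f = comp, f
        if best is not None:
            optima.append(best)
    # dedup + nested resolution: larger F wins, then smaller set
    optima = sorted(
        set(optima), key=lambda c: (-oracle_f(c, scored), len(c), sorted(c))
    )
    kept: list[frozenset[str]] = []
    for comp in optima:
        if any(comp < other or other < comp for other in kept):
            continue
        kept.append(comp)
    return kept


# --------------------------------------------------------------- generators


def random_nodes(
    rng: np.random.Generator,
    n_nodes: int = 30,
    n_metabolites: int = 40,
    transport_fraction: float = 0.2,
) -> list[ReactionNode]:
    """Random reaction rows, independent of the synthetic_data module."""
    nodes = []
    for i in range(n_nodes):
        is_transport = rng.random() < transport_fraction
        if is_transport:
            mets = frozenset({f"m{int(rng.integers(n_metabolites))}"})
        else:
            k = int(rng.integers(2, 4))
            mets = frozenset(
                f"m{j}" for j in rng.choice(n_metabolites, size=k, replace=False)
            )
        nodes.append(
            ReactionNode(
                id=f"n{i:03d}",
                kind=TRANSPORT if is_transport else ENZYMATIC,
                metabolites=mets,
                genes=frozenset({f"g{i}"}),
                reversible=is_transport,
            )
        )
    return nodes


def random_scored_network(
    rng: np.random.Generator,
    n_nodes: int = 30,
    n_metabolites: int = 40,
    sigma: float = 1.5,
) -> ScoredNetwork:
    nodes = random_nodes(rng, n_nodes=n_nodes, n_metabolites=n_metabolites)
    network = ReferenceNetwork(nodes)
    scores = {n.id: float(s) for n, s in zip(nodes, rng.normal(0, sigma, n_nodes))}
    return ScoredNetwork(network, "organ1", scores)


# ----------------------------------------------------------------- fixtures


@pytest.fixture
def toy_triplet() -> list[ReactionNode]:
    """E1 (A->B), E2 (B->C) and transport T_A carrying A."""
    return [
        ReactionNode("E1", ENZYMATIC, frozenset({"A", "B"}), frozenset({"g1"})),
        ReactionNode("E2", ENZYMATIC, frozenset({"B", "C"}), frozenset({"g2"})),
        ReactionNode(
            "T_A", TRANSPORT, frozenset({"A"}), frozenset({"SlcA"}),
            reversible=True,
        ),
    ]


@pytest.fixture
def path_scored() -> ScoredNetwork:
    """Path A-B-C-D with scores (3.0, 0.5, 2.0, 1.9)."""
    nodes = [
        ReactionNode("A", ENZYMATIC, frozenset({"mAB"}), frozenset({"gA"})),
        ReactionNode("B", ENZYMATIC, frozenset({"mAB", "mBC"}), frozenset({"gB"})),
        ReactionNode("C", ENZYMATIC, frozenset({"mBC", "mCD"}), frozenset({"gC"})),
        ReactionNode("D", ENZYMATIC, frozenset({"mCD"}), frozenset({"gD"})),
    ]
    network = ReferenceNetwork(nodes)
    return ScoredNetwork(
        network, "liver", {"A": 3.0, "B": 0.5, "C": 2.0, "D": 1.9}
    )
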