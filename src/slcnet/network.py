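"""Reference metabolism/transport network.

The reference network integrates enzymatic reactions and Slc-mediated
plasma-membrane transport processes into a single undirected graph.  Nodes
are reactions (enzymatic or transport); two nodes are joined by an edge
whenever they share at least one non-currency metabolite.  Currency
metabolites (ATP, H2O, NAD+, ...) are excluded from edge construction
because they would otherwise collapse the graph into a single component;
they remain listed on the nodes themselves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "DEFAULT_CURRENCY_METABOLITES",
    "Metabolite",
    "ReactionNode",
    "ReferenceNetwork",
    "build_reference_network",
    "node_neighbors",
]

#: Ubiquitous cofactors excluded from edge construction by default.  Keys are
#: KEGG compound identifiers; comments give the common name.
DEFAULT_CURRENCY_METABOLITES: frozenset[str] = frozenset(
    {
        "C00001",  # H2O
        "C00002",  # ATP
        "C00008",  # ADP
        "C00003",  # NAD+
        "C00004",  # NADH
        "C00006",  # NADP+
        "C00005",  # NADPH
        "C00011",  # CO2
        "C00009",  # orthophosphate
        "C00010",  # CoA
        "C00007",  # O2
        "C00080",  # H+
    }
)

#: The seven compound categories used to partition transportable metabolites.
METABOLITE_CATEGORIES: tuple[str, ...] = (
    "carbohydrate",
    "hormone/transmitter",
    "lipid",
    "nucleic-acid",
    "organic-acid",
    "amino-acid",
    "steroid",
    "uncategorized",
)

ENZYMATIC = "enzymatic"
TRANSPORT = "transport"


@dataclass(frozen=True)
class Metabolite:
    """A small-molecule compound referenced by reactions and transports."""

    id: str
    name: str = ""
    category: str = "uncategorized"
    is_slc_transportable: bool = False
    is_currency: bool = False

    def __post_init__(self) -> None:
        if self.category not in METABOLITE_CATEGORIES:
            raise ValueError(
                f"unknown metabolite category {self.category!r} for {self.id}; "
                f"expected one of {METABOLITE_CATEGORIES}"
            )


@dataclass(frozen=True)
class ReactionNode:
    """One reaction node: an enzymatic reaction or an Slc-mediated transport.

    ``metabolites`` holds the main substrates and products for enzymatic
    reactions, and the transported solute(s) for transport nodes (the
    extracellular/intracellular pair collapses to one compound id).
    ``genes`` holds the catalysing enzymes or mediating Slcs (OR semantics:
    isozymes and alternative Slcs).
    """

    id: str
    kind: str
    metabolites: frozenset[str]
    genes: frozenset[str]
    reversible: bool = False
    pathway_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.kind not in (ENZYMATIC, TRANSPORT):
            raise ValueError(f"node {self.id}: kind must be enzymatic/transport")
        if not self.genes:
            raise ValueError(f"node {self.id}: gene set is empty")
        if not self.metabolites:
            raise ValueError(f"node {self.id}: metabolite set is empty")
        if self.kind == TRANSPORT and not self.reversible:
            # Slc-mediated transport is treated as reversible.
            object.__setattr__(self, "reversible", True)


class ReferenceNetwork:
    """Undirected shared-metabolite graph over reaction/transport nodes."""

    def __init__(self, nodes: Iterable[ReactionNode], currency: Iterable[str] = ()):
        self.currency: frozenset[str] = frozenset(currency)
        self.nodes: dict[str, ReactionNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise ValueError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
        # metabolite -> ids of nodes that touch it (currency included; the
        # exclusion applies only to edge construction)
        self.metabolite_index: dict[str, set[str]] = {}
        for node in self.nodes.values():
            for met in node.metabolites:
                self.metabolite_index.setdefault(met, set()).add(node.id)
        self.graph = nx.Graph()
        self.graph.add_nodes_from(self.nodes)
        for met, ids in self.metabolite_index.items():
            if met in self.currency:
                continue
            for a, b in itertools.combinations(sorted(ids), 2):
                self.graph.add_edge(a, b)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def transport_nodes(self) -> list[ReactionNode]:
        return [n for n in self.nodes.values() if n.kind == TRANSPORT]

    def enzymatic_nodes(self) -> list[ReactionNode]:
        return [n for n in self.nodes.values() if n.kind == ENZYMATIC]

    def subgraph(self, node_ids: Iterable[str]) -> nx.Graph:
        return self.graph.subgraph(node_ids)


def _dedup_key(node: ReactionNode) -> tuple:
    return (node.kind, node.metabolites, node.genes)


def build_reference_network(
    enzymatic_reactions: Iterable[ReactionNode],
    transports: Iterable[ReactionNode],
    currency_metabolites: Iterable[str] = DEFAULT_CURRENCY_METABOLITES,
    metabolite_registry: Mapping[str, Metabolite] | None = None,
) -> ReferenceNetwork:
    """Integrate enzymatic reactions and Slc transports into one network.

    Exact-duplicate reaction definitions (same kind, metabolite set and gene
    set) are merged into one node, keeping the first id.  When a
    ``metabolite_registry`` is supplied, transport rows referencing unknown
    compound ids are rejected.

    Raises
    ------
    ValueError
        for rows with empty gene or metabolite sets (named by row id), or
        unknown transported compounds when a registry is given.
    """
    seen: dict[tuple, str] = {}
    unique: list[ReactionNode] = []
    for node in itertools.chain(enzymatic_reactions, transports):
        if metabolite_registry is not None and node.kind == TRANSPORT:
            unknown = node.metabolites - set(metabolite_registry)
            if unknown:
                raise ValueError(
                    f"transport {node.id!r} references unknown compound id(s) "
                    f"{sorted(unknown)}"
                )
        key = _dedup_key(node)
        if key in seen:
            continue
        seen[key] = node.id
        unique.append(node)
    return ReferenceNetwork(unique, currency=currency_metabolites)


def node_neighbors(network: ReferenceNetwork, node_id: str) -> set[str]:
    """Nodes sharing a non-currency metabolite with ``node_id``."""
    if node_id not in network.nodes:
        raise KeyError(f"unknown node id {node_id!r}")
    return set(network.graph.neighbors(node_id))
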