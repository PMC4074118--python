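"""Synthetic reaction/transport networks with planted high-score clusters.

The generator emulates the shape of the real inputs — a sparse
shared-metabolite reaction graph with a configurable fraction of transport
nodes, median-centered (hence zero-centered Gaussian) background scores,
and planted connected clusters whose member scores are shifted upward — so
every pipeline stage is testable without any external download.  It does
not attempt realistic metabolic topology (no scale-free degree fitting, no
KEGG mimicry).

Defaults mirror the benchmark conditions used throughout the test suite:
a 200-node network (185 enzymatic + 15 transport), background scores
Normal(0, 0.5) and one planted 15-node cluster shifted by +3.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import (
    ENZYMATIC,
    TRANSPORT,
    ReactionNode,
    ReferenceNetwork,
    build_reference_network,
)
from .scoring import ExpressionDataset, GeneScoreTable, ScoredNetwork

__all__ = [
    "SyntheticSpec",
    "planted_node_ids",
    "generate_network",
    "generate_scores",
    "generate_organ_scores",
    "expression_from_scores",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic network + score draw.

    ``planted`` lists (size, score_shift) pairs; each planted cluster is a
    chain of nodes connected through dedicated linker metabolites, ending in
    one transport node when ``transport_in_planted`` is set (so the
    classification and connectivity stages see coupled transports).
    Generation is fully determined by ``seed``.
    """

    n_enzymatic: int = 185
    n_transport: int = 15
    n_metabolites: int = 300
    metabolites_per_reaction: tuple[int, int] = (2, 3)
    background_sigma: float = 0.5
    planted: tuple[tuple[int, float], ...] = ((15, 3.0),)
    seed: int = 0
    transport_in_planted: bool = True
    multi_gene_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.background_sigma <= 0:
            raise ValueError("background_sigma must be > 0")
        lo, hi = self.metabolites_per_reaction
        if not (1 <= lo <= hi):
            raise ValueError("invalid metabolites_per_reaction range")
        n_nodes = self.n_enzymatic + self.n_transport
        if sum(size for size, _ in self.planted) > n_nodes:
            raise ValueError("planted cluster sizes exceed the node count")
        for size, _ in self.planted:
            if size < 1:
                raise ValueError("planted cluster size must be >= 1")

    @property
    def n_nodes(self) -> int:
        return self.n_enzymatic + self.n_transport


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def _met_id(i: int) -> str:
    return f"M{i:05d}"


def planted_node_ids(spec: SyntheticSpec) -> list[frozenset[str]]:
    """The node ids of each planted cluster (pure function of the spec)."""
    out: list[frozenset[str]] = []
    enz_cursor = 0
    for j, (size, _) in enumerate(spec.planted):
        use_transport = (
            spec.transport_in_planted and size >= 2 and j < spec.n_transport
        )
        n_enz = size - 1 if use_transport else size
        members = [f"E{enz_cursor + k:05d}" for k in range(n_enz)]
        enz_cursor += n_enz
        if use_transport:
            members.append(f"T{j:04d}")
        out.append(frozenset(members))
    return out


def generate_network(spec: SyntheticSpec) -> ReferenceNetwork:
    """Draw a random shared-metabolite network with planted connected chains.

    Enzymatic nodes draw their metabolites uniformly from the registry;
    each transport node carries exactly one transportable compound drawn
    uniformly (two transports may collide on a compound and thereby share
    an edge).  Planted members are then rewired into a chain by giving each
    member one metabolite of its predecessor.
    """
    rng = _rng(spec, 0)
    registry = [_met_id(i) for i in range(spec.n_metabolites)]
    lo, hi = spec.metabolites_per_reaction

    enz_nodes: dict[str, set[str]] = {}
    for i in range(spec.n_enzymatic):
        k = int(rng.integers(lo, hi + 1))
        mets = set(rng.choice(spec.n_metabolites, size=k, replace=False))
        enz_nodes[f"E{i:05d}"] = {_met_id(m) for m in mets}

    transport_compound: dict[str, str] = {
        f"T{i:04d}": _met_id(int(rng.integers(spec.n_metabolites)))
        for i in range(spec.n_transport)
    }

    # rewire planted members into connected chains via shared metabolites
    for members in planted_node_ids(spec):
        chain = sorted(members)  # enzymatic first, transport (T...) last
        for prev, cur in zip(chain, chain[1:]):
            prev_mets = (
                enz_nodes[prev]
                if prev.startswith("E")
                else {transport_compound[prev]}
            )
            linker = sorted(prev_mets)[0]
            if cur.startswith("E"):
                enz_nodes[cur].add(linker)
            else:
                transport_compound[cur] = linker

    def genes_for(node_id: str) -> frozenset[str]:
        genes = {f"g_{node_id}"}
        if spec.multi_gene_prob > 0 and rng.random() < spec.multi_gene_prob:
            genes.add(f"g2_{node_id}")
        return frozenset(genes)

    enzymatic = [
        ReactionNode(
            id=node_id,
            kind=ENZYMATIC,
            metabolites=frozenset(mets),
            genes=genes_for(node_id),
            reversible=bool(rng.integers(2)),
        )
        for node_id, mets in enz_nodes.items()
    ]
    transports = [
        ReactionNode(
            id=node_id,
            kind=TRANSPORT,
            metabolites=frozenset({compound}),
            genes=genes_for(node_id),
            reversible=True,
        )
        for node_id, compound in transport_compound.items()
    ]
    # synthetic registries carry no currency metabolites
    return build_reference_network(enzymatic, transports, currency_metabolites=())


def _draw_scores(
    network: ReferenceNetwork,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    planted_active: Sequence[frozenset[str]],
) -> dict[str, float]:
    shift_of: dict[str, float] = {}
    for members, (_, shift) in zip(planted_node_ids(spec), spec.planted):
        if frozenset(members) in planted_active:
            for node_id in members:
                shift_of[node_id] = shift
    node_ids = sorted(network.nodes)
    noise = rng.normal(0.0, spec.background_sigma, size=len(node_ids))
    return {
        node_id: float(noise[i]) + shift_of.get(node_id, 0.0)
        for i, node_id in enumerate(node_ids)
    }


def generate_scores(
    network: ReferenceNetwork,
    spec: SyntheticSpec,
    organ: str = "organ1",
) -> tuple[GeneScoreTable, ScoredNetwork]:
    """Background Normal(0, sigma) scores with planted members shifted.

    One synthetic gene per node carries the node's score, so the scoring
    path (max over genes) is exercised end to end; with
    ``multi_gene_prob > 0`` some nodes get a second, lower-scoring gene to
    exercise the max rule.
    """
    rng = _rng(spec, 1)
    node_scores = _draw_scores(network, spec, rng, planted_node_ids(spec))
    rows: dict[str, float] = {}
    for node_id, score in node_scores.items():
        rows[f"g_{node_id}"] = score
        if f"g2_{node_id}" in network.nodes[node_id].genes:
            # secondary gene scores strictly below the primary: the node
            # score stays the primary score under the max rule
            rows[f"g2_{node_id}"] = score - float(
                abs(rng.normal(0.0, spec.background_sigma)) + 0.1
            )
    table = GeneScoreTable(
        scores=pd.DataFrame({organ: pd.Series(rows)}), organs=[organ]
    )
    scored = ScoredNetwork(network, organ, node_scores)
    return table, scored


def generate_organ_scores(
    network: ReferenceNetwork,
    spec: SyntheticSpec,
    organs: Sequence[str],
) -> tuple[GeneScoreTable, dict[str, ScoredNetwork]]:
    """Independent background per organ; planted cluster j is active in
    organ j mod len(organs), giving each organ its own specific signal."""
    planted = planted_node_ids(spec)
    columns: dict[str, pd.Series] = {}
    scored: dict[str, ScoredNetwork] = {}
    for idx, organ in enumerate(organs):
        rng = _rng(spec, 10 + idx)
        active = [
            members
            for j, members in enumerate(planted)
            if j % len(organs) == idx
        ]
        node_scores = _draw_scores(network, spec, rng, active)
        columns[organ] = pd.Series(
            {f"g_{n}": s for n, s in node_scores.items()}
        )
        scored[organ] = ScoredNetwork(network, organ, node_scores)
    table = GeneScoreTable(scores=pd.DataFrame(columns), organs=list(organs))
    return table, scored


def expression_from_scores(
    table: GeneScoreTable,
    n_datasets: int = 3,
    replicates: int = 2,
    baseline: float = 2.0,
) -> list[ExpressionDataset]:
    """Back-convert a score table into linear-scale expression datasets.

    Each dataset carries 1/n_datasets of the score on the log10 scale around
    a common per-gene baseline, with identical replicate samples per organ;
    integrating the datasets recovers the row median-centered score table.
    Used to exercise the full expression-integration path on synthetic data.
    """
    datasets = []
    for d in range(n_datasets):
        samples = {}
        sample_organ = {}
        for organ in table.organs:
            for r in range(replicates):
                name = f"ds{d}_{organ}_r{r}"
                samples[name] = 10 ** (
                    table.scores[organ] / n_datasets + baseline
                )
                sample_organ[name] = organ
        values = pd.DataFrame(samples)
        datasets.append(
            ExpressionDataset(
                values=values, sample_organ=sample_organ, name=f"synthetic-{d}"
            )
        )
    return datasets
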