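"""Tabular input/output and result export.

All tables are UTF-8 TSV with a header row, mirroring spreadsheet exports:

* reaction table — ``reaction_id, pathway, direction, kegg_reaction_id,
  substrates, products, genes`` (list cells separated by ", ")
* transport table — ``transport_id, pathway, direction, metabolite_id,
  metabolite_name, slcs``
* gene score table — ``gene_id, gene_symbol, <one column per organ>``
* predefined group table — ``group, description, pathway, reaction_ids,
  genes``
* compound category table — ``metabolite_id, category``

Cluster networks are exported as GraphML (node attributes: kind, score,
cluster id, transport class) and SIF for interactive exploration in
Cytoscape; matrices as TSV with organ/compound headers; every run writes a
JSON manifest recording config, seed and versions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .cluster_search import PredefinedGroup, TissueClusterSet
from .component_tree import DEFAULT_N_LEVELS, DEFAULT_START, DEFAULT_STEP
from .connectivity import (
    ConnectivityMatrix,
    OrganCompoundMatrix,
    TransportClassification,
)
from .network import (
    DEFAULT_CURRENCY_METABOLITES,
    ENZYMATIC,
    TRANSPORT,
    ReactionNode,
    ReferenceNetwork,
    build_reference_network,
)
from .scoring import GeneScoreTable, ScoredNetwork

__all__ = [
    "RunConfig",
    "read_reaction_table",
    "read_transport_table",
    "read_score_table",
    "read_group_table",
    "read_category_table",
    "read_inputs",
    "write_reaction_table",
    "write_transport_table",
    "write_score_table",
    "write_matrix",
    "export_results",
]

logger = logging.getLogger(__name__)

LIST_SEP = ", "


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    reactions: str
    transports: str
    scores: str
    groups: str | None = None
    categories: str | None = None
    organs: list[str] = field(default_factory=list)
    currency: list[str] = field(default_factory=lambda: sorted(
        DEFAULT_CURRENCY_METABOLITES))
    threshold_start: float = DEFAULT_START
    threshold_step: float = DEFAULT_STEP
    n_levels: int = DEFAULT_N_LEVELS
    n_perm: int = 100
    seed: int = 0
    outdir: str = "slcnet_out"

    def __post_init__(self) -> None:
        if self.threshold_start <= 0 or self.threshold_step <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def _split_list(cell: str) -> frozenset[str]:
    return frozenset(x.strip() for x in str(cell).split(",") if x.strip())


def read_reaction_table(path: str | Path) -> list[ReactionNode]:
    df = _read_tsv(
        path,
        ["reaction_id", "direction", "substrates", "products", "genes"],
    )
    if df["reaction_id"].duplicated().any():
        dup = df.loc[df["reaction_id"].duplicated(), "reaction_id"].iloc[0]
        raise ValueError(f"{path}: duplicate reaction id {dup!r}")
    nodes = []
    for _, row in df.iterrows():
        genes = _split_list(row["genes"])
        if not genes:
            raise ValueError(
                f"{path}: reaction {row['reaction_id']!r} has no genes"
            )
        mets = _split_list(row["substrates"]) | _split_list(row["products"])
        if not mets:
            raise ValueError(
                f"{path}: reaction {row['reaction_id']!r} has no metabolites"
            )
        nodes.append(
            ReactionNode(
                id=row["reaction_id"],
                kind=ENZYMATIC,
                metabolites=mets,
                genes=genes,
                reversible=str(row["direction"]).lower().startswith("rev"),
                pathway_ids=_split_list(row.get("pathway", "")),
            )
        )
    return nodes


def read_transport_table(path: str | Path) -> list[ReactionNode]:
    df = _read_tsv(path, ["transport_id", "metabolite_id", "slcs"])
    if df["transport_id"].duplicated().any():
        dup = df.loc[df["transport_id"].duplicated(), "transport_id"].iloc[0]
        raise ValueError(f"{path}: duplicate transport id {dup!r}")
    nodes = []
    for _, row in df.iterrows():
        slcs = _split_list(row["slcs"])
        if not slcs:
            raise ValueError(
                f"{path}: transport {row['transport_id']!r} has no Slc genes"
            )
        nodes.append(
            ReactionNode(
                id=row["transport_id"],
                kind=TRANSPORT,
                metabolites=frozenset({row["metabolite_id"].strip()}),
                genes=slcs,
                reversible=True,
                pathway_ids=_split_list(row.get("pathway", "")),
            )
        )
    return nodes


def read_score_table(
    path: str | Path, organs: Sequence[str] | None = None
) -> GeneScoreTable:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing column(s) ['gene_id']")
    symbol_col = "gene_symbol" if "gene_symbol" in df.columns else "gene_id"
    organ_cols = [c for c in df.columns if c not in ("gene_id", "gene_symbol")]
    if organs is not None:
        missing = [o for o in organs if o not in organ_cols]
        if missing:
            raise ValueError(
                f"{path}: organ(s) {missing} requested by the config are "
                f"absent from the score table (has {organ_cols})"
            )
        organ_cols = list(organs)
    scores = (
        df.set_index(df[symbol_col].astype(str))[organ_cols]
        .astype(float)
        .groupby(level=0)
        .max()  # duplicate symbols: keep the best-scoring entry
    )
    scores.index.name = None
    return GeneScoreTable(scores=scores, organs=organ_cols)


def read_group_table(path: str | Path) -> list[PredefinedGroup]:
    df = _read_tsv(path, ["group", "reaction_ids"])
    return [
        PredefinedGroup(
            name=row["group"],
            description=row.get("description", ""),
            reaction_ids=_split_list(row["reaction_ids"]),
            summary=row.get("summary", ""),
        )
        for _, row in df.iterrows()
    ]


def read_category_table(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, ["metabolite_id", "category"])
    return dict(zip(df["metabolite_id"], df["category"]))


def read_inputs(
    config: RunConfig,
) -> tuple[ReferenceNetwork, GeneScoreTable, list[PredefinedGroup], dict[str, str]]:
    """Parse all configured tables and build the reference network."""
    enzymatic = read_reaction_table(config.reactions)
    transports = read_transport_table(config.transports)
    network = build_reference_network(
        enzymatic, transports, currency_metabolites=config.currency
    )
    table = read_score_table(config.scores, organs=config.organs or None)
    groups = read_group_table(config.groups) if config.groups else []
    categories = (
        read_category_table(config.categories) if config.categories else {}
    )
    logger.info(
        "inputs: %d nodes (%d transport), %d edges, %d genes, %d organs",
        len(network), len(network.transport_nodes()),
        network.graph.number_of_edges(), len(table.scores), len(table.organs),
    )
    return network, table, groups, categories


# ---------------------------------------------------------------- writers

def write_reaction_table(nodes: Iterable[ReactionNode], path: str | Path) -> None:
    rows = []
    for n in nodes:
        if n.kind != ENZYMATIC:
            continue
        mets = sorted(n.metabolites)
        half = max(1, len(mets) // 2)
        rows.append(
            {
                "reaction_id": n.id,
                "pathway": LIST_SEP.join(sorted(n.pathway_ids)),
                "direction": "reversible" if n.reversible else "irreversible",
                "kegg_reaction_id": "",
                "substrates": LIST_SEP.join(mets[:half]),
                "products": LIST_SEP.join(mets[half:]) or mets[0],
                "genes": LIST_SEP.join(sorted(n.genes)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_transport_table(nodes: Iterable[ReactionNode], path: str | Path) -> None:
    rows = []
    for n in nodes:
        if n.kind != TRANSPORT:
            continue
        for met in sorted(n.metabolites):
            rows.append(
                {
                    "transport_id": n.id,
                    "pathway": LIST_SEP.join(sorted(n.pathway_ids)),
                    "direction": "reversible",
                    "metabolite_id": met,
                    "metabolite_name": met,
                    "slcs": LIST_SEP.join(sorted(n.genes)),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_score_table(table: GeneScoreTable, path: str | Path) -> None:
    out = table.scores.copy()
    out.insert(0, "gene_symbol", out.index)
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def write_matrix(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index=True)


def _cluster_graph(
    clusters: TissueClusterSet,
    scored: ScoredNetwork,
    classification: TransportClassification | None,
) -> nx.Graph:
    network = scored.network
    g = nx.Graph()
    for idx, cluster in enumerate(clusters):
        for node_id in cluster.node_ids:
            node = network.nodes[node_id]
            attrs = {
                "kind": node.kind,
                "score": scored.node_scores[node_id],
                "cluster": idx,
            }
            if classification is not None and node_id in classification.entries:
                attrs["transport_class"] = classification.entries[node_id]
            g.add_node(node_id, **attrs)
        sub = network.subgraph(cluster.node_ids)
        g.add_edges_from(sub.edges)
    return g


def _write_sif(graph: nx.Graph, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(map(sorted, graph.edges)):
            fh.write(f"{a}\tshared_metabolite\t{b}\n")
        for n in sorted(graph.nodes):
            if graph.degree[n] == 0:
                fh.write(f"{n}\n")


def export_results(
    clusters: Mapping[str, TissueClusterSet],
    scored_networks: Mapping[str, ScoredNetwork],
    classifications: Mapping[str, TransportClassification],
    M: OrganCompoundMatrix | None,
    C: ConnectivityMatrix | None,
    outdir: str | Path,
    config: RunConfig | None = None,
) -> list[Path]:
    """Write per-organ GraphML + SIF, matrices, and a JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for organ, cluster_set in clusters.items():
        graph = _cluster_graph(
            cluster_set, scored_networks[organ], classifications.get(organ)
        )
        gml = outdir / f"clusters_{organ}.graphml"
        nx.write_graphml(graph, gml)
        sif = outdir / f"clusters_{organ}.sif"
        _write_sif(graph, sif)
        written += [gml, sif]
    if M is not None:
        p = outdir / "organ_compound_matrix.tsv"
        write_matrix(M.values, p)
        written.append(p)
    if C is not None:
        p = outdir / "organ_connectivity.tsv"
        write_matrix(C.values, p)
        written.append(p)
    manifest = {
        "package": "slcnet",
        "version": __version__,
        "config": asdict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
        "organs": list(clusters),
        "n_clusters": {o: len(cs) for o, cs in clusters.items()},
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    written.append(mp)
    return written
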