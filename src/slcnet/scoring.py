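"""Organ-specificity gene scores and node scoring.

Expression intensities (linear scale, MAS5-style) from one or more
multi-organ microarray datasets are turned into per-organ gene specificity
scores: within each dataset, replicate samples of an organ are averaged
after log10 transform, brain sub-regions are averaged into a single brain
value, and the per-gene median across the covered organs is subtracted.
Contributions are summed across datasets.  A score of 0 therefore means
"median-typical expression"; positive scores mark organ-enriched genes.

A reaction node's score in an organ is the maximum score over its
associated genes (isozymes / alternative Slcs act as OR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ReferenceNetwork

__all__ = [
    "ExpressionDataset",
    "GeneScoreTable",
    "ScoredNetwork",
    "integrate_expression_datasets",
    "score_network",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """One gene(or probe) x sample expression matrix with organ labels.

    ``values`` is indexed by probe or gene identifier; when ``probe_to_gene``
    is given, probes are collapsed to genes by per-sample maximum before the
    log transform (robust to dead probes).
    """

    values: pd.DataFrame
    sample_organ: Mapping[str, str]
    name: str = ""
    probe_to_gene: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sample_organ)
        if missing:
            raise ValueError(
                f"dataset {self.name!r}: samples without organ label: "
                f"{sorted(missing)[:5]}"
            )

    def organs(self) -> set[str]:
        return {self.sample_organ[s] for s in self.values.columns}


@dataclass
class GeneScoreTable:
    """Gene x organ matrix of integrated organ-specificity scores."""

    scores: pd.DataFrame
    organs: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not list(self.organs):
            self.organs = list(self.scores.columns)
        self.scores = self.scores.reindex(columns=list(self.organs))

    def gene_score(self, gene: str, organ: str) -> float | None:
        if gene not in self.scores.index:
            return None
        val = self.scores.at[gene, organ]
        return None if pd.isna(val) else float(val)


@dataclass
class ScoredNetwork:
    """A reference network with one score per node for a single organ."""

    network: ReferenceNetwork
    organ: str
    node_scores: dict[str, float]
    unscored_nodes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = set(self.network.nodes) - set(self.node_scores)
        if missing:
            raise ValueError(f"nodes without score: {sorted(missing)[:5]}")
        for node_id, score in self.node_scores.items():
            if not math.isfinite(score):
                raise ValueError(f"non-finite score for node {node_id!r}")

    def score(self, node_id: str) -> float:
        return self.node_scores[node_id]

    def with_scores(self, node_scores: dict[str, float]) -> "ScoredNetwork":
        return ScoredNetwork(self.network, self.organ, node_scores)


def _dataset_contribution(
    ds: ExpressionDataset,
    organs: Sequence[str],
    brain_region_map: Mapping[str, str] | None,
    floor: float | None,
) -> pd.DataFrame:
    values = ds.values
    if ds.probe_to_gene is not None:
        gene_index = values.index.map(lambda p: ds.probe_to_gene.get(p, p))
        values = values.groupby(gene_index).max()

    if (values <= 0).any().any():
        if floor is None:
            bad = values.le(0)
            gene = bad.any(axis=1).idxmax()
            sample = bad.loc[gene].idxmax()
            raise ValueError(
                f"dataset {ds.name!r}: non-positive intensity for gene "
                f"{gene!r}, sample {sample!r} and no floor configured"
            )
        values = values.clip(lower=floor)

    logged = np.log10(values)

    # map each sample to its organ, folding brain sub-regions into "brain"
    def organ_of(sample: str) -> str:
        organ = ds.sample_organ[sample]
        if brain_region_map is not None:
            organ = brain_region_map.get(organ, organ)
        return organ

    sample_organs = pd.Series({s: organ_of(s) for s in logged.columns})
    per_organ = logged.T.groupby(sample_organs).mean().T
    covered = [o for o in organs if o in per_organ.columns]
    if len(covered) < 2:
        raise ValueError(
            f"dataset {ds.name!r} covers {len(covered)} of the requested "
            "organs; at least 2 are required for median-centering"
        )
    per_organ = per_organ[covered]
    centered = per_organ.sub(per_organ.median(axis=1), axis=0)
    return centered


def integrate_expression_datasets(
    datasets: Iterable[ExpressionDataset],
    organs: Sequence[str],
    brain_region_map: Mapping[str, str] | None = None,
    floor: float | None = 1.0,
) -> GeneScoreTable:
    """Integrate expression datasets into per-organ specificity scores.

    Per dataset: log10, replicate averaging per organ, per-gene median
    centering across the covered organs.  Per gene and organ the centered
    contributions are summed across datasets; a gene missing from a dataset
    contributes 0 from it.

    Parameters
    ----------
    brain_region_map
        optional map from sub-region organ labels (e.g. "cerebellum") to the
        aggregate label (e.g. "brain"); matching samples are averaged into
        the aggregate organ.
    floor
        linear-scale floor substituted for non-positive intensities before
        log10 (default 1.0, i.e. log score 0); ``None`` disables flooring
        and makes non-positive values an error.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("at least one expression dataset is required")
    contributions = [
        _dataset_contribution(ds, organs, brain_region_map, floor)
        for ds in datasets
    ]
    genes = sorted(set().union(*(c.index for c in contributions)))
    total = pd.DataFrame(0.0, index=genes, columns=list(organs))
    for contrib in contributions:
        total = total.add(contrib.reindex(index=genes, columns=list(organs)),
                          fill_value=0.0)
    total = total.fillna(0.0)
    return GeneScoreTable(scores=total, organs=list(organs))


def score_network(
    network: ReferenceNetwork, table: GeneScoreTable, organ: str
) -> ScoredNetwork:
    """Assign each node the maximum score of its genes in ``organ``.

    Genes absent from the score table are ignored; a node none of whose
    genes appear in the table gets score 0 and is flagged in
    ``unscored_nodes`` (with a logged warning).
    """
    if organ not in table.organs:
        raise KeyError(
            f"unknown organ {organ!r}; available: {list(table.organs)}"
        )
    node_scores: dict[str, float] = {}
    unscored: set[str] = set()
    for node_id, node in network.nodes.items():
        gene_scores = [
            s for g in node.genes
            if (s := table.gene_score(g, organ)) is not None
        ]
        if gene_scores:
            node_scores[node_id] = max(gene_scores)
        else:
            node_scores[node_id] = 0.0
            unscored.add(node_id)
    if unscored:
        logger.warning(
            "%d node(s) have no gene in the score table (score set to 0), "
            "e.g. %s", len(unscored), sorted(unscored)[:3]
        )
    return ScoredNetwork(network, organ, node_scores,
                         unscored_nodes=frozenset(unscored))
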