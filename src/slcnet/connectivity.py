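"""Transport classification and interorgan connectivity matrices.

A transport node inside a selected cluster is *class 1* (enzyme-coupled)
when at least one enzymatic node sharing a metabolite with it lies in the
same cluster — transporter and enzyme locally co-expressed, the membrane
transport metabolon picture.  Otherwise it is *class 2* (isolated
transport, e.g. epithelial excretion/reabsorption).

The organ-compound matrix M has one row per organ and one column per
Slc-transportable compound; M[t, c] is the best F score among organ t's
selected clusters that contain a transport node for compound c (0 when no
cluster transports c).  The organ-organ connectivity matrix is the Gram
product C = M Mᵀ: symmetric, positive semidefinite, with C[t, t] =
Σ_c M[t, c]² summarising organ t's overall transport activity.  Restricting
M's columns to one compound category before the product gives the
per-category connectivity; the per-category matrices of a partition sum to
the full C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster_search import TissueClusterSet, component_score
from .network import TRANSPORT, ReferenceNetwork
from .scoring import ScoredNetwork

__all__ = [
    "TransportClassification",
    "OrganCompoundMatrix",
    "ConnectivityMatrix",
    "classify_transports",
    "organ_compound_matrix",
    "organ_connectivity",
    "type_connectivity",
]

CLASS1 = "class1"
CLASS2 = "class2"


@dataclass
class TransportClassification:
    organ: str
    entries: dict[str, str] = field(default_factory=dict)
    coupled_enzymes: dict[str, set[str]] = field(default_factory=dict)

    def counts(self) -> tuple[int, int]:
        """(#class1, #class2) — the per-organ bar heights."""
        vals = list(self.entries.values())
        return vals.count(CLASS1), vals.count(CLASS2)


@dataclass
class OrganCompoundMatrix:
    """Organ x transportable-compound matrix of transport-capability scores."""

    values: pd.DataFrame
    categories: Mapping[str, str] | None = None

    @property
    def organs(self) -> list[str]:
        return list(self.values.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ConnectivityMatrix:
    """Symmetric PSD organ x organ Gram matrix of transport capability."""

    values: pd.DataFrame
    source: str = "all compounds"


def classify_transports(
    clusters: TissueClusterSet, network: ReferenceNetwork
) -> TransportClassification:
    """Split clustered transport nodes into enzyme-coupled vs isolated."""
    result = TransportClassification(organ=clusters.organ)
    for cluster in clusters:
        members = cluster.node_ids
        for node_id in members:
            node = network.nodes[node_id]
            if node.kind != TRANSPORT:
                continue
            coupled = {
                nb
                for nb in network.graph.neighbors(node_id)
                if nb in members and network.nodes[nb].kind != TRANSPORT
            }
            # a transport node may sit in several clusters; keep the coupled
            # call if any cluster couples it
            if node_id in result.entries and result.entries[node_id] == CLASS1:
                result.coupled_enzymes[node_id] |= coupled
                continue
            result.entries[node_id] = CLASS1 if coupled else CLASS2
            result.coupled_enzymes[node_id] = coupled
    return result


def organ_compound_matrix(
    all_cluster_sets: Mapping[str, TissueClusterSet],
    compounds: Sequence[str],
    scored_networks: Mapping[str, ScoredNetwork],
    categories: Mapping[str, str] | None = None,
) -> OrganCompoundMatrix:
    """M[t, c] = best cluster F among organ t's clusters transporting c.

    ``scored_networks`` supplies the per-organ node scores used to evaluate
    cluster F.  Compounds never transported in an organ's clusters score 0.
    """
    organs = list(all_cluster_sets)
    compound_set = set(compounds)
    values = pd.DataFrame(0.0, index=organs, columns=list(compounds))
    for organ, cluster_set in all_cluster_sets.items():
        scored = scored_networks[organ]
        network = scored.network
        for cluster in cluster_set:
            f = component_score(cluster.node_ids, scored)
            cluster_compounds: set[str] = set()
            for node_id in cluster.node_ids:
                node = network.nodes[node_id]
                if node.kind == TRANSPORT:
                    unknown = node.metabolites - compound_set
                    if unknown:
                        raise KeyError(
                            f"transport {node_id!r} carries compound(s) "
                            f"{sorted(unknown)} not in the registry"
                        )
                    cluster_compounds |= node.metabolites
            for c in cluster_compounds:
                values.at[organ, c] = max(values.at[organ, c], f)
    return OrganCompoundMatrix(values=values, categories=categories)


def organ_connectivity(M: OrganCompoundMatrix) -> ConnectivityMatrix:
    """C = M·Mᵀ over all compound columns."""
    mat = M.values.to_numpy(dtype=float)
    gram = mat @ mat.T
    return ConnectivityMatrix(
        values=pd.DataFrame(gram, index=M.organs, columns=M.organs),
        source="all compounds",
    )


def type_connectivity(M: OrganCompoundMatrix, category: str) -> ConnectivityMatrix:
    """Gram product restricted to the compounds of one category."""
    if M.categories is None:
        raise ValueError("matrix carries no compound category map")
    cols = [c for c in M.compounds if M.categories.get(c) == category]
    if not cols:
        raise ValueError(f"no compound in category {category!r}")
    sub = M.values[cols].to_numpy(dtype=float)
    gram = sub @ sub.T
    return ConnectivityMatrix(
        values=pd.DataFrame(gram, index=M.organs, columns=M.organs),
        source=category,
    )


def check_gram(C: ConnectivityMatrix, atol: float = 1e-9) -> None:
    """Assert the Gram-matrix invariants (symmetry, PSD)."""
    arr = C.values.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=atol):
        raise AssertionError("connectivity matrix is not symmetric")
    eig = np.linalg.eigvalsh((arr + arr.T) / 2)
    if eig.min() < -max(atol, 1e-9 * max(1.0, abs(eig).max())):
        raise AssertionError("connectivity matrix is not positive semidefinite")
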