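"""Transport classification and the organ-compound / connectivity matrices:
coupling definition, Gram identities, category additivity."""

import numpy as np
import pandas as pd
import pytest

from slcnet.cluster_search import select_optimal_clusters
from slcnet.component_tree import build_component_tree
from slcnet.connectivity import (
    CLASS1,
    CLASS2,
    OrganCompoundMatrix,
    check_gram,
    classify_transports,
    organ_compound_matrix,
    organ_connectivity,
    type_connectivity,
)
from slcnet.network import (
    ENZYMATIC,
    TRANSPORT,
    ReactionNode,
    ReferenceNetwork,
)
from slcnet.scoring import ScoredNetwork
from slcnet.synthetic import (
    SyntheticSpec,
    generate_network,
    generate_organ_scores,
)


def toy_clustered(scores):
    """T_A transports A; E1 converts A->B; T_X transports X, isolated."""
    nodes = [
        ReactionNode("E1", ENZYMATIC, frozenset({"A", "B"}), frozenset({"g1"})),
        ReactionNode("T_A", TRANSPORT, frozenset({"A"}), frozenset({"SlcA"})),
        ReactionNode("T_X", TRANSPORT, frozenset({"X"}), frozenset({"SlcX"})),
    ]
    network = ReferenceNetwork(nodes)
    scored = ScoredNetwork(network, "liver", scores)
    tree = build_component_tree(scored)
    clusters = select_optimal_clusters(tree, scored)
    return network, scored, clusters


class TestClassifyTransports:
    def test_coupled_transport_is_class1(self):
        network, _, clusters = toy_clustered(
            {"E1": 3.0, "T_A": 3.0, "T_X": 3.0}
        )
        cls = classify_transports(clusters, network)
        assert cls.entries["T_A"] == CLASS1
        assert cls.coupled_enzymes["T_A"] == {"E1"}

    def test_singleton_transport_is_class2(self):
        network, _, clusters = toy_clustered(
            {"E1": 3.0, "T_A": 3.0, "T_X": 3.0}
        )
        cls = classify_transports(clusters, network)
        assert cls.entries["T_X"] == CLASS2
        assert cls.coupled_enzymes["T_X"] == set()
        assert cls.counts() == (1, 1)

    def test_transport_with_low_scoring_enzyme_neighbor_is_class2(self):
        # E1 below every threshold: T_A sits alone in its cluster
        network, _, clusters = toy_clustered(
            {"E1": -1.0, "T_A": 3.0, "T_X": 3.0}
        )
        cls = classify_transports(clusters, network)
        assert cls.entries["T_A"] == CLASS2

    def test_all_clustered_transports_classified(self):
        spec = SyntheticSpec(
            n_enzymatic=60, n_transport=20, n_metabolites=100,
            planted=((8, 3.0), (6, 3.0)), seed=3,
        )
        net = generate_network(spec)
        _, scored_map = generate_organ_scores(net, spec, ["o1"])
        scored = scored_map["o1"]
        tree = build_component_tree(scored)
        clusters = select_optimal_clusters(tree, scored)
        cls = classify_transports(clusters, net)
        clustered_transports = {
            n for ns in clusters.node_sets() for n in ns
            if net.nodes[n].kind == TRANSPORT
        }
        assert set(cls.entries) == clustered_transports
        assert all(v in (CLASS1, CLASS2) for v in cls.entries.values())
        for node_id, kind in cls.entries.items():
            assert (kind == CLASS1) == bool(cls.coupled_enzymes[node_id])


class TestOrganCompoundMatrix:
    def test_toy_matrix_values(self):
        network, scored, clusters = toy_clustered(
            {"E1": 3.0, "T_A": 3.0, "T_X": 1.0}
        )
        M = organ_compound_matrix(
            {"liver": clusters}, ["A", "X"], {"liver": scored}
        )
        # {E1, T_A} cluster: F = 6/sqrt(2); T_X alone: F = 1.0
        assert M.values.at["liver", "A"] == pytest.approx(6 / np.sqrt(2))
        assert M.values.at["liver", "X"] == pytest.approx(1.0)

    def test_absent_compound_scores_zero(self):
        network, scored, clusters = toy_clustered(
            {"E1": 3.0, "T_A": 3.0, "T_X": -2.0}
        )
        M = organ_compound_matrix(
            {"liver": clusters}, ["A", "X"], {"liver": scored}
        )
        assert M.values.at["liver", "X"] == 0.0

    def test_unregistered_compound_rejected(self):
        network, scored, clusters = toy_clustered(
            {"E1": 3.0, "T_A": 3.0, "T_X": 3.0}
        )
        with pytest.raises(KeyError, match="X"):
            organ_compound_matrix({"liver": clusters}, ["A"], {"liver": scored})

    def test_multi_organ_shape_and_zero_rows(self):
        spec = SyntheticSpec(seed=5)
        net = generate_network(spec)
        organs = [f"organ{i}" for i in range(4)]
        _, scored_map = generate_organ_scores(net, spec, organs)
        cluster_sets = {}
        for organ, scored in scored_map.items():
            tree = build_component_tree(scored)
            cluster_sets[organ] = select_optimal_clusters(tree, scored)
        compounds = sorted(
            {m for n in net.transport_nodes() for m in n.metabolites}
        )
        M = organ_compound_matrix(cluster_sets, compounds, scored_map)
        assert M.values.shape == (4, len(compounds))
        # capability scores come from selected clusters, which all have F > 0
        assert (M.values.values >= 0).all()


class TestConnectivityMatrices:
    def test_hand_multiplied_gram(self):
        M = OrganCompoundMatrix(
            values=pd.DataFrame([[1.0, 2.0], [0.0, 3.0]],
                                index=["t1", "t2"], columns=["c1", "c2"])
        )
        C = organ_connectivity(M)
        assert C.values.values.tolist() == [[5.0, 6.0], [6.0, 9.0]]

    def test_zero_row_propagates(self):
        M = OrganCompoundMatrix(
            values=pd.DataFrame(
                [[0.0, 0.0], [1.0, 2.0]], index=["spleen", "liver"],
                columns=["c1", "c2"],
            )
        )
        C = organ_connectivity(M)
        assert (C.values.loc["spleen"] == 0).all()
        assert (C.values["spleen"] == 0).all()

    def test_gram_identities_on_random_matrix(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 5, size=(6, 11)) * (rng.random((6, 11)) < 0.4)
        M = OrganCompoundMatrix(
            values=pd.DataFrame(
                vals, index=[f"t{i}" for i in range(6)],
                columns=[f"c{j}" for j in range(11)],
            )
        )
        C = organ_connectivity(M)
        check_gram(C)
        # diagonal = row sums of squares
        assert np.allclose(np.diag(C.values.values), (vals**2).sum(axis=1))

    def test_category_additivity_and_rank_one(self):
        rng = np.random.default_rng(10)
        compounds = [f"c{j}" for j in range(9)]
        cats = {c: ["carbohydrate", "lipid", "amino-acid"][j % 3]
                for j, c in enumerate(compounds)}
        vals = rng.uniform(0, 3, size=(5, 9))
        M = OrganCompoundMatrix(
            values=pd.DataFrame(vals, index=[f"t{i}" for i in range(5)],
                                columns=compounds),
            categories=cats,
        )
        total = organ_connectivity(M).values.values
        parts = sum(
            type_connectivity(M, cat).values.values
            for cat in ("carbohydrate", "lipid", "amino-acid")
        )
        assert np.allclose(total, parts)
        # singleton category is rank one
        M1 = OrganCompoundMatrix(
            values=M.values, categories={**cats, "c0": "steroid"}
        )
        C1 = type_connectivity(M1, "steroid")
        outer = np.outer(M.values["c0"], M.values["c0"])
        assert np.allclose(C1.values.values, outer)

    def test_empty_category_rejected(self):
        M = OrganCompoundMatrix(
            values=pd.DataFrame([[1.0]], index=["t"], columns=["c"]),
            categories={"c": "lipid"},
        )
        with pytest.raises(ValueError, match="steroid"):
            type_connectivity(M, "steroid")

    def test_removing_column_never_increases_connectivity(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0, 2, size=(4, 6))
        full = OrganCompoundMatrix(
            values=pd.DataFrame(vals, index=list("wxyz"),
                                columns=[f"c{j}" for j in range(6)])
        )
        reduced = OrganCompoundMatrix(values=full.values.drop(columns=["c3"]))
        assert (
            organ_connectivity(reduced).values.values
            <= organ_connectivity(full).values.values + 1e-12
        ).all()
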