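"""Consensus targets, anti-correlation network, Jaccard overlap, topology."""

import networkx as nx
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirmint.errors import InputError
from mirmint.network import (
    AlgorithmRegistry,
    augment_with_ppi,
    build_network,
    consensus_targets,
    jaccard_overlap,
    topology_stats,
)

REGISTRY = AlgorithmRegistry(
    prediction=frozenset({"A", "B", "C", "D", "E"}),
    validated=frozenset({"VDB"}),
)


def pred_table(rows):
    return pd.DataFrame(rows, columns=["mirna", "gene", "algorithm", "validated"])


def simple_network(edge_rows, mirnas_up=("m1",), mirnas_down=(), genes_up=(), genes_down=("g1", "g2", "g3")):
    cand = pd.DataFrame(edge_rows, columns=["mirna", "gene", "support", "validated"])
    return build_network(cand, list(mirnas_up), list(mirnas_down), list(genes_up), list(genes_down))


class TestConsensusTargets:
    def test_four_algorithm_boundary_retained(self):
        rows = [("m1", "g1", a, 0) for a in "ABCD"]
        out = consensus_targets(pred_table(rows), REGISTRY, min_algorithms=4)
        assert len(out) == 1
        assert out.iloc[0]["support"] == 4

    def test_three_algorithms_not_validated_dropped(self):
        rows = [("m1", "g1", a, 0) for a in "ABC"]
        out = consensus_targets(pred_table(rows), REGISTRY, min_algorithms=4)
        assert len(out) == 0

    def test_validated_rescues_single_algorithm_pair(self):
        rows = [("m1", "g1", "A", 0), ("m1", "g1", "VDB", 1)]
        out = consensus_targets(pred_table(rows), REGISTRY, min_algorithms=4, accept_validated=True)
        assert len(out) == 1
        assert bool(out.iloc[0]["validated"])
        out2 = consensus_targets(pred_table(rows), REGISTRY, min_algorithms=4, accept_validated=False)
        assert len(out2) == 0

    def test_unknown_algorithm_error_lists_registry(self):
        with pytest.raises(InputError, match="mystery.*A"):
            consensus_targets(pred_table([("m1", "g1", "mystery", 0)]), REGISTRY)

    def test_duplicate_rows_collapse_distinct_algorithms(self):
        rows = [("m1", "g1", "A", 0)] * 3 + [("m1", "g1", "B", 0)]
        out = consensus_targets(pred_table(rows), REGISTRY, min_algorithms=2)
        assert len(out) == 1
        assert out.iloc[0]["support"] == 2

    def test_registry_rejects_overlapping_roles(self):
        with pytest.raises(InputError):
            AlgorithmRegistry(prediction=frozenset({"A"}), validated=frozenset({"A"}))


class TestBuildNetwork:
    def candidates(self, *pairs):
        return pd.DataFrame([(m, g, 4, False) for m, g in pairs],
                            columns=["mirna", "gene", "support", "validated"])

    def test_opposite_directions_kept(self):
        net = build_network(self.candidates(("m1", "g1")), ["m1"], [], [], ["g1"])
        assert net.edges == {("m1", "g1")}
        assert net.graph.nodes["m1"]["direction"] == "up"
        assert net.graph.nodes["g1"]["direction"] == "down"

    def test_same_direction_dropped(self):
        net = build_network(self.candidates(("m1", "g1")), ["m1"], [], ["g1"], [])
        assert net.edges == set()
        assert net.n_dropped_same_direction == 1

    def test_non_de_candidates_skipped_with_count(self):
        net = build_network(self.candidates(("m1", "g1"), ("m2", "g9")), ["m1", "m2"], [], [], ["g1"])
        assert net.edges == {("m1", "g1")}
        assert net.n_skipped_unknown == 1

    def test_feature_in_both_directions_is_hard_error(self):
        with pytest.raises(InputError, match="both up and down"):
            build_network(self.candidates(("m1", "g1")), ["m1"], ["m1"], [], ["g1"])

    def test_every_edge_is_anti_correlated_property(self, rng):
        """Anti-correlation invariant holds for arbitrary candidate tables."""
        mirnas = [f"m{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(20)]
        for _ in range(20):
            pairs = {(rng.choice(mirnas), rng.choice(genes)) for _ in range(30)}
            mu = [m for m in mirnas if rng.random() < 0.4]
            md = [m for m in mirnas if m not in mu and rng.random() < 0.5]
            gu = [g for g in genes if rng.random() < 0.3]
            gd = [g for g in genes if g not in gu and rng.random() < 0.4]
            net = build_network(self.candidates(*sorted(pairs)), mu, md, gu, gd)
            for m, g in net.edges:
                assert net.graph.nodes[m]["direction"] != net.graph.nodes[g]["direction"]

    def test_zero_noise_candidates_recover_truth(self, zero_noise_dataset):
        from mirmint.simulate import generate_prediction_tables

        cfg, _, _, truth = zero_noise_dataset
        table = generate_prediction_tables(truth, cfg)
        registry = AlgorithmRegistry.from_table(table)
        cand = consensus_targets(table, registry, min_algorithms=4)
        net = build_network(cand, truth.mirnas_up(), truth.mirnas_down(),
                            truth.genes_up(), truth.genes_down())
        assert net.edges == set(truth.true_edges)


class TestJaccard:
    def build(self, target_sets: dict[str, set[str]]):
        pairs = [(m, g) for m, genes in target_sets.items() for g in genes]
        all_genes = sorted({g for gs in target_sets.values() for g in gs})
        net = build_network(
            pd.DataFrame([(m, g, 4, False) for m, g in pairs],
                         columns=["mirna", "gene", "support", "validated"]),
            sorted(target_sets), [], [], all_genes,
        )
        return net, jaccard_overlap(net)

    def test_identical_target_sets_give_one(self):
        _, jc = self.build({"m1": {"a", "b"}, "m2": {"a", "b"}})
        assert len(jc) == 1
        assert jc.iloc[0]["jc"] == 1.0

    def test_disjoint_sets_emit_no_edge(self):
        _, jc = self.build({"m1": {"a"}, "m2": {"b"}})
        assert len(jc) == 0

    def test_hand_enumerated_half_overlap(self):
        _, jc = self.build({"m1": {"a", "b", "c"}, "m2": {"b", "c", "d"}})
        assert jc.iloc[0]["jc"] == pytest.approx(0.5)

    @given(st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_brute_force_over_five_element_universe(self, data):
        universe = ["a", "b", "c", "d", "e"]
        t1 = set(data.draw(st.sets(st.sampled_from(universe), min_size=1)))
        t2 = set(data.draw(st.sets(st.sampled_from(universe), min_size=1)))
        _, jc = self.build({"m1": t1, "m2": t2})
        expected = len(t1 & t2) / len(t1 | t2)
        if expected == 0:
            assert len(jc) == 0
        else:
            got = jc.iloc[0]["jc"]
            assert got == pytest.approx(expected)
            assert 0 < got <= 1
            assert (got == 1.0) == (t1 == t2)


class TestTopology:
    def test_empty_network_all_zero(self):
        net = simple_network([])
        stats = topology_stats(net)
        assert stats.n_interactions == stats.n_mirnas == stats.n_genes == 0
        assert stats.frac_mirnas_with_min_targets == 0.0

    def test_two_mirnas_three_disjoint_targets_each(self):
        rows = [("m1", f"ga{i}", 4, False) for i in range(3)] + [("m2", f"gb{i}", 4, False) for i in range(3)]
        cand = pd.DataFrame(rows, columns=["mirna", "gene", "support", "validated"])
        net = build_network(cand, ["m1", "m2"], [], [], [f"ga{i}" for i in range(3)] + [f"gb{i}" for i in range(3)])
        stats = topology_stats(net, min_targets=2)
        assert stats.n_interactions == 6
        assert stats.frac_mirnas_with_min_targets == 1.0
        assert sum(stats.targets_per_mirna.values()) == sum(stats.regulators_per_gene.values()) == 6

    def test_matches_generator_bookkeeping(self, zero_noise_dataset):
        from mirmint.network import consensus_targets
        from mirmint.simulate import generate_prediction_tables

        cfg, _, _, truth = zero_noise_dataset
        table = generate_prediction_tables(truth, cfg)
        cand = consensus_targets(table, AlgorithmRegistry.from_table(table))
        net = build_network(cand, truth.mirnas_up(), truth.mirnas_down(),
                            truth.genes_up(), truth.genes_down())
        stats = topology_stats(net, coregulation=3)
        assert stats.n_interactions == len(truth.true_edges)
        per_mirna = {}
        for m, _ in truth.true_edges:
            per_mirna[m] = per_mirna.get(m, 0) + 1
        assert stats.targets_per_mirna == per_mirna
        expected_coreg = {g for g in {e[1] for e in truth.true_edges}
                          if sum(1 for _, gg in truth.true_edges if gg == g) >= 3}
        assert set(stats.coregulated_genes) == expected_coreg

    def test_interaction_count_invariant_under_relabeling(self, rng):
        rows = [(f"m{i}", f"g{j}", 4, False) for i in range(3) for j in rng.choice(10, 4, replace=False)]
        cand = pd.DataFrame(rows, columns=["mirna", "gene", "support", "validated"])
        genes = sorted({r[1] for r in rows})
        net = topology_stats(build_network(cand, ["m0", "m1", "m2"], [], [], genes))
        relabel = {g: f"x_{g}" for g in genes}
        cand2 = cand.assign(gene=cand["gene"].map(relabel))
        net2 = topology_stats(build_network(cand2, ["m0", "m1", "m2"], [], [], [relabel[g] for g in genes]))
        assert net.n_interactions == net2.n_interactions
        assert sorted(net.regulators_per_gene.values()) == sorted(net2.regulators_per_gene.values())


class TestPPI:
    def ppi(self, *pairs):
        return pd.DataFrame(pairs, columns=["gene_1", "gene_2"])

    def test_empty_table_leaves_network_unchanged(self):
        net = simple_network([("m1", "g1", 4, False)])
        before = set(net.graph.edges)
        augment_with_ppi(net, self.ppi())
        assert set(net.graph.edges) == before

    def test_edge_between_network_genes_added_as_annotation(self):
        net = simple_network([("m1", "g1", 4, False), ("m1", "g2", 4, False)])
        augment_with_ppi(net, self.ppi(("g1", "g2")))
        assert net.graph.edges["g1", "g2"]["interaction"] == "ppi"
        assert net.edges == {("m1", "g1"), ("m1", "g2")}

    def test_edge_touching_unknown_gene_skipped_and_counted(self):
        net = simple_network([("m1", "g1", 4, False)])
        augment_with_ppi(net, self.ppi(("g1", "unknown")))
        assert net.n_skipped_ppi == 1


class TestExports:
    def test_sif_has_one_row_per_edge(self, tmp_path):
        net = simple_network([("m1", "g1", 4, False), ("m1", "g2", 5, True)])
        path = tmp_path / "net.sif"
        net.to_sif(path)
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert len(rows) == 2
        assert {r[1] for r in rows} == {"regulates"}

    def test_graphml_reimport_preserves_attributes(self, tmp_path):
        net = simple_network([("m1", "g1", 4, False), ("m1", "g2", 5, True)])
        jaccard_overlap(net)
        path = tmp_path / "net.graphml"
        net.to_graphml(path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.graph.nodes)
        assert back.number_of_edges() == net.graph.number_of_edges()
        assert back.nodes["m1"]["kind"] == "mirna"
        assert back.edges["m1", "g2"]["support"] == 5
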