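import numpy as np
import pytest

from evostrata import synthetic_data as syn
from evostrata import tree_clustering as tc
from evostrata import pair_scoring as ps
from tests.reference_clustering import reference_cluster


def as_partition(clusters):
    return {frozenset(cl.genes) for cl in clusters}


class TestProcessNodeRules:
    GENES = {"A": ["a1"], "B": ["b1"], "C": ["c1"]}

    def test_outgroup_hit_blocks_then_root_merges(self, toy_tree_abc):
        # the stronger a1-c1 hit blocks a1 at the (A,B) node, keeping a1 and
        # b1 separate there; at the root everything is internal and merges
        scores = {("a1", "c1"): 150.0, ("a1", "b1"): 100.0}
        log = []
        clusters = tc.cluster_orthologs(toy_tree_abc, scores, self.GENES, log=log)
        assert as_partition(clusters) == {frozenset({"a1", "b1", "c1"})}
        blocks = [e for e in log if e["action"] == "block"]
        assert blocks and blocks[0]["entity"] == ["a1"]
        ab_merges = [
            e for e in log
            if e["action"] == "merge" and e["node"] == blocks[0]["node"]
        ]
        assert ab_merges == []  # a1 and b1 stayed separate at the lower node

    def test_mutual_best_merges_in_step1(self, toy_tree_abc):
        log = []
        clusters = tc.cluster_orthologs(
            toy_tree_abc, {("a1", "b1"): 90.0}, self.GENES, log=log
        )
        assert frozenset({"a1", "b1"}) in as_partition(clusters)
        assert any(e["step"] == 1 for e in log if e["action"] == "merge")

    def test_gene_without_hits_stays_singleton(self, toy_tree_abc):
        clusters = tc.cluster_orthologs(toy_tree_abc, {}, self.GENES)
        assert as_partition(clusters) == {
            frozenset({"a1"}), frozenset({"b1"}), frozenset({"c1"}),
        }


class TestAgainstReference:
    def _random_case(self, rng, tree, max_genes=3):
        genes_by_sp = {
            sp: [f"{sp.lower()}{i}" for i in range(1, int(rng.integers(1, max_genes + 1)) + 1)]
            for sp in tree.species
        }
        all_genes = [g for gs in genes_by_sp.values() for g in gs]
        scores = {}
        for i in range(len(all_genes)):
            for j in range(i + 1, len(all_genes)):
                if rng.random() < 0.5:
                    # a small value set makes score ties likely, stressing
                    # the tie-break rules
                    scores[tuple(sorted((all_genes[i], all_genes[j])))] = float(
                        rng.choice([10.0, 20.0, 30.0, 40.0])
                    )
        return genes_by_sp, scores

    @pytest.mark.parametrize("tree_fixture", ["toy_tree_abc", "toy_tree_5sp"])
    def test_partitions_match_reference(self, tree_fixture, request):
        tree = request.getfixturevalue(tree_fixture)
        rng = np.random.default_rng(11)
        for _ in range(40):
            genes_by_sp, scores = self._random_case(rng, tree)
            got = as_partition(tc.cluster_orthologs(tree, scores, genes_by_sp))
            want = reference_cluster(tree, scores, genes_by_sp)
            assert got == want

    def test_blocking_example_trace_matches_reference(self, toy_tree_abc):
        scores = {("a1", "c1"): 150.0, ("a1", "b1"): 100.0}
        genes = {"A": ["a1"], "B": ["b1"], "C": ["c1"]}
        got = as_partition(tc.cluster_orthologs(toy_tree_abc, scores, genes))
        ref_log = []
        want = reference_cluster(toy_tree_abc, scores, genes, log=ref_log)
        assert got == want
        assert ("block", ref_log[0][1], ("a1",)) in ref_log


class TestClusterOrthologs:
    def test_perfect_recovery_zero_loss(self, tree23):
        truth = syn.generate_families(
            tree23, n_families=40, loss_prob_per_branch=0.0,
            dup_prob=0.3, seed=5,
        )
        hsps = syn.generate_hits(truth, seed=6)
        table = ps.build_pair_table(hsps)
        clusters = tc.cluster_orthologs(
            tree23, table, syn.genes_by_species(truth), debug=True
        )
        planted = {
            frozenset(g for sp in f.members for g in f.members[sp])
            for f in truth.families
        }
        assert as_partition(clusters) == planted

    def test_determinism_under_input_order(self, toy_tree_5sp):
        rng = np.random.default_rng(2)
        genes = {sp: [f"{sp.lower()}{i}" for i in (1, 2)] for sp in toy_tree_5sp.species}
        all_genes = [g for gs in genes.values() for g in gs]
        items = []
        for i in range(len(all_genes)):
            for j in range(i + 1, len(all_genes)):
                items.append((tuple(sorted((all_genes[i], all_genes[j]))),
                              float(rng.choice([10.0, 20.0, 30.0]))))
        forward = dict(items)
        backward = dict(reversed(items))
        got_f = as_partition(tc.cluster_orthologs(toy_tree_5sp, forward, genes))
        got_b = as_partition(tc.cluster_orthologs(toy_tree_5sp, backward, genes))
        assert got_f == got_b

    def test_unknown_species_rejected(self, toy_tree_abc):
        with pytest.raises(ValueError, match="not a leaf"):
            tc.cluster_orthologs(toy_tree_abc, {}, {"Zz": ["z1"]})

    def test_every_gene_in_exactly_one_cluster(self, tree23):
        truth = syn.generate_families(tree23, n_families=30, seed=9)
        hsps = syn.generate_hits(truth, seed=10)
        table = ps.build_pair_table(hsps)
        gbs = syn.genes_by_species(truth)
        clusters = tc.cluster_orthologs(tree23, table, gbs)
        seen = [g for cl in clusters for g in cl.genes]
        assert sorted(seen) == sorted(g for gs in gbs.values() for g in gs)


class TestPresenceMatrix:
    def _clusters(self):
        return [
            tc.OrthoCluster("C1", ("a1", "b1", "e1"), frozenset({"A", "B", "E"})),
            tc.OrthoCluster("C2", ("a2",), frozenset({"A"})),
            tc.OrthoCluster("C3", ("a3", "a4", "c1"), frozenset({"A", "C"})),
        ]

    def test_rows_follow_cluster_species(self, toy_tree_5sp):
        pm = tc.build_presence_matrix(
            self._clusters(), ["a1", "a2", "a3", "a4"], toy_tree_5sp
        )
        assert pm.data.loc["a1"].to_dict() == {
            "A": True, "B": True, "C": False, "D": False, "E": True,
        }
        assert pm.data.loc["a2"].sum() == 1  # focal-only singleton
        # two focal genes in one cluster produce identical rows
        assert pm.data.loc["a3"].equals(pm.data.loc["a4"])

    def test_missing_focal_gene_reported(self, toy_tree_5sp):
        pm = tc.build_presence_matrix(self._clusters(), ["a1", "zz"], toy_tree_5sp)
        assert pm.missing == ["zz"]
        assert list(pm.data.index) == ["a1"]

    def test_roundtrip(self, toy_tree_5sp, tmp_path):
        pm = tc.build_presence_matrix(self._clusters(), ["a1", "a2"], toy_tree_5sp)
        tc.write_presence_matrix(pm, tmp_path / "pm.tsv")
        again = tc.read_presence_matrix(tmp_path / "pm.tsv")
        assert again.data.equals(pm.data)


def test_cluster_roundtrip(tmp_path, toy_tree_abc):
    scores = {("a1", "b1"): 50.0}
    genes = {"A": ["a1"], "B": ["b1"], "C": ["c1"]}
    clusters = tc.cluster_orthologs(toy_tree_abc, scores, genes)
    species_of = {"a1": "A", "b1": "B", "c1": "C"}
    tc.write_clusters(clusters, species_of, tmp_path / "cl.tsv")
    again = tc.read_clusters(tmp_path / "cl.tsv")
    assert as_partition(again) == as_partition(clusters)
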