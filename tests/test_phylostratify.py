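from math import comb

import numpy as np
import pandas as pd
import pytest

from evostrata import phylostratify as pst
from evostrata import synthetic_data as syn
from evostrata.model_io import PHYLOSTRATA, STRATUM_NAMES
from evostrata.tree_clustering import PresenceMatrix
from evostrata.stats import hypergeom_over_p


def presence(tree, rows: dict[str, list[str]]) -> PresenceMatrix:
    cols = tree.species
    df = pd.DataFrame(
        [[sp in present for sp in cols] for present in rows.values()],
        index=list(rows), columns=cols, dtype=bool,
    )
    return PresenceMatrix(data=df)


class TestAssignStratum:
    @pytest.mark.parametrize("present,expected", [
        (["Hs", "Mb"], "Filozoa"),
        (["Hs"], "Vertebrata"),
        (["Hs", "Nv", "Dm"], "Parahoxozoa"),
        (["Hs", "Gg", "Ci"], "Deuterostomia"),
    ])
    def test_minimum_rank_wins(self, tree23, present, expected):
        pm = presence(tree23, {"g": present})
        assert pst.assign_stratum(pm.data.loc["g"], tree23).name == expected

    def test_all_false_row_rejected(self, tree23):
        pm = presence(tree23, {"g": []})
        with pytest.raises(ValueError, match="all-false"):
            pst.assign_stratum(pm.data.loc["g"], tree23)

    def test_monotone_in_added_presence(self, tree23):
        rng = np.random.default_rng(8)
        species = tree23.species
        for _ in range(100):
            chosen = ["Hs"] + list(
                rng.choice(species, size=int(rng.integers(0, 8)), replace=False)
            )
            base = pst.assign_stratum(
                presence(tree23, {"g": chosen}).data.loc["g"], tree23
            )
            extra = str(rng.choice(species))
            more = pst.assign_stratum(
                presence(tree23, {"g": chosen + [extra]}).data.loc["g"], tree23
            )
            assert more.rank <= base.rank


class TestStratify:
    def test_toy_counts(self, tree23):
        pm = presence(tree23, {
            "g1": ["Hs", "Co"],          # Filozoa
            "g2": ["Hs", "Ml"],          # Metazoa
            "g3": ["Hs", "Ta", "Dm"],    # Parahoxozoa
            "g4": ["Hs"],                # Vertebrata
        })
        _asg, dist = pst.stratify(pm, tree23)
        assert dist.as_vector().tolist() == [1, 1, 1, 0, 0, 1]
        assert dist.total == 4

    def test_zero_loss_matches_planted_distribution(self, tree23):
        truth = syn.generate_families(
            tree23, n_families=150, loss_prob_per_branch=0.0, seed=21
        )
        pm = syn.expected_presence_matrix(truth, tree23)
        _asg, dist = pst.stratify(pm, tree23)
        planted = {n: 0 for n in STRATUM_NAMES}
        for f in truth.families:
            planted[f.origin_stratum] += len(f.members.get("Hs", ()))
        assert dist.counts == planted

    def test_empty_matrix(self, tree23):
        pm = presence(tree23, {})
        _asg, dist = pst.stratify(pm, tree23)
        assert dist.total == 0

    def test_counts_sum_to_assigned(self, tree23):
        truth = syn.generate_families(tree23, n_families=60, seed=3)
        pm = syn.expected_presence_matrix(truth, tree23)
        asg, dist = pst.stratify(pm, tree23)
        assert dist.total == len(asg) == len(pm.data)


class TestGlobalDistributionTests:
    def test_hypergeometric_matches_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            M = int(rng.integers(5, 61))
            K = int(rng.integers(0, M + 1))
            N = int(rng.integers(1, M + 1))
            k = int(rng.integers(0, min(K, N) + 1))
            # brute-force tail of the exact distribution
            want = sum(
                comb(K, x) * comb(M - K, N - x)
                for x in range(k, min(K, N) + 1)
                if N - x <= M - K
            ) / comb(M, N)
            assert hypergeom_over_p(k, M, K, N) == pytest.approx(want, rel=1e-9)

    def test_proportional_distributions_give_chi2_zero(self):
        d = pst.StratumDistribution.from_counts([10, 5, 3, 2, 0, 10])
        b = pst.StratumDistribution.from_counts([20, 10, 6, 4, 0, 20])
        report = pst.global_distribution_tests(d, b)
        assert report["chi2_statistic"] == pytest.approx(0.0)
        assert report["chi2_p"] == pytest.approx(1.0)
        assert report["chi2_df"] == 4  # one bin empty in both rows

    def test_chi2_matches_hand_formula(self):
        d = pst.StratumDistribution.from_counts([8, 2, 3, 1, 1, 5])
        b = pst.StratumDistribution.from_counts([10, 9, 4, 6, 2, 9])
        report = pst.global_distribution_tests(d, b)
        table = np.array([d.as_vector(), b.as_vector()], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        assert report["chi2_statistic"] == pytest.approx(stat)

    def test_disease_bin_exceeding_background_rejected(self):
        d = pst.StratumDistribution.from_counts([5, 0, 0, 0, 0, 0])
        b = pst.StratumDistribution.from_counts([4, 10, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="exceeds"):
            pst.global_distribution_tests(d, b)


class TestLossCandidateAnalysis:
    def test_toy_boolean_filter(self, tree23):
        pm = presence(tree23, {
            "g1": ["Hs", "Ce", "Dm"],
            "g2": ["Hs", "Nv"],          # absent in worm+fly, present deeper
            "g3": ["Hs"],                # absent, no deeper presence
            "g4": ["Hs", "Ce"],
            "g5": ["Hs", "Dm", "Nv"],
        })
        rep = pst.loss_candidate_analysis(pm, ["Ce", "Dm"], 3, tree23)
        assert rep["n_absent"] == 2          # g2, g3
        assert rep["n_loss_candidates"] == 1  # g2 only
        assert rep["genes_absent"] == ["g2", "g3"]

    def test_empty_absent_list_is_vacuous(self, tree23):
        pm = presence(tree23, {"g1": ["Hs"], "g2": ["Hs", "Nv"]})
        rep = pst.loss_candidate_analysis(pm, [], 3, tree23)
        assert rep["n_absent"] == rep["total"] == 2

    def test_zero_loss_data_has_no_candidates(self, tree23):
        truth = syn.generate_families(
            tree23, n_families=120, loss_prob_per_branch=0.0, seed=33
        )
        pm = syn.expected_presence_matrix(truth, tree23)
        rep = pst.loss_candidate_analysis(pm, ["Ce", "Dm"], 3, tree23)
        # without loss, a gene absent in the protostomes cannot appear deeper
        assert rep["n_loss_candidates"] == 0

    def test_unknown_species_rejected(self, tree23):
        pm = presence(tree23, {"g1": ["Hs"]})
        with pytest.raises(ValueError, match="unknown species"):
            pst.loss_candidate_analysis(pm, ["Zz"], 3, tree23)


def _assignments(spec: dict[str, int], method: str, prefix: str):
    out = []
    i = 0
    for name, count in spec.items():
        stratum = PHYLOSTRATA[STRATUM_NAMES.index(name)]
        for _ in range(count):
            out.append(pst.StratumAssignment(f"{prefix}{i}", stratum, method))
            i += 1
    return out


class TestYeastControl:
    def test_breakdown_sums(self):
        # control genes: 572 basal + the reference non-basal breakdown
        control_counts = {
            "Filozoa": 572, "Metazoa": 51, "Parahoxozoa": 8,
            "Bilateria": 5, "Deuterostomia": 4, "Vertebrata": 15,
        }
        control = _assignments(control_counts, "clusters", "c")
        filler = _assignments({"Filozoa": 2727 - 655}, "clusters", "x")
        rep = pst.yeast_control_analysis(
            [a.gene_id for a in control],
            {"clusters": control + filler},
        )["clusters"]
        assert rep["n_non_basal"] == 83
        assert rep["non_basal_breakdown"] == {
            "Metazoa": 51, "Parahoxozoa": 8, "Bilateria": 5,
            "Deuterostomia": 4, "Vertebrata": 15,
        }
        assert rep["pct_non_basal_of_assigned"] == 3.0

    def test_empty_intersection(self):
        asg = _assignments({"Filozoa": 5}, "rbh", "g")
        rep = pst.yeast_control_analysis(["nope"], {"rbh": asg})["rbh"]
        assert rep["n_control_assigned"] == 0
        assert rep["n_non_basal"] == 0

    def test_all_basal_control_has_zero_remainder(self, tree23):
        truth = syn.generate_families(
            tree23, n_families=100, loss_prob_per_branch=0.0, seed=12
        )
        pm = syn.expected_presence_matrix(truth, tree23)
        asg, _ = pst.stratify(pm, tree23)
        control = syn.control_gene_set(truth, tree23)
        rep = pst.yeast_control_analysis(control, {"clusters": asg})["clusters"]
        assert rep["n_non_basal"] == 0
        assert rep["n_basal"] == len(control)


def test_assignments_roundtrip(tmp_path):
    asg = _assignments({"Filozoa": 2, "Vertebrata": 1}, "clusters", "g")
    pst.write_assignments(asg, tmp_path / "a.tsv")
    assert pst.read_assignments(tmp_path / "a.tsv") == asg
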