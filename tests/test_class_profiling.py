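from math import comb

import numpy as np
import pandas as pd
import pytest

from evostrata import class_profiling as cp
from evostrata.phylostratify import StratumDistribution
from evostrata.model_io import STRATUM_NAMES
from evostrata.stats import fisher_2xk_p


def dist(counts):
    return StratumDistribution.from_counts(counts)


def hypergeom_tail_ge(a, row1, row2, col1):
    """P(X >= a) for the 2x2 margin-conditional distribution, by enumeration."""
    n = row1 + row2
    total = 0.0
    for x in range(a, min(row1, col1) + 1):
        if col1 - x <= row2:
            total += comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)
    return total


class TestEnrichAnnotations:
    @staticmethod
    def _tables(disease_members, nondisease_members, n_disease=10, n_background=100):
        disease = [f"d{i}" for i in range(n_disease)]
        nondis = [f"n{i}" for i in range(n_background - n_disease)]
        rows = [(g, 1, "X") for g in disease[:disease_members]]
        rows += [(g, 1, "X") for g in nondis[:nondisease_members]]
        ann = pd.DataFrame(rows, columns=["gene_id", "level", "class_label"])
        return ann, disease, disease + nondis

    def test_enriched_class_selected_and_p_matches_enumeration(self):
        ann, disease, background = self._tables(8, 2)
        df = cp.enrich_annotations(ann, disease, background)
        # one-tailed Fisher == hypergeometric upper tail on the 2x2 margins
        want = hypergeom_tail_ge(8, 10, 90, 10)
        assert df.loc[0, "p_raw"] == pytest.approx(want, rel=1e-9)
        assert bool(df.loc[0, "selected"])

    def test_uniform_class_not_selected(self):
        ann, disease, background = self._tables(2, 18)  # 20% in both groups
        df = cp.enrich_annotations(ann, disease, background)
        assert not bool(df.loc[0, "selected"])

    def test_bh_adjustment_is_step_up_within_level(self):
        rng = np.random.default_rng(5)
        rows = []
        for ci in range(4):
            genes = rng.choice([f"d{i}" for i in range(10)] +
                               [f"n{i}" for i in range(90)],
                               size=12, replace=False)
            rows += [(g, 1, f"C{ci}") for g in genes]
        ann = pd.DataFrame(rows, columns=["gene_id", "level", "class_label"])
        disease = [f"d{i}" for i in range(10)]
        background = disease + [f"n{i}" for i in range(90)]
        df = cp.enrich_annotations(ann, disease, background)
        raw = df["p_raw"].to_numpy()
        m = len(raw)
        order = np.argsort(raw)
        stepup = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, raw[idx] * m / (rank + 1))
            stepup[idx] = running
        assert df["p_adj"].to_numpy() == pytest.approx(stepup)

    def test_class_without_background_gene_rejected(self):
        ann = pd.DataFrame([("zz", 1, "X")], columns=["gene_id", "level", "class_label"])
        with pytest.raises(ValueError, match="no background gene"):
            cp.enrich_annotations(ann, ["d1"], ["d1", "n1"])


class TestClassDeviationTest:
    def test_proportional_class_has_p_one(self):
        p, method, sig = cp.class_deviation_test(
            dist([4, 2, 2, 0, 0, 2]), dist([8, 4, 4, 0, 0, 4]), m_tests=1
        )
        assert method == "exact"
        assert p == pytest.approx(1.0)
        assert not sig

    def test_montecarlo_within_3se_of_exact(self):
        rng = np.random.default_rng(23)
        reps = 20_000
        for _ in range(20):
            class_counts = rng.multinomial(int(rng.integers(4, 10)),
                                           np.ones(6) / 6)
            null_counts = class_counts + rng.multinomial(
                int(rng.integers(4, 11)), np.ones(6) / 6
            )
            table = np.vstack([class_counts, null_counts])
            if table.sum() > 20:
                continue
            p_exact, m1 = fisher_2xk_p(table)
            assert m1 == "exact"
            p_mc, m2 = fisher_2xk_p(
                table, max_enum_total=0, mc_reps=reps,
                rng=np.random.default_rng(99),
            )
            assert m2 == "montecarlo"
            se = np.sqrt(p_exact * (1 - p_exact) / reps)
            assert abs(p_mc - p_exact) <= 3 * se + 2 / reps

    def test_bonferroni_divisor_applied(self):
        skewed_class = dist([0, 0, 0, 0, 0, 12])
        null = dist([40, 10, 10, 10, 10, 20])
        _p, _m, sig_single = cp.class_deviation_test(skewed_class, null, m_tests=1)
        _p2, _m2, sig_many = cp.class_deviation_test(
            skewed_class, null, m_tests=10**9
        )
        assert sig_single and not sig_many

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cp.class_deviation_test(dist([0] * 6), dist([1] * 6), 1)


class TestBinRepresentationTests:
    def test_vertebrate_heavy_class_flags_expected_bins(self):
        cls = dist([0, 0, 0, 0, 0, 30])
        null = dist([50, 50, 50, 50, 50, 50])
        recs = {r.stratum: r for r in cp.bin_representation_tests(cls, null)}
        assert recs["Vertebrata"].direction == "over" and recs["Vertebrata"].significant
        assert recs["Filozoa"].direction == "under" and recs["Filozoa"].significant

    def test_class_equal_to_null_has_no_calls(self):
        cls = dist([5, 5, 5, 5, 5, 5])
        recs = cp.bin_representation_tests(cls, cls)
        assert all(r.direction == "none" and not r.significant for r in recs)

    def test_two_sided_fisher_matches_enumeration(self):
        # table (9,1; 10,90): sum every margin-fixed table no more probable
        cls = dist([9, 1, 0, 0, 0, 0])
        null = dist([10, 90, 0, 0, 0, 0])
        rec = cp.bin_representation_tests(cls, null)[0]
        row1, row2, col1 = 10, 100, 19
        probs = {
            x: comb(row1, x) * comb(row2, col1 - x) / comb(row1 + row2, col1)
            for x in range(max(0, col1 - row2), min(row1, col1) + 1)
        }
        p_obs = probs[9]
        want = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
        assert rec.p == pytest.approx(want, rel=1e-7)

    def test_strict_threshold_uses_divisor(self):
        cls = dist([0, 0, 0, 0, 0, 30])
        null = dist([50, 50, 50, 50, 50, 50])
        recs = cp.bin_representation_tests(cls, null, m_bin_tests=77)
        vert = [r for r in recs if r.stratum == "Vertebrata"][0]
        assert vert.significant_strict == (vert.p < 0.05 / 77)


class TestClassifySignature:
    @staticmethod
    def _records(over=(), under=()):
        recs = []
        for name in STRATUM_NAMES:
            if name in over:
                recs.append(cp.BinRecord(name, "over", 0.001, True, True))
            elif name in under:
                recs.append(cp.BinRecord(name, "under", 0.001, True, True))
            else:
                recs.append(cp.BinRecord(name, "none", 0.5, False, False))
        return recs

    @pytest.mark.parametrize("over,want", [
        (("Vertebrata",), "vertebrate_specific"),
        (("Metazoa",), "early_metazoan"),
        (("Parahoxozoa",), "early_metazoan"),
        (("Parahoxozoa", "Vertebrata"), "multi_stage_metazoan"),
        ((), "conforming"),
    ])
    def test_signature_rules(self, over, want):
        recs = self._records(over=over, under=("Filozoa",))
        assert cp.classify_signature(recs) == want

    def test_no_basal_underrepresentation_means_conforming(self):
        recs = self._records(over=("Vertebrata",))
        assert cp.classify_signature(recs) == "conforming"

    def test_rules_are_mutually_exclusive(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            recs = []
            for name in STRATUM_NAMES:
                direction = str(rng.choice(["over", "under", "none"]))
                sig = bool(rng.random() < 0.5)
                recs.append(cp.BinRecord(name, direction, 0.01, sig, sig))
            got = cp.classify_signature(recs)
            by = {r.stratum: r for r in recs}
            vert = by["Vertebrata"].significant and by["Vertebrata"].direction == "over"
            early = any(
                by[n].significant and by[n].direction == "over"
                for n in ("Metazoa", "Parahoxozoa")
            )
            basal_under = by["Filozoa"].significant and by["Filozoa"].direction == "under"
            if got == "vertebrate_specific":
                assert basal_under and vert and not early
            elif got == "early_metazoan":
                assert basal_under and early and not vert
            elif got == "multi_stage_metazoan":
                assert basal_under and early and vert


def test_profile_classes_gates_signature_on_global_deviation():
    null = dist([520, 162, 57, 57, 57, 147])
    classes = {
        ("Conform", 1): dist([52, 16, 6, 6, 6, 15]),
        ("VertHeavy", 1): dist([10, 10, 5, 5, 5, 65]),
    }
    results = cp.profile_classes(classes, null, seed=1)
    by_label = {r.class_label: r for r in results}
    assert by_label["Conform"].signature == "conforming"
    assert not by_label["Conform"].significant_global
    assert by_label["VertHeavy"].significant_global
    assert by_label["VertHeavy"].signature == "vertebrate_specific"
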