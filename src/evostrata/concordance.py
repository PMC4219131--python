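"""Agreement between the cluster-based and RBH-based phylostratifications.

Two views: per-gene bin agreement (exact and with a one-bin tolerance), and
a distribution-level similarity check — for every ordered pair of class
distributions across the two methods, a chi-square two-sample statistic is
divided by its degrees of freedom, and a one-tailed two-sample t-test asks
whether the same-label (matched) pairs have a smaller mean adjusted
statistic than the cross-label (reference) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .phylostratify import StratumAssignment, StratumDistribution
from .stats import chi2_two_sample

__all__ = [
    "AgreementSummary",
    "phylostratum_agreement",
    "adjusted_chi2",
    "distribution_similarity_ttest",
]


@dataclass(frozen=True)
class AgreementSummary:
    n_common: int
    n_exact: int
    n_adjacent: int
    pct_exact: float
    pct_adjacent: float


def phylostratum_agreement(
    assign_a: list[StratumAssignment],
    assign_b: list[StratumAssignment],
) -> AgreementSummary:
    """Bin agreement over the genes assigned by both methods.

    Exact = identical stratum; adjacent = |rank difference| <= 1 (which
    includes exact matches). Percentages are rounded to one decimal.
    """
    ranks_a = {a.gene_id: a.stratum.rank for a in assign_a}
    ranks_b = {a.gene_id: a.stratum.rank for a in assign_b}
    common = sorted(set(ranks_a) & set(ranks_b))
    if not common:
        raise ValueError("no genes in common between the two assignment sets")
    n_exact = sum(1 for g in common if ranks_a[g] == ranks_b[g])
    n_adjacent = sum(1 for g in common if abs(ranks_a[g] - ranks_b[g]) <= 1)
    n = len(common)
    return AgreementSummary(
        n_common=n,
        n_exact=n_exact,
        n_adjacent=n_adjacent,
        pct_exact=round(100.0 * n_exact / n, 1),
        pct_adjacent=round(100.0 * n_adjacent / n, 1),
    )


def adjusted_chi2(counts_a, counts_b) -> float:
    """Chi-square two-sample statistic divided by its degrees of freedom.

    df = (number of bins non-empty in either distribution) - 1. Zero iff
    the two distributions are proportional.
    """
    stat, _p, df = chi2_two_sample(counts_a, counts_b, return_df=True)
    if df == 0:
        return 0.0
    return stat / df


def distribution_similarity_ttest(
    dists_a: dict[str, StratumDistribution],
    dists_b: dict[str, StratumDistribution],
) -> dict:
    """Are same-class distributions more alike across methods than cross-class?

    Computes the adjusted chi-square statistic for every ordered
    (class-from-A, class-from-B) pair; matched = same label, reference = all
    cross-label pairs. One-tailed Welch t-test that the matched mean is
    smaller.
    """
    labels = sorted(set(dists_a) & set(dists_b))
    if not labels:
        raise ValueError("no class labels shared between methods")
    for name, dists in (("A", dists_a), ("B", dists_b)):
        for label in labels:
            if dists[label].total == 0:
                raise ValueError(f"class {label!r} has an all-zero distribution in method {name}")
    matched, reference = [], []
    for la in labels:
        va = dists_a[la].as_vector()
        for lb in labels:
            stat = adjusted_chi2(va, dists_b[lb].as_vector())
            (matched if la == lb else reference).append(stat)
    matched = np.asarray(matched)
    reference = np.asarray(reference)
    t, p = sps.ttest_ind(matched, reference, equal_var=False, alternative="less")
    return {
        "matched_mean": float(matched.mean()),
        "reference_mean": float(reference.mean()),
        "n_matched": int(len(matched)),
        "n_reference": int(len(reference)),
        "t_statistic": float(t),
        "p_one_tailed": float(p),
    }
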