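"""Binning genes into phylostrata and the distribution-level analyses.

A gene's phylostratum is the most basal bin (minimum rank) among the
species where an ortholog is present — either via its ortholog cluster or
via reciprocal best hits. On top of the per-gene assignments this module
provides the global disease-vs-background distribution tests, the
protostome-loss candidate analysis, and the far-outgroup (yeast-like)
taxon-sampling control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import PHYLOSTRATA, Phylostratum, SpeciesTree, STRATUM_NAMES
from .stats import chi2_two_sample, hypergeom_over_p
from .tree_clustering import PresenceMatrix

__all__ = [
    "StratumAssignment",
    "StratumDistribution",
    "assign_stratum",
    "stratify",
    "presence_matrix_from_rbh",
    "global_distribution_tests",
    "loss_candidate_analysis",
    "yeast_control_analysis",
    "write_assignments",
    "read_assignments",
]


@dataclass(frozen=True)
class StratumAssignment:
    gene_id: str
    stratum: Phylostratum
    method: str  # "clusters" or "rbh"


@dataclass
class StratumDistribution:
    """Six per-bin counts over the phylostrata, basal to recent."""

    counts: dict[str, int] = field(
        default_factory=lambda: {n: 0 for n in STRATUM_NAMES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[n] for n in STRATUM_NAMES], dtype=int)

    def percentages(self) -> dict[str, float]:
        """Per-bin percentages rounded to one decimal."""
        t = self.total
        return {
            n: round(100.0 * c / t, 1) if t else 0.0
            for n, c in self.counts.items()
        }

    @classmethod
    def from_counts(cls, counts) -> "StratumDistribution":
        if len(counts) != len(STRATUM_NAMES):
            raise ValueError("need one count per phylostratum")
        d = cls()
        for name, c in zip(STRATUM_NAMES, counts):
            c = int(c)
            if c < 0:
                raise ValueError("negative count")
            d.counts[name] = c
        return d


def assign_stratum(presence_row: pd.Series, tree: SpeciesTree) -> Phylostratum:
    """Minimum-rank stratum among the species marked present."""
    present = [sp for sp, flag in presence_row.items() if flag]
    if not present:
        raise ValueError("all-false presence row: the focal gene must be present")
    rank = min(tree.stratum_of(sp).rank for sp in present)
    return PHYLOSTRATA[rank]


def stratify(
    pm: PresenceMatrix, tree: SpeciesTree, method: str = "clusters"
) -> tuple[list[StratumAssignment], StratumDistribution]:
    assignments = []
    dist = StratumDistribution()
    for gene, row in pm.data.iterrows():
        stratum = assign_stratum(row, tree)
        assignments.append(StratumAssignment(str(gene), stratum, method))
        dist.counts[stratum.name] += 1
    return assignments, dist


def presence_matrix_from_rbh(rbh_pairs, focal_genes, tree: SpeciesTree) -> PresenceMatrix:
    """Presence = an RBH in that species; the focal column is always true."""
    cols = tree.species
    by_gene: dict[str, set[str]] = {g: {tree.focal} for g in focal_genes}
    for p in rbh_pairs:
        if p.focal_gene in by_gene:
            by_gene[p.focal_gene].add(p.other_species)
    rows = [[sp in by_gene[g] for sp in cols] for g in focal_genes]
    df = pd.DataFrame(rows, index=list(focal_genes), columns=cols, dtype=bool)
    return PresenceMatrix(data=df)


def global_distribution_tests(
    disease: StratumDistribution, background: StratumDistribution
) -> dict:
    """Per-bin one-tailed hypergeometric tests plus an overall chi-square.

    The disease set must be a subset of the background; per bin the
    hypergeometric asks whether the disease set over-draws that bin.
    """
    d = disease.as_vector()
    b = background.as_vector()
    if (d > b).any():
        raise ValueError("disease bin count exceeds background bin count")
    M, N = int(b.sum()), int(d.sum())
    per_bin = {
        name: hypergeom_over_p(int(d[i]), M, int(b[i]), N)
        for i, name in enumerate(STRATUM_NAMES)
    }
    stat, p, df = chi2_two_sample(d, b, return_df=True)
    return {
        "hypergeometric_over_p": per_bin,
        "chi2_statistic": stat,
        "chi2_df": df,
        "chi2_p": p,
    }


def loss_candidate_analysis(
    pm: PresenceMatrix,
    absent_in: list[str],
    earlier_than_rank: int,
    tree: SpeciesTree,
) -> dict:
    """Genes missing from named species but conserved in deeper lineages.

    Subset A: rows absent at every species in ``absent_in`` (an empty list
    makes the condition vacuous, so A = all rows). Subset B: A-rows present
    in at least one species of rank < ``earlier_than_rank`` (loss
    candidates). Subset C: B-rows present in >= 2 such species.
    """
    for sp in absent_in:
        if sp not in pm.data.columns:
            raise ValueError(f"unknown species code {sp!r}")
    df = pm.data
    total = len(df)
    if absent_in:
        mask_a = ~df[list(absent_in)].any(axis=1)
    else:
        mask_a = pd.Series(True, index=df.index)
    deep_species = [
        sp for sp in df.columns if tree.stratum_of(sp).rank < earlier_than_rank
    ]
    deep_presence = df[deep_species].sum(axis=1)
    mask_b = mask_a & (deep_presence >= 1)
    mask_c = mask_a & (deep_presence >= 2)
    def pct(n):
        return round(100.0 * n / total, 1) if total else 0.0
    n_a, n_b, n_c = int(mask_a.sum()), int(mask_b.sum()), int(mask_c.sum())
    return {
        "total": total,
        "n_absent": n_a,
        "n_loss_candidates": n_b,
        "n_strong_candidates": n_c,
        "pct_absent": pct(n_a),
        "pct_loss_candidates": pct(n_b),
        "pct_strong_candidates": pct(n_c),
        "absent_in": list(absent_in),
        "genes_absent": sorted(df.index[mask_a]),
    }


def yeast_control_analysis(
    control_gene_set,
    assignments_by_method: dict[str, list[StratumAssignment]],
) -> dict:
    """Far-outgroup control: how often confidently-ancient genes miss Filozoa.

    ``control_gene_set`` lists genes with an independent homolog in a deep
    outgroup proteome (e.g. yeast RBHs); for each binning method
    the report counts how many of those genes were nonetheless binned above
    the basal stratum, with the per-stratum breakdown of that remainder.
    """
    control = set(control_gene_set)
    report: dict[str, dict] = {}
    for method, assignments in assignments_by_method.items():
        in_control = [a for a in assignments if a.gene_id in control]
        n_assigned_total = len(assignments)
        basal = sum(1 for a in in_control if a.stratum.rank == 0)
        breakdown = {n: 0 for n in STRATUM_NAMES[1:]}
        for a in in_control:
            if a.stratum.rank > 0:
                breakdown[a.stratum.name] += 1
        non_basal = sum(breakdown.values())
        report[method] = {
            "n_control_assigned": len(in_control),
            "n_basal": basal,
            "n_non_basal": non_basal,
            "non_basal_breakdown": breakdown,
            "pct_non_basal_of_assigned": (
                round(100.0 * non_basal / n_assigned_total, 1)
                if n_assigned_total else 0.0
            ),
        }
    return report


def write_assignments(assignments: list[StratumAssignment], path) -> None:
    rows = [(a.gene_id, a.stratum.name, a.method) for a in assignments]
    pd.DataFrame(rows, columns=["gene_id", "stratum", "method"]).to_csv(
        path, sep="\t", index=False
    )


def read_assignments(path) -> list[StratumAssignment]:
    from .model_io import stratum_by_name

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        StratumAssignment(r.gene_id, stratum_by_name(r.stratum), r.method)
        for r in df.itertuples()
    ]
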