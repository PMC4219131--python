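"""Synthetic input bundles with exported ground truth.

The generator emulates the five external inputs of the pipeline — species
tree, gene tables, all-vs-all protein hits, class annotations, and
per-species dN/dS tables — for a focal species and its relatives, with
known per-family origin strata, per-branch loss events, planted class
enrichments and planted selection-rate shifts.

Families are born exactly at stratum-defining ancestors (the focal-path
node where each stratum's clade attaches), so the planted stratum label is
unambiguous ground truth; presence then propagates toward the leaves with
independent per-branch loss. Families that would be invisible to the focal
species are discarded and redrawn, mirroring a disease-gene list that is by
construction observable in the focal genome.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model_io import HSP, PHYLOSTRATA, STRATUM_NAMES, SpeciesTree
from .tree_clustering import PresenceMatrix

__all__ = [
    "DEFAULT_ORIGIN_PROBS",
    "DEFAULT_RATE_SPECIES",
    "ClassSpec",
    "FamilyTruth",
    "SyntheticTruth",
    "generate_families",
    "expected_presence_matrix",
    "generate_hits",
    "write_blast_tab",
    "generate_gene_table",
    "generate_annotations",
    "generate_rates",
    "control_gene_set",
    "default_class_specs",
    "write_bundle",
]

#: Origin-stratum proportions of the focal disease-gene families: just over
#: half pre-animal, a sixth at the base of the animals, a seventh within the
#: vertebrates, the rest spread evenly over the middle bins.
DEFAULT_ORIGIN_PROBS = (0.52, 0.162, 0.057, 0.057, 0.057, 0.147)

#: Mammal-like species codes for the rate tables (the dN/dS side of the
#: analysis lives on a much shallower timescale than the species tree).
DEFAULT_RATE_SPECIES = ("Cfa", "Cja", "Fca", "Mml", "Mmu", "Ocu", "Oga", "Ptr", "Rno")

DEFAULT_RATIO_MEDIANS = {
    name: (0.25 if name == "Vertebrata" else 0.10) for name in STRATUM_NAMES
}


@dataclass(frozen=True)
class ClassSpec:
    label: str
    level: int
    size: int
    enrich_stratum: str | None = None
    factor: float = 1.0


@dataclass
class FamilyTruth:
    family_id: str
    origin_rank: int
    origin_stratum: str
    members: dict[str, list[str]]  # species -> gene ids
    losses: list[int]              # postorder indices of lost child branches


@dataclass
class SyntheticTruth:
    master_seed: int
    families: list[FamilyTruth] = field(default_factory=list)
    classes: dict[str, dict] = field(default_factory=dict)
    rate_medians: dict[str, float] = field(default_factory=dict)
    rate_species: list[str] = field(default_factory=list)

    def focal_genes(self, tree: SpeciesTree) -> list[str]:
        out: list[str] = []
        for fam in self.families:
            out.extend(fam.members.get(tree.focal, ()))
        return out

    def origin_of(self, tree: SpeciesTree) -> dict[str, str]:
        """Planted origin stratum per focal gene."""
        mapping = {}
        for fam in self.families:
            for g in fam.members.get(tree.focal, ()):
                mapping[g] = fam.origin_stratum
        return mapping

    def to_json(self, path) -> None:
        payload = {
            "master_seed": self.master_seed,
            "families": [asdict(f) for f in self.families],
            "classes": self.classes,
            "rate_medians": self.rate_medians,
            "rate_species": self.rate_species,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        truth = cls(master_seed=payload["master_seed"])
        truth.families = [FamilyTruth(**f) for f in payload["families"]]
        truth.classes = payload["classes"]
        truth.rate_medians = payload["rate_medians"]
        truth.rate_species = payload["rate_species"]
        return truth


# ---------------------------------------------------------------------------
# Families: birth at stratum ancestors, per-branch Dollo loss
# ---------------------------------------------------------------------------

def generate_families(
    tree: SpeciesTree,
    n_families: int = 2000,
    origin_probs=DEFAULT_ORIGIN_PROBS,
    loss_prob_per_branch: float = 0.05,
    dup_prob: float = 0.01,
    seed: int = 0,
) -> SyntheticTruth:
    probs = np.asarray(origin_probs, dtype=float)
    if probs.shape != (6,) or (probs < 0).any() or (probs > 1).any():
        raise ValueError("origin_probs must be six probabilities in [0, 1]")
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("origin_probs must sum to 1")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(master_seed=seed)

    origin_nodes = {rank: tree.origin_node_for_rank(rank) for rank in range(6)}

    for i in range(n_families):
        rank = int(rng.choice(6, p=probs))
        node = origin_nodes[rank]
        # redraw loss pattern until the focal species survives
        while True:
            present_species: list[str] = []
            losses: list[int] = []

            def descend(nd):
                if nd.is_leaf():
                    present_species.append(next(iter(nd.leafset)))
                    return
                for child in nd.child_nodes():
                    if rng.random() < loss_prob_per_branch:
                        losses.append(child.postorder_index)
                    else:
                        descend(child)

            descend(node)
            if tree.focal in present_species:
                break
        fid = f"F{i + 1:05d}"
        members: dict[str, list[str]] = {}
        for sp in present_species:
            genes = [f"{fid}_{sp}"]
            if rng.random() < dup_prob:
                genes.append(f"{fid}_{sp}b")
            members[sp] = genes
        truth.families.append(FamilyTruth(
            family_id=fid,
            origin_rank=rank,
            origin_stratum=PHYLOSTRATA[rank].name,
            members=members,
            losses=sorted(losses),
        ))
    return truth


def expected_presence_matrix(truth: SyntheticTruth, tree: SpeciesTree) -> PresenceMatrix:
    """The presence matrix implied directly by the planted truth."""
    cols = tree.species
    rows, index = [], []
    for fam in truth.families:
        present = set(fam.members)
        for g in fam.members.get(tree.focal, ()):
            rows.append([sp in present for sp in cols])
            index.append(g)
    df = pd.DataFrame(rows, index=index, columns=cols, dtype=bool)
    return PresenceMatrix(data=df)


def genes_by_species(truth: SyntheticTruth) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for fam in truth.families:
        for sp, genes in fam.members.items():
            out.setdefault(sp, []).extend(genes)
    for sp in out:
        out[sp].sort()
    return out


# ---------------------------------------------------------------------------
# Hits (outfmt-6-like HSPs)
# ---------------------------------------------------------------------------

def _evalue_for(bits: float) -> float:
    return float(max(min(10.0, 10.0 ** (1.0 - bits / 10.0)), 1e-180))


def _pident_for(bits: float, rng) -> float:
    return float(np.clip(35.0 + bits / 10.0 + rng.normal(0, 2), 20.0, 99.9))


def _emit_pair_hsps(a: str, b: str, target_score: float, rng,
                    inject_overlap: bool) -> list[HSP]:
    """1-3 colinear HSPs whose chained score equals ``target_score``.

    Segments are disjoint by default (so the chain score is the plain sum);
    with ``inject_overlap`` the second segment overlaps the first by an
    admissible sliver, exercising the chaining penalty.
    """
    k = int(rng.integers(2, 4)) if inject_overlap else int(rng.integers(1, 4))
    weights = rng.dirichlet(np.ones(k) * 4.0)
    bits = np.maximum(target_score * weights, 2.0)
    hsps = []
    q_cursor = s_cursor = 1
    prev_q_end = prev_len = 0
    for j in range(k):
        length = max(30, int(round(bits[j] / 2.0)))
        q_start, s_start = q_cursor, s_cursor
        if inject_overlap and j == 1:
            # overlap the previous segment by <5% of the shorter span: the
            # pair stays chainable but pays the overlap penalty
            ov = max(1, int(0.03 * min(prev_len, length)))
            q_start = max(1, prev_q_end - ov + 1)
        q_end = q_start + length - 1
        s_end = s_start + length - 1
        prev_q_end, prev_len = q_end, length
        hsps.append(HSP(
            query_id=a, subject_id=b,
            q_start=q_start, q_end=q_end,
            s_start=s_start, s_end=s_end,
            aln_length=length,
            bit_score=float(bits[j]),
            e_value=_evalue_for(float(bits[j])),
        ))
        q_cursor = q_end + 6
        s_cursor = s_end + 6
    return hsps


def generate_hits(
    truth: SyntheticTruth,
    within_score_mean: float = 200.0,
    between_score_mean: float = 20.0,
    noise_sd: float = 5.0,
    cross_pair_fraction: float = 0.0,
    overlap_inject_fraction: float = 0.0,
    seed: int = 1,
) -> list[HSP]:
    """All-vs-all-like HSP rows for the planted families.

    Every within-family gene pair receives 1-3 colinear HSPs whose chained
    score is ~Normal(within_score_mean, noise_sd); a fraction of
    cross-family pairs receives low-score hits ~Normal(between_score_mean,
    noise_sd). E-values decrease monotonically with bit score.
    """
    if within_score_mean < between_score_mean:
        raise ValueError("within-family scores must not be below between-family scores")
    rng = np.random.default_rng(seed)
    hsps: list[HSP] = []
    family_of: dict[str, str] = {}
    all_genes: list[str] = []
    for fam in truth.families:
        members = [g for sp in sorted(fam.members) for g in fam.members[sp]]
        for g in members:
            family_of[g] = fam.family_id
        all_genes.extend(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                score = max(float(rng.normal(within_score_mean, noise_sd)), 5.0)
                inject = rng.random() < overlap_inject_fraction
                hsps.extend(_emit_pair_hsps(members[i], members[j], score, rng, inject))
    if cross_pair_fraction > 0 and len(all_genes) > 1:
        n_within = sum(
            len(v) * (len(v) - 1) // 2
            for v in (
                [g for sp in f.members for g in f.members[sp]]
                for f in truth.families
            )
        )
        n_total = len(all_genes) * (len(all_genes) - 1) // 2
        n_noise = int(round(cross_pair_fraction * (n_total - n_within)))
        drawn: set[tuple[str, str]] = set()
        while len(drawn) < n_noise:
            a, b = rng.choice(len(all_genes), size=2, replace=False)
            ga, gb = all_genes[a], all_genes[b]
            if family_of[ga] == family_of[gb]:
                continue
            drawn.add((ga, gb) if ga < gb else (gb, ga))
        for ga, gb in sorted(drawn):
            score = max(float(rng.normal(between_score_mean, noise_sd)), 2.0)
            hsps.extend(_emit_pair_hsps(ga, gb, score, rng, False))
    return hsps


def write_blast_tab(hsps: list[HSP], path, rng_seed: int = 0) -> None:
    """Write HSPs as the 12 standard tabular columns."""
    rng = np.random.default_rng(rng_seed)
    with open(path, "w") as fh:
        for h in hsps:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id,
                f"{_pident_for(h.bit_score, rng):.1f}",
                h.aln_length, 0, 0,
                h.q_start, h.q_end, h.s_start, h.s_end,
                f"{h.e_value:.3g}", f"{h.bit_score:.1f}",
            ])) + "\n")


# ---------------------------------------------------------------------------
# Gene table, annotations, rates
# ---------------------------------------------------------------------------

def generate_gene_table(
    truth: SyntheticTruth,
    tree: SpeciesTree,
    unmapped_frac: float = 0.087,
    unclustered_frac: float = 0.032,
    seed: int = 2,
) -> pd.DataFrame:
    """Gene table with OMIM-like mapping/clustering failure flags.

    Focal genes are flagged unmapped / unclustered at the given disjoint
    rates (defaults mirror the 270 and 99 of 3096 failure proportions of a
    curated disease-gene list); non-focal genes always pass both.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for fam in truth.families:
        for sp in sorted(fam.members):
            for g in fam.members[sp]:
                if sp == tree.focal:
                    u = rng.random()
                    mapped = u >= unmapped_frac
                    clustered = u >= unmapped_frac + unclustered_frac
                    # an unmapped gene may also carry clustered=0; the
                    # filter tallies it once, as unmapped
                    rows.append((g, sp, int(mapped), int(clustered)))
                else:
                    rows.append((g, sp, 1, 1))
    df = pd.DataFrame(rows, columns=["gene_id", "species", "mapped", "clustered"])
    return df


def generate_annotations(
    truth: SyntheticTruth,
    classes_spec: list[ClassSpec],
    tree: SpeciesTree,
    seed: int = 3,
) -> pd.DataFrame:
    """Class annotations over focal genes, with optional planted enrichment.

    A neutral class samples members uniformly; a planted class oversamples
    genes whose family originated in ``enrich_stratum`` by ``factor``.
    Expected six-bin counts per class are recorded in the truth object.
    """
    rng = np.random.default_rng(seed)
    origin = truth.origin_of(tree)
    genes = sorted(origin)
    rows = []
    for spec in classes_spec:
        if spec.size == 0:
            warnings.warn(f"class {spec.label!r} has size 0 and is omitted")
            continue
        if spec.size > len(genes):
            raise ValueError(
                f"class {spec.label!r} wants {spec.size} genes; only {len(genes)} exist"
            )
        weights = np.array([
            spec.factor if origin[g] == spec.enrich_stratum else 1.0
            for g in genes
        ])
        weights = weights / weights.sum()
        chosen = rng.choice(genes, size=spec.size, replace=False, p=weights)
        rows.extend((g, spec.level, spec.label) for g in sorted(chosen))
        expected = {}
        for name in STRATUM_NAMES:
            mass = float(np.sum(weights[[origin[g] == name for g in genes]]))
            expected[name] = spec.size * mass
        truth.classes[spec.label] = {
            "level": spec.level,
            "size": spec.size,
            "enrich_stratum": spec.enrich_stratum,
            "factor": spec.factor,
            "expected_distribution": expected,
        }
    return pd.DataFrame(rows, columns=["gene_id", "level", "class_label"])


def generate_rates(
    truth: SyntheticTruth,
    tree: SpeciesTree,
    stratum_ratio_medians: dict[str, float] | None = None,
    species: tuple[str, ...] = DEFAULT_RATE_SPECIES,
    sigma_ratio: float = 0.6,
    ds_median: float = 0.2,
    sigma_ds: float = 0.5,
    decoy_prob: float = 0.3,
    missing_prob: float = 0.05,
    seed: int = 4,
) -> dict[str, pd.DataFrame]:
    """Per-species ortholog rate tables with planted dN/dS medians.

    dN/dS is lognormal with median set by the gene's origin stratum; dS is
    lognormal; dN = ratio x dS. Each (gene, species) gets one
    high-confidence candidate (the one the top-ortholog rule must pick) and,
    with ``decoy_prob``, one confidence-0 decoy. ``missing_prob`` drops a
    (gene, species) entry entirely, emulating genes with no assigned rates.
    """
    medians = dict(stratum_ratio_medians or DEFAULT_RATIO_MEDIANS)
    for name, m in medians.items():
        if m <= 0:
            raise ValueError(f"ratio median for {name} must be positive")
    rng = np.random.default_rng(seed)
    origin = truth.origin_of(tree)
    tables: dict[str, list] = {sp: [] for sp in species}
    for g in sorted(origin):
        mu = float(np.log(medians[origin[g]]))
        for sp in species:
            if rng.random() < missing_prob:
                continue
            ratio = float(rng.lognormal(mu, sigma_ratio))
            dS = float(rng.lognormal(np.log(ds_median), sigma_ds))
            dN = ratio * dS
            tables[sp].append((
                g, f"{g}_{sp}", 1,
                round(float(rng.uniform(70, 95)), 1),
                round(dN, 6), round(dS, 6),
            ))
            if rng.random() < decoy_prob:
                d_ratio = float(rng.lognormal(np.log(0.5), 0.5))
                d_dS = float(rng.lognormal(np.log(ds_median), sigma_ds))
                tables[sp].append((
                    g, f"{g}_{sp}x", 0,
                    round(float(rng.uniform(50, 80)), 1),
                    round(d_ratio * d_dS, 6), round(d_dS, 6),
                ))
    truth.rate_medians = medians
    truth.rate_species = list(species)
    cols = ["gene_id", "ortholog_id", "confidence", "pct_identity", "dN", "dS"]
    return {sp: pd.DataFrame(rows, columns=cols) for sp, rows in tables.items()}


def control_gene_set(truth: SyntheticTruth, tree: SpeciesTree) -> list[str]:
    """Focal genes of basal-origin families: the far-outgroup control set."""
    origin = truth.origin_of(tree)
    return sorted(g for g, s in origin.items() if s == STRATUM_NAMES[0])


# ---------------------------------------------------------------------------
# Full input bundle
# ---------------------------------------------------------------------------

#: (label, level, fraction of focal genes, enriched stratum, factor).
#: At the 2000-family default the planted classes have ~120 members drawn
#: with a 4x preference for their target stratum; the rest are neutral.
DEFAULT_CLASS_FRACTIONS = (
    ("NeutralA", 1, 0.060, None, 1.0),
    ("NeutralB", 1, 0.040, None, 1.0),
    ("NeutralC", 1, 0.075, None, 1.0),
    ("NeutralD", 2, 0.030, None, 1.0),
    ("NeutralE", 2, 0.050, None, 1.0),
    ("InflamDis", 1, 0.060, "Vertebrata", 4.0),
    ("EmbryDev", 1, 0.060, "Metazoa", 4.0),
)


def default_class_specs(n_focal_genes: int) -> tuple[ClassSpec, ...]:
    return tuple(
        ClassSpec(label, level, min(max(10, round(frac * n_focal_genes)), n_focal_genes),
                  enrich_stratum=stratum, factor=factor)
        for label, level, frac, stratum, factor in DEFAULT_CLASS_FRACTIONS
    )


def write_bundle(
    outdir,
    tree: SpeciesTree,
    *,
    n_families: int = 2000,
    origin_probs=DEFAULT_ORIGIN_PROBS,
    loss_prob_per_branch: float = 0.05,
    dup_prob: float = 0.01,
    within_score_mean: float = 200.0,
    between_score_mean: float = 20.0,
    noise_sd: float = 5.0,
    cross_pair_fraction: float = 0.0,
    overlap_inject_fraction: float = 0.0,
    unmapped_frac: float = 0.087,
    unclustered_frac: float = 0.032,
    classes_spec: tuple[ClassSpec, ...] | None = None,
    stratum_ratio_medians: dict[str, float] | None = None,
    rate_species: tuple[str, ...] = DEFAULT_RATE_SPECIES,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate and write the complete input bundle plus the truth JSON.

    Child seeds for each generator are spawned deterministically from the
    master seed, so one seed fixes every file byte-for-byte.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

    truth = generate_families(
        tree, n_families=n_families, origin_probs=origin_probs,
        loss_prob_per_branch=loss_prob_per_branch, dup_prob=dup_prob,
        seed=child[0],
    )
    truth.master_seed = seed
    hsps = generate_hits(
        truth, within_score_mean=within_score_mean,
        between_score_mean=between_score_mean, noise_sd=noise_sd,
        cross_pair_fraction=cross_pair_fraction,
        overlap_inject_fraction=overlap_inject_fraction, seed=child[1],
    )
    write_blast_tab(hsps, outdir / "hits.tsv", rng_seed=child[1])
    genes = generate_gene_table(
        truth, tree, unmapped_frac=unmapped_frac,
        unclustered_frac=unclustered_frac, seed=child[2],
    )
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    if classes_spec is None:
        classes_spec = default_class_specs(len(truth.focal_genes(tree)))
    annotations = generate_annotations(truth, list(classes_spec), tree, seed=child[3])
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    rates = generate_rates(
        truth, tree, stratum_ratio_medians=stratum_ratio_medians,
        species=rate_species, seed=child[4],
    )
    for sp, df in rates.items():
        df.to_csv(outdir / f"rates_{sp}.tsv", sep="\t", index=False)
    with open(outdir / "control_genes.txt", "w") as fh:
        fh.write("\n".join(control_gene_set(truth, tree)) + "\n")
    truth.to_json(outdir / "truth.json")
    return truth
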