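"""End-to-end orchestration with reproducible run metadata.

The pipeline chains the stages: input generation (optional) -> pair scoring
-> tree clustering -> phylostratification (clusters and RBH) -> class
profiling -> selection rates -> concordance, writing each stage's outputs
and a JSON manifest of seeds, parameters and row counts. Any stage error is
re-raised with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import class_profiling as cp
from . import concordance as cc
from . import model_io as mio
from . import pair_scoring as ps
from . import phylostratify as pst
from . import selection_rates as sr
from . import synthetic_data as syn
from . import tree_clustering as tc

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "evostrata_run"
    seed: int = 0
    # inputs; None means "synthesize into <outdir>/inputs"
    tree_newick: str | None = None
    strata_tsv: str | None = None
    hits_path: str | None = None
    genes_path: str | None = None
    annotations_path: str | None = None
    rates_paths: dict = field(default_factory=dict)  # species -> path
    control_genes_path: str | None = None
    # synthesis parameters (used when inputs are not given)
    n_families: int = 300
    loss_prob_per_branch: float = 0.05
    dup_prob: float = 0.01
    cross_pair_fraction: float = 0.0
    # statistics
    alpha: float = 0.05
    mc_reps: int = 100_000
    loss_absent_in: list = field(default_factory=lambda: ["Ce", "Dm"])
    loss_earlier_than_rank: int = 3  # candidates must appear below Bilateria
    rate_species: list = field(default_factory=list)  # empty = all available

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@contextmanager
def _stage(name: str, manifest: dict):
    try:
        yield
    except Exception as exc:
        raise StageError(name, exc) from exc
    manifest["stages_completed"].append(name)


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages_completed": [],
        "counts": {},
    }

    # ---- model_io: tree and inputs --------------------------------------
    with _stage("model_io", manifest):
        if config.tree_newick and config.strata_tsv:
            tree = mio.parse_species_tree(
                Path(config.tree_newick).read_text(),
                mio.read_stratum_table(config.strata_tsv),
            )
        else:
            tree = mio.load_default_tree()

        if config.hits_path is None:
            indir = out / "inputs"
            syn.write_bundle(
                indir, tree,
                n_families=config.n_families,
                loss_prob_per_branch=config.loss_prob_per_branch,
                dup_prob=config.dup_prob,
                cross_pair_fraction=config.cross_pair_fraction,
                seed=config.seed,
            )
            config.hits_path = str(indir / "hits.tsv")
            config.genes_path = str(indir / "genes.tsv")
            config.annotations_path = str(indir / "annotations.tsv")
            config.rates_paths = {
                sp: str(indir / f"rates_{sp}.tsv")
                for sp in syn.DEFAULT_RATE_SPECIES
            }
            config.control_genes_path = str(indir / "control_genes.txt")

        hsps = mio.read_blast_tab(config.hits_path)
        genes, annotations, rates = mio.read_gene_tables(
            config.genes_path, config.annotations_path, config.rates_paths
        )
        control_genes: list[str] = []
        if config.control_genes_path:
            control_genes = [
                ln.strip() for ln in Path(config.control_genes_path).read_text().splitlines()
                if ln.strip()
            ]
        manifest["counts"]["hsps"] = len(hsps)
        manifest["counts"]["genes"] = len(genes)

    # ---- pair scoring ----------------------------------------------------
    with _stage("pair_scoring", manifest):
        pair_table = ps.build_pair_table(hsps)
        ps.write_pair_table(pair_table, out / "pair_scores.tsv")
        species_of = dict(zip(genes["gene_id"], genes["species"]))
        best = ps.directed_best_hits(pair_table, species_of)
        rbh = ps.compute_rbh(best, species_of, tree.focal)
        pd.DataFrame(
            [(p.focal_gene, p.other_gene, p.other_species, p.e_forward, p.e_reverse)
             for p in rbh],
            columns=["focal_gene", "other_gene", "other_species",
                     "e_forward", "e_reverse"],
        ).to_csv(out / "rbh.tsv", sep="\t", index=False)
        manifest["counts"]["gene_pairs"] = len(pair_table)
        manifest["counts"]["rbh_pairs"] = len(rbh)

    # ---- clustering ------------------------------------------------------
    with _stage("tree_clustering", manifest):
        genes_by_sp: dict[str, list[str]] = {
            sp: sorted(grp["gene_id"]) for sp, grp in genes.groupby("species")
        }
        clusters = tc.cluster_orthologs(tree, pair_table, genes_by_sp)
        tc.write_clusters(clusters, species_of, out / "clusters.tsv")
        manifest["counts"]["clusters"] = len(clusters)

    # ---- disease-gene filtering and stratification -----------------------
    with _stage("phylostratify", manifest):
        focal_tbl = genes[genes["species"] == tree.focal]
        if "clustered" not in focal_tbl.columns:
            in_cluster = {g for cl in clusters for g in cl.genes}
            focal_tbl = focal_tbl.assign(
                clustered=focal_tbl["gene_id"].isin(in_cluster)
            )
        records = [
            mio.GeneRecord(r.gene_id, r.species, bool(r.mapped), bool(r.clustered))
            for r in focal_tbl.itertuples()
        ]
        retained, filter_report = mio.filter_disease_genes(records)
        disease_genes = [r.gene_id for r in retained]

        pm_clusters = tc.build_presence_matrix(clusters, disease_genes, tree)
        tc.write_presence_matrix(pm_clusters, out / "presence_clusters.tsv")
        pm_rbh = pst.presence_matrix_from_rbh(
            rbh, [g for g in disease_genes if g in pm_clusters.data.index], tree
        )
        tc.write_presence_matrix(pm_rbh, out / "presence_rbh.tsv")

        assign_cl, dist_cl = pst.stratify(pm_clusters, tree, method="clusters")
        assign_rbh, dist_rbh = pst.stratify(pm_rbh, tree, method="rbh")
        pst.write_assignments(assign_cl + assign_rbh, out / "assignments.tsv")

        loss_report = pst.loss_candidate_analysis(
            pm_clusters, config.loss_absent_in,
            config.loss_earlier_than_rank, tree,
        )
        loss_report.pop("genes_absent", None)
        control_report = pst.yeast_control_analysis(
            control_genes, {"clusters": assign_cl, "rbh": assign_rbh}
        )
        _dump_json({
            "filter": filter_report.as_dict(),
            "distribution_clusters": dist_cl.counts,
            "distribution_rbh": dist_rbh.counts,
            "pct_clusters": dist_cl.percentages(),
            "loss_analysis": loss_report,
            "control": control_report,
        }, out / "stratification.json")
        manifest["counts"]["disease_genes_retained"] = filter_report.n_retained

    # ---- class profiling -------------------------------------------------
    with _stage("class_profiling", manifest):
        stratum_of = {a.gene_id: a.stratum.name for a in assign_cl}
        ann = annotations[annotations["gene_id"].isin(stratum_of)]
        class_dists: dict[tuple[str, int], pst.StratumDistribution] = {}
        for (level, label), grp in ann.groupby(["level", "class_label"]):
            dist = pst.StratumDistribution()
            for g in grp["gene_id"]:
                dist.counts[stratum_of[g]] += 1
            if dist.total:
                class_dists[(str(label), int(level))] = dist
        results = cp.profile_classes(
            class_dists, dist_cl,
            alpha=config.alpha, mc_reps=config.mc_reps, seed=config.seed,
        )
        cp.results_to_frame(results).to_csv(
            out / "class_profiles.tsv", sep="\t", index=False
        )
        manifest["counts"]["classes_tested"] = len(results)
        manifest["counts"]["classes_deviating"] = sum(
            r.significant_global for r in results
        )

    # ---- selection rates ---------------------------------------------------
    with _stage("selection_rates", manifest):
        rate_table = sr.build_rate_table(rates)
        species_list = config.rate_species or sorted(rates)
        unknown = set(species_list) - set(rates)
        if unknown:
            raise ValueError(f"rate tables missing for species: {sorted(unknown)}")
        disease_set = set(disease_genes)
        rt = rate_table[rate_table["gene_id"].isin(disease_set)]
        comparisons = []
        m = max(len(class_dists), 1) * len(species_list)
        for sp in species_list:
            null_ratios = rt.loc[
                (rt["species"] == sp) & rt["ratio"].notna(), "ratio"
            ].to_numpy()
            for (label, level) in sorted(class_dists):
                members = set(
                    ann.loc[
                        (ann["class_label"] == label) & (ann["level"] == level),
                        "gene_id",
                    ]
                )
                class_ratios = rt.loc[
                    (rt["species"] == sp)
                    & rt["gene_id"].isin(members)
                    & rt["ratio"].notna(),
                    "ratio",
                ].to_numpy()
                if len(class_ratios) == 0 or len(null_ratios) == 0:
                    continue
                comp = sr.class_rate_deviation(
                    class_ratios, null_ratios, m,
                    label=label, species=sp, alpha=config.alpha,
                )
                comparisons.append(comp)
        pd.DataFrame(
            [(c.label, c.species, c.n, c.median.median, c.median.ci_low,
              c.median.ci_high, c.u_statistic, c.p_mwu, c.significant)
             for c in comparisons],
            columns=["class_label", "species", "n", "median_ratio", "ci_low",
                     "ci_high", "u", "p_mwu", "significant"],
        ).to_csv(out / "class_rate_comparisons.tsv", sep="\t", index=False)
        pairwise = sr.stratum_pairwise_comparison(
            assign_cl, rt, species_list, alpha=config.alpha
        )
        pairwise.to_csv(out / "stratum_pairwise.tsv", sep="\t", index=False)
        manifest["counts"]["rate_comparisons"] = len(comparisons)

    # ---- concordance -------------------------------------------------------
    with _stage("concordance", manifest):
        agreement = cc.phylostratum_agreement(assign_cl, assign_rbh)
        stratum_rbh = {a.gene_id: a.stratum.name for a in assign_rbh}
        dists_a, dists_b = {}, {}
        for (label, level), _d in class_dists.items():
            members = ann.loc[
                (ann["class_label"] == label) & (ann["level"] == level), "gene_id"
            ]
            da, db = pst.StratumDistribution(), pst.StratumDistribution()
            for g in members:
                da.counts[stratum_of[g]] += 1
                if g in stratum_rbh:
                    db.counts[stratum_rbh[g]] += 1
            if da.total and db.total:
                dists_a[label], dists_b[label] = da, db
        similarity = (
            cc.distribution_similarity_ttest(dists_a, dists_b)
            if len(dists_a) >= 2 else None
        )
        _dump_json({
            "agreement": asdict(agreement),
            "distribution_similarity": similarity,
        }, out / "concordance.json")
        manifest["counts"]["agreement_pct_exact"] = agreement.pct_exact

    manifest["parameters"]["rates_paths"] = dict(config.rates_paths)
    digest_src = json.dumps(manifest["counts"], sort_keys=True).encode()
    manifest["counts_digest"] = hashlib.sha256(digest_src).hexdigest()[:16]
    _dump_json(manifest, out / "manifest.json")
    return manifest
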