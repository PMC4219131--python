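"""Disease-class evolutionary profiling.

Selects annotation classes enriched in the disease-gene set (one-tailed
Fisher, Benjamini-Hochberg within annotation level), tests each selected
class's six-bin phylostratum distribution against the all-disease null
(Fisher on the 2x6 table, Bonferroni across classes), tests each bin for
over/under-representation (two-sided 2x2 Fisher), and classifies the
per-bin pattern into one of three evolutionary signatures — or "conforming"
when the class tracks the null.

By default the null for the 2x6 and per-bin tests is the complete
all-disease distribution including the class itself, mirroring a comparison
of each class against the full disease set; ``exclude_class_from_null``
switches to the complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model_io import STRATUM_NAMES
from .phylostratify import StratumDistribution
from .stats import fisher_2xk_p

__all__ = [
    "SIGNATURES",
    "BinRecord",
    "ClassDeviationResult",
    "enrich_annotations",
    "class_deviation_test",
    "bin_representation_tests",
    "classify_signature",
    "profile_classes",
]

SIGNATURES = (
    "vertebrate_specific",
    "early_metazoan",
    "multi_stage_metazoan",
    "conforming",
)

_EARLY_BINS = ("Metazoa", "Parahoxozoa")


@dataclass(frozen=True)
class BinRecord:
    stratum: str
    direction: str  # "over", "under" or "none"
    p: float
    significant: bool
    significant_strict: bool


@dataclass
class ClassDeviationResult:
    class_label: str
    level: int
    distribution: StratumDistribution
    p_global: float
    p_global_method: str
    significant_global: bool
    per_bin: list[BinRecord]
    signature: str


def enrich_annotations(
    annotations: pd.DataFrame,
    disease_genes,
    background_genes,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classes over-represented among disease genes (Fisher + BH per level).

    ``annotations`` has columns gene_id, level, class_label. For each class
    a 2x2 table (disease vs non-disease x annotated vs not) is tested
    one-tailed for over-representation; BH correction runs across the
    classes of each level separately. Returns a DataFrame with raw and
    adjusted p-values and a ``selected`` flag (adjusted p < alpha).
    """
    disease = set(disease_genes)
    background = set(background_genes)
    if not disease <= background:
        raise ValueError("disease genes must be a subset of the background")
    n_dis = len(disease)
    n_non = len(background) - n_dis
    rows = []
    for (level, label), grp in annotations.groupby(["level", "class_label"]):
        members = set(grp["gene_id"]) & background
        if not members:
            raise ValueError(f"class {label!r} annotates no background gene")
        a = len(members & disease)
        b = len(members) - a
        table = [[a, n_dis - a], [b, n_non - b]]
        _, p = sps.fisher_exact(table, alternative="greater")
        rows.append((label, int(level), len(members), a, float(p)))
    df = pd.DataFrame(
        rows, columns=["class_label", "level", "n_annotated", "n_disease", "p_raw"]
    )
    df["p_adj"] = np.nan
    for level, idx in df.groupby("level").groups.items():
        _, p_adj, _, _ = multipletests(df.loc[idx, "p_raw"], method="fdr_bh")
        df.loc[idx, "p_adj"] = p_adj
    df["selected"] = df["p_adj"] < alpha
    return df.sort_values(["level", "class_label"]).reset_index(drop=True)


def class_deviation_test(
    class_dist: StratumDistribution,
    null_dist: StratumDistribution,
    m_tests: int,
    *,
    alpha: float = 0.05,
    mc_reps: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, str, bool]:
    """Global 2x6 Fisher deviation test with Bonferroni significance.

    Returns ``(p, method, significant)`` where significant means
    ``p < alpha / m_tests``.
    """
    if class_dist.total == 0:
        raise ValueError("empty class distribution")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    table = np.vstack([class_dist.as_vector(), null_dist.as_vector()])
    p, method = fisher_2xk_p(table, mc_reps=mc_reps, rng=rng)
    return p, method, bool(p < alpha / m_tests)


def bin_representation_tests(
    class_dist: StratumDistribution,
    null_dist: StratumDistribution,
    m_bin_tests: int = 77,
    alpha: float = 0.05,
) -> list[BinRecord]:
    """Two-sided 2x2 Fisher per bin: class-in-bin vs null-in-bin.

    ``significant_strict`` applies the Bonferroni divisor ``m_bin_tests``
    (number of classes tested at the level).
    """
    cv = class_dist.as_vector()
    nv = null_dist.as_vector()
    ct, nt = int(cv.sum()), int(nv.sum())
    records = []
    for i, name in enumerate(STRATUM_NAMES):
        a, b = int(cv[i]), ct - int(cv[i])
        c, d = int(nv[i]), nt - int(nv[i])
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        class_prop = a / ct if ct else 0.0
        null_prop = c / nt if nt else 0.0
        if class_prop > null_prop:
            direction = "over"
        elif class_prop < null_prop:
            direction = "under"
        else:
            direction = "none"
        sig = bool(p < alpha)
        records.append(BinRecord(
            stratum=name,
            direction=direction,
            p=float(p),
            significant=sig,
            significant_strict=bool(p < alpha / m_bin_tests),
        ))
    return records


def _sig_over(rec: BinRecord) -> bool:
    return rec.significant and rec.direction == "over"


def classify_signature(per_bin: list[BinRecord]) -> str:
    """Map a per-bin over/under pattern to an evolutionary signature.

    All three non-conforming signatures require a significant
    under-representation in the basal (Filozoa) bin; they then split on
    where the significant over-representations sit: only in Vertebrata
    (vertebrate-specific), only in the early-animal bins (early metazoan),
    or in both (multi-stage metazoan).
    """
    by_name = {r.stratum: r for r in per_bin}
    filozoa = by_name["Filozoa"]
    if not (filozoa.significant and filozoa.direction == "under"):
        return "conforming"
    vert_over = _sig_over(by_name["Vertebrata"])
    early_over = any(_sig_over(by_name[n]) for n in _EARLY_BINS)
    if vert_over and early_over:
        return "multi_stage_metazoan"
    if vert_over:
        return "vertebrate_specific"
    if early_over:
        return "early_metazoan"
    return "conforming"


def profile_classes(
    class_distributions: dict[tuple[str, int], StratumDistribution],
    null_dist: StratumDistribution,
    *,
    alpha: float = 0.05,
    mc_reps: int = 100_000,
    seed: int | None = None,
) -> list[ClassDeviationResult]:
    """Run the deviation test, per-bin tests and signature call per class.

    The Bonferroni divisor per level is the number of classes tested at
    that level.
    """
    m_by_level: dict[int, int] = {}
    for (_label, level) in class_distributions:
        m_by_level[level] = m_by_level.get(level, 0) + 1
    rng = np.random.default_rng(seed)
    results = []
    for (label, level), dist in sorted(class_distributions.items()):
        m = m_by_level[level]
        p_global, method, sig_global = class_deviation_test(
            dist, null_dist, m, alpha=alpha, mc_reps=mc_reps, rng=rng
        )
        per_bin = bin_representation_tests(dist, null_dist, m_bin_tests=m, alpha=alpha)
        signature = classify_signature(per_bin) if sig_global else "conforming"
        results.append(ClassDeviationResult(
            class_label=label, level=level, distribution=dist,
            p_global=p_global, p_global_method=method,
            significant_global=sig_global, per_bin=per_bin,
            signature=signature,
        ))
    return results


def results_to_frame(results: list[ClassDeviationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "class_label": r.class_label,
            "level": r.level,
            **{f"n_{n}": r.distribution.counts[n] for n in STRATUM_NAMES},
            "p_global": r.p_global,
            "p_global_method": r.p_global_method,
            "significant_global": r.significant_global,
            "signature": r.signature,
        }
        for rec in r.per_bin:
            row[f"dir_{rec.stratum}"] = rec.direction if rec.significant else "none"
            row[f"p_{rec.stratum}"] = rec.p
        rows.append(row)
    return pd.DataFrame(rows)
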