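"""Selection-rate (dN/dS) comparisons across disease classes and strata.

Each focal gene gets one ortholog per species — the top candidate by
orthology confidence, then percent identity, then minimum dN/dS — and the
resulting per-class and per-stratum dN/dS samples are compared with
two-tailed Mann-Whitney tests under Bonferroni correction. Medians carry
distribution-free 95% confidence intervals. Records with dS = 0 carry no
ratio and are excluded from ratio statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import MedianCI, mann_whitney, median_ci

__all__ = [
    "RateRecord",
    "RateComparison",
    "select_top_ortholog",
    "build_rate_table",
    "class_rate_deviation",
    "stratum_pairwise_comparison",
]


@dataclass(frozen=True)
class RateRecord:
    gene_id: str
    species: str
    ortholog_id: str
    confidence: int
    pct_identity: float
    dN: float
    dS: float

    def __post_init__(self):
        if self.dN < 0 or self.dS < 0:
            raise ValueError("substitution rates must be non-negative")

    @property
    def ratio(self) -> float | None:
        """dN/dS, undefined (None) when dS is zero."""
        return self.dN / self.dS if self.dS > 0 else None


@dataclass
class RateComparison:
    label: str
    species: str
    n: int
    median: MedianCI
    u_statistic: float
    p_mwu: float
    mwu_method: str
    significant: bool


def select_top_ortholog(candidates: list[RateRecord]) -> RateRecord:
    """Top ortholog: confidence desc, identity desc, ratio asc, then id.

    Candidates without a defined ratio (dS = 0) sort after those with one;
    any residual tie falls to the lexicographically smallest ortholog id,
    making the choice order-independent.
    """
    if not candidates:
        raise ValueError("empty candidate list")

    def sort_key(r: RateRecord):
        ratio = r.ratio
        return (
            -r.confidence,
            -r.pct_identity,
            math.inf if ratio is None else ratio,
            r.ortholog_id,
        )

    return min(candidates, key=sort_key)


def build_rate_table(rates_by_species: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """One row per (gene, species) via the top-ortholog rule.

    Input frames have columns gene_id, ortholog_id, confidence,
    pct_identity, dN, dS; the output adds a ``ratio`` column (NaN when
    dS = 0).
    """
    out = []
    for species, df in rates_by_species.items():
        for gene_id, grp in df.groupby("gene_id", sort=True):
            cands = [
                RateRecord(
                    gene_id=str(gene_id), species=species,
                    ortholog_id=str(r.ortholog_id),
                    confidence=int(r.confidence),
                    pct_identity=float(r.pct_identity),
                    dN=float(r.dN), dS=float(r.dS),
                )
                for r in grp.itertuples()
            ]
            top = select_top_ortholog(cands)
            out.append((
                top.gene_id, species, top.ortholog_id, top.confidence,
                top.pct_identity, top.dN, top.dS,
                np.nan if top.ratio is None else top.ratio,
            ))
    return pd.DataFrame(out, columns=[
        "gene_id", "species", "ortholog_id", "confidence",
        "pct_identity", "dN", "dS", "ratio",
    ])


def class_rate_deviation(
    class_ratios,
    all_disease_ratios,
    m_tests: int,
    *,
    label: str = "",
    species: str = "",
    alpha: float = 0.05,
) -> RateComparison:
    """Two-tailed Mann-Whitney of a class's dN/dS sample against the null."""
    x = np.asarray(class_ratios, dtype=float)
    y = np.asarray(all_disease_ratios, dtype=float)
    u, p, method = mann_whitney(x, y)
    return RateComparison(
        label=label, species=species, n=len(x),
        median=median_ci(x),
        u_statistic=u, p_mwu=p, mwu_method=method,
        significant=bool(p < alpha / max(m_tests, 1)),
    )


def stratum_pairwise_comparison(
    assignments,
    rate_table: pd.DataFrame,
    species_list: list[str],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney on every stratum pair within every species.

    Restricted to genes carrying a defined ratio in *every* listed species;
    Bonferroni divisor = (number of testable pairs) x (number of species).
    Pairs where a stratum has fewer than two genes are reported as skipped.
    Empty ``species_list`` yields an empty result.
    """
    cols = [
        "species", "stratum_a", "stratum_b", "n_a", "n_b",
        "u_statistic", "p_raw", "significant", "skipped",
    ]
    if not species_list:
        return pd.DataFrame(columns=cols)
    sub = rate_table[rate_table["species"].isin(species_list)]
    ok = sub.dropna(subset=["ratio"]).groupby("gene_id")["species"].nunique()
    complete_genes = set(ok[ok == len(species_list)].index)
    stratum_of = {a.gene_id: a.stratum.name for a in assignments}
    sub = sub[sub["gene_id"].isin(complete_genes)].copy()
    sub["stratum"] = sub["gene_id"].map(stratum_of)
    sub = sub.dropna(subset=["stratum"])

    strata = sorted(sub["stratum"].unique())
    pairs = list(itertools.combinations(strata, 2))
    rows = []
    for species in species_list:
        per = sub[sub["species"] == species]
        groups = {s: per.loc[per["stratum"] == s, "ratio"].to_numpy() for s in strata}
        for sa, sb in pairs:
            xa, xb = groups.get(sa, ()), groups.get(sb, ())
            if len(xa) < 2 or len(xb) < 2:
                rows.append((species, sa, sb, len(xa), len(xb),
                             np.nan, np.nan, False, True))
                continue
            u, p, _ = mann_whitney(xa, xb)
            rows.append((species, sa, sb, len(xa), len(xb), u, p, None, False))
    df = pd.DataFrame(rows, columns=cols)
    m = int((~df["skipped"]).sum())
    df.loc[~df["skipped"], "significant"] = (
        df.loc[~df["skipped"], "p_raw"] < alpha / max(m, 1)
    )
    df["significant"] = df["significant"].astype(bool)
    df.attrs["bonferroni_m"] = m
    return df
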