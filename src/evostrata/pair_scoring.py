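"""Gene-pair scores from chained HSPs, and reciprocal-best-hit calls.

The clustering algorithm works on one aggregate bit score per gene pair.
That score is the best colinear chain of the pair's HSPs: HSPs strictly
increasing in both query and subject start coordinate, where two adjacent
chain members may overlap by less than 5% of the shorter member's span on
the worse axis, and each admissible overlap is penalized by the score mass
of the overlapped residues — max over the two HSPs of
``overlap_length * bit_score / aln_length``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model_io import HSP

__all__ = [
    "GenePairScore",
    "RBHPair",
    "chain_and_score",
    "build_pair_table",
    "directed_best_hits",
    "compute_rbh",
    "write_pair_table",
    "read_pair_table",
]

MAX_OVERLAP_FRACTION = 0.05


@dataclass(frozen=True)
class GenePairScore:
    gene_a: str
    gene_b: str
    score: float
    best_evalue: float
    n_hsps_used: int

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


@dataclass(frozen=True)
class RBHPair:
    focal_gene: str
    other_gene: str
    other_species: str
    e_forward: float
    e_reverse: float


def _overlap_penalty(first: HSP, second: HSP):
    """(admissible, penalty) for placing ``second`` after ``first`` in a chain.

    Overlap is measured on the axis where it is largest, as a fraction of the
    shorter HSP's span on that axis; fractions >= 5% bar the two HSPs from
    co-occurring. The penalty charges the overlapped residues at each HSP's
    own per-residue score, taking the larger.
    """
    ov_q = max(0, first.q_end - second.q_start + 1)
    ov_s = max(0, first.s_end - second.s_start + 1)
    if ov_q >= ov_s:
        ov, span = ov_q, min(first.q_span, second.q_span)
    else:
        ov, span = ov_s, min(first.s_span, second.s_span)
    if ov == 0:
        return True, 0.0
    if ov / span >= MAX_OVERLAP_FRACTION:
        return False, 0.0
    penalty = max(
        ov * first.bit_score / first.aln_length,
        ov * second.bit_score / second.aln_length,
    )
    return True, penalty


def chain_and_score(hsps: list[HSP]) -> GenePairScore:
    """Best colinear penalized chain over one gene pair's HSPs.

    Dynamic programme over HSPs sorted by query start; a predecessor must
    strictly precede in both query and subject start, and the adjacent
    overlap (if any) must be admissible. The chain score is the sum of
    member bit scores minus the adjacent-overlap penalties.
    """
    if not hsps:
        raise ValueError("empty HSP list")
    pair = {frozenset((h.query_id, h.subject_id)) for h in hsps}
    if len(pair) != 1:
        raise ValueError(f"HSPs mix gene pairs: {sorted(map(sorted, pair))}")
    order = sorted(hsps, key=lambda h: (h.q_start, h.s_start, -h.bit_score))
    n = len(order)
    best = [h.bit_score for h in order]
    back = [-1] * n
    for i in range(n):
        hi = order[i]
        for j in range(i):
            hj = order[j]
            if hj.q_start >= hi.q_start or hj.s_start >= hi.s_start:
                continue
            ok, penalty = _overlap_penalty(hj, hi)
            if not ok:
                continue
            cand = best[j] + hi.bit_score - penalty
            if cand > best[i]:
                best[i] = cand
                back[i] = j
    end = max(range(n), key=lambda i: best[i])
    members = []
    i = end
    while i != -1:
        members.append(order[i])
        i = back[i]
    return GenePairScore(
        gene_a=order[0].query_id,
        gene_b=order[0].subject_id,
        score=float(best[end]),
        best_evalue=min(h.e_value for h in members),
        n_hsps_used=len(members),
    )


def build_pair_table(hsps: list[HSP]) -> dict[tuple[str, str], GenePairScore]:
    """Chain HSPs per directed pair, keep the better direction per pair.

    Self-hits are dropped. Keys are sorted (gene_a, gene_b) tuples.
    """
    directed: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        if h.query_id == h.subject_id:
            continue
        directed.setdefault((h.query_id, h.subject_id), []).append(h)
    table: dict[tuple[str, str], GenePairScore] = {}
    for (q, s), group in directed.items():
        gps = chain_and_score(group)
        key = tuple(sorted((q, s)))
        prev = table.get(key)
        if prev is None or gps.score > prev.score:
            table[key] = GenePairScore(
                gene_a=key[0], gene_b=key[1],
                score=gps.score, best_evalue=gps.best_evalue,
                n_hsps_used=gps.n_hsps_used,
            )
    return table


def directed_best_hits(
    pair_table: dict[tuple[str, str], GenePairScore],
    species_of: dict[str, str],
) -> dict[tuple[str, str], tuple[str, float, float]]:
    """Resolve each gene's best partner per target species.

    Returns (gene, target_species) -> (partner, score, e_value). Ties are
    broken by higher score, then lexicographically smaller partner id (which
    always resolves two distinct partners).
    """
    best: dict[tuple[str, str], tuple[str, float, float]] = {}
    for (a, b), gps in pair_table.items():
        for g, partner in ((a, b), (b, a)):
            sp = species_of.get(partner)
            if sp is None:
                continue
            key = (g, sp)
            cur = best.get(key)
            if cur is None or gps.score > cur[1] or (
                gps.score == cur[1] and partner < cur[0]
            ):
                best[key] = (partner, gps.score, gps.best_evalue)
    return best


def compute_rbh(
    best_hits: dict[tuple[str, str], tuple[str, float, float]],
    species_of: dict[str, str],
    focal_species: str,
    e_max: float = 1e-3,
) -> list[RBHPair]:
    """Reciprocal best hits between the focal species and every other.

    (f, g) is a pair iff g is f's best hit within g's species, f is g's best
    hit within the focal species, and both e-values are below ``e_max``.
    The result is one-to-one per (focal gene, other species).
    """
    pairs: list[RBHPair] = []
    for (gene, target_sp), (partner, _score, e_fwd) in best_hits.items():
        if species_of.get(gene) != focal_species or target_sp == focal_species:
            continue
        reverse = best_hits.get((partner, focal_species))
        if reverse is None:
            continue
        back, _s, e_rev = reverse
        if back == gene and e_fwd < e_max and e_rev < e_max:
            pairs.append(RBHPair(gene, partner, target_sp, e_fwd, e_rev))
    pairs.sort(key=lambda p: (p.focal_gene, p.other_species))
    return pairs


def write_pair_table(table: dict, path) -> None:
    rows = [
        (g.gene_a, g.gene_b, g.score, g.best_evalue, g.n_hsps_used)
        for g in table.values()
    ]
    df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "score", "best_evalue", "n_hsps_used"]
    ).sort_values(["gene_a", "gene_b"])
    df.to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> dict[tuple[str, str], GenePairScore]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    table = {}
    for r in df.itertuples():
        gps = GenePairScore(r.gene_a, r.gene_b, float(r.score),
                            float(r.best_evalue), int(r.n_hsps_used))
        table[gps.key] = gps
    return table
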