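"""Domain model and file I/O for phylostratigraphic profiling.

This module defines the six phylostrata used to bin gene origins along the
path from the animal/unicellular ancestor (Filozoa) to the focal vertebrate
species, a validated species-tree wrapper, the HSP record consumed from
BLAST tabular output, and the bookkeeping used to filter a disease-gene
list down to the genes that both map to proteins and fall into ortholog
clusters.

Coordinates are 1-based inclusive everywhere, following the BLAST tabular
convention; nothing in the package converts them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import pandas as pd

__all__ = [
    "STRATUM_NAMES",
    "PHYLOSTRATA",
    "Phylostratum",
    "stratum_by_name",
    "SpeciesTree",
    "HSP",
    "GeneRecord",
    "FilterReport",
    "parse_species_tree",
    "load_default_tree",
    "read_stratum_table",
    "read_blast_tab",
    "read_gene_tables",
    "filter_disease_genes",
]

#: Bin names ordered from the most basal divergence toward the focal species.
STRATUM_NAMES = (
    "Filozoa",
    "Metazoa",
    "Parahoxozoa",
    "Bilateria",
    "Deuterostomia",
    "Vertebrata",
)


@dataclass(frozen=True, order=True)
class Phylostratum:
    """One of the six taxonomic bins; rank 0 is the most basal (Filozoa)."""

    rank: int
    name: str


PHYLOSTRATA = tuple(Phylostratum(i, n) for i, n in enumerate(STRATUM_NAMES))
_BY_NAME = {p.name: p for p in PHYLOSTRATA}


def stratum_by_name(name: str) -> Phylostratum:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ValueError(
            f"unknown phylostratum {name!r}; expected one of {STRATUM_NAMES}"
        ) from None


class SpeciesTreeError(ValueError):
    """Raised when a species tree violates the model's invariants."""


class SpeciesTree:
    """A rooted binary species tree with per-leaf phylostratum labels.

    Leaves carry species codes (``Hs``, ``Nv``, ...); exactly one leaf is
    flagged focal and must carry the highest-ranked stratum present. The
    strata must be monophyletically consistent: walking the root-to-focal
    path, every subtree that branches off the path is uniform in stratum and
    the stratum ranks never decrease.

    Use :func:`parse_species_tree` to construct a validated instance.
    """

    def __init__(self, tree: dendropy.Tree, stratum_of: dict[str, Phylostratum],
                 focal: str):
        self._tree = tree
        self._stratum_of = dict(stratum_of)
        self.focal = focal
        self._index_nodes()
        self._validate()

    # -- construction helpers -------------------------------------------

    def _index_nodes(self) -> None:
        for i, node in enumerate(self._tree.postorder_node_iter()):
            node.postorder_index = i
            if node.is_leaf():
                node.leafset = frozenset({node.taxon.label})
            else:
                node.leafset = frozenset().union(
                    *(c.leafset for c in node.child_nodes())
                )
        self._leaf_order = [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def _validate(self) -> None:
        leaves = set(self._leaf_order)
        if len(self._leaf_order) != len(leaves):
            raise SpeciesTreeError("duplicate species codes among leaves")
        missing = leaves - set(self._stratum_of)
        if missing:
            raise SpeciesTreeError(f"leaves missing from stratum table: {sorted(missing)}")
        extra = set(self._stratum_of) - leaves
        if extra:
            raise SpeciesTreeError(f"stratum table species not in tree: {sorted(extra)}")
        if self.focal not in leaves:
            raise SpeciesTreeError(f"focal species {self.focal!r} is not a leaf")
        for node in self._tree.preorder_node_iter():
            n = len(node.child_nodes())
            if node is self._tree.seed_node and len(leaves) == 1:
                continue  # degenerate single-leaf tree
            if n not in (0, 2):
                raise SpeciesTreeError(
                    f"non-binary node with {n} children over leaves "
                    f"{sorted(node.leafset)}; resolve the tree before use"
                )
        self._check_stratum_monophyly()

    def _check_stratum_monophyly(self) -> None:
        """Off-path clades must be stratum-uniform with non-decreasing rank."""
        node = self._tree.seed_node
        prev_rank = -1
        while not node.is_leaf():
            on_path = [c for c in node.child_nodes() if self.focal in c.leafset]
            off_path = [c for c in node.child_nodes() if self.focal not in c.leafset]
            if len(on_path) != 1:
                raise SpeciesTreeError("focal path is ambiguous")
            for clade in off_path:
                ranks = {self._stratum_of[s].rank for s in clade.leafset}
                if len(ranks) != 1:
                    raise SpeciesTreeError(
                        f"stratum not monophyletic: clade {sorted(clade.leafset)} "
                        "mixes strata"
                    )
                rank = ranks.pop()
                if rank < prev_rank:
                    raise SpeciesTreeError(
                        f"stratum ranks decrease along the focal path at clade "
                        f"{sorted(clade.leafset)}"
                    )
                prev_rank = rank
            node = on_path[0]
        focal_rank = self._stratum_of[self.focal].rank
        if focal_rank < prev_rank:
            raise SpeciesTreeError("focal species does not carry the most recent stratum")

    # -- queries ---------------------------------------------------------

    @property
    def species(self) -> list[str]:
        """Leaf labels in tree order."""
        return list(self._leaf_order)

    def stratum_of(self, species: str) -> Phylostratum:
        try:
            return self._stratum_of[species]
        except KeyError:
            raise SpeciesTreeError(f"unknown species code {species!r}") from None

    @property
    def strata_present(self) -> list[Phylostratum]:
        return sorted({self._stratum_of[s] for s in self._leaf_order})

    @property
    def root(self):
        return self._tree.seed_node

    def postorder_internal_nodes(self):
        for node in self._tree.postorder_node_iter():
            if not node.is_leaf():
                yield node

    def species_of_rank_at_least(self, rank: int) -> frozenset[str]:
        return frozenset(
            s for s in self._leaf_order if self._stratum_of[s].rank >= rank
        )

    def origin_node_for_rank(self, rank: int):
        """The focal-path ancestor where the given stratum's clade attaches.

        This is the MRCA of all species with rank >= ``rank`` — the node a
        gene family born in that stratum descends from.
        """
        want = self.species_of_rank_at_least(rank)
        node = self._tree.seed_node
        while True:
            for child in node.child_nodes():
                if want <= child.leafset:
                    node = child
                    break
            else:
                return node

    def __len__(self) -> int:
        return len(self._leaf_order)


def read_stratum_table(path_or_buf) -> pd.DataFrame:
    """Read a stratum TSV with columns species_code, stratum_name, is_focal."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"species_code": str})
    required = {"species_code", "stratum_name", "is_focal"}
    if not required <= set(df.columns):
        raise ValueError(f"stratum table must have columns {sorted(required)}")
    return df


def parse_species_tree(newick_text: str, stratum_table: pd.DataFrame) -> SpeciesTree:
    """Parse and validate a rooted species tree against a stratum table.

    ``stratum_table`` has columns species_code, stratum_name, is_focal
    (exactly one row with is_focal truthy).
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise SpeciesTreeError(f"unparseable newick: {exc}") from exc
    stratum_of = {
        str(r.species_code): stratum_by_name(str(r.stratum_name))
        for r in stratum_table.itertuples()
    }
    focal_rows = stratum_table[stratum_table["is_focal"].astype(int) == 1]
    if len(focal_rows) != 1:
        raise SpeciesTreeError("exactly one focal species is required")
    focal = str(focal_rows.iloc[0]["species_code"])
    return SpeciesTree(tree, stratum_of, focal)


def load_default_tree() -> SpeciesTree:
    """The packaged 23-species tree with its six-stratum labelling."""
    pkg = resources.files("evostrata.data")
    newick = (pkg / "species_tree.nwk").read_text()
    table = read_stratum_table(io.StringIO((pkg / "phylostrata.tsv").read_text()))
    return parse_species_tree(newick, table)


# ---------------------------------------------------------------------------
# BLAST tabular input
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HSP:
    """One BLASTP high-scoring segment pair (outfmt 6 row)."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aln_length: int
    bit_score: float
    e_value: float

    def __post_init__(self):
        if self.q_start > self.q_end:
            raise ValueError(f"q_start > q_end in HSP {self.query_id}/{self.subject_id}")
        if self.s_start > self.s_end:
            raise ValueError(
                f"s_start > s_end in HSP {self.query_id}/{self.subject_id}; "
                "reversed protein coordinates are not valid"
            )
        if self.bit_score <= 0:
            raise ValueError("bit_score must be positive")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start + 1


_OUTFMT6_NCOLS = 12


def read_blast_tab(path) -> list[HSP]:
    """Read BLAST tabular (outfmt 6) into HSP records.

    Comment lines starting with ``#`` are skipped. Coordinates stay 1-based
    inclusive. Rows with a wrong column count or non-numeric numeric fields
    raise ``ValueError``.
    """
    hsps: list[HSP] = []
    opened = open(path) if not hasattr(path, "read") else path
    try:
        for lineno, line in enumerate(opened, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _OUTFMT6_NCOLS:
                raise ValueError(
                    f"line {lineno}: expected {_OUTFMT6_NCOLS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                hsp = HSP(
                    query_id=fields[0],
                    subject_id=fields[1],
                    aln_length=int(fields[3]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            hsps.append(hsp)
    finally:
        if opened is not path:
            opened.close()
    return hsps


# ---------------------------------------------------------------------------
# Gene / annotation / rate tables
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    gene_id: str
    species: str
    mapped: bool
    clustered: bool = True


@dataclass
class FilterReport:
    total: int
    n_unmapped: int
    n_unclustered: int
    n_retained: int

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "n_unmapped": self.n_unmapped,
            "n_unclustered": self.n_unclustered,
            "n_retained": self.n_retained,
        }


def read_gene_tables(genes_path, annotations_path, rates_paths: dict):
    """Read the gene, annotation and per-species rate tables.

    Returns ``(genes, annotations, rates)`` where ``genes`` is a DataFrame
    (gene_id, species, mapped[, clustered]), ``annotations`` a DataFrame
    (gene_id, level, class_label) and ``rates`` a dict species ->
    DataFrame (gene_id, ortholog_id, confidence, pct_identity, dN, dS).

    Duplicate (gene_id, ortholog_id) rate rows raise; annotations naming
    genes absent from the gene table are kept (the caller may warn).
    """
    genes = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str, "species": str})
    if "mapped" not in genes.columns:
        raise ValueError("gene table needs a 'mapped' column")
    genes["mapped"] = genes["mapped"].astype(int).astype(bool)
    if "clustered" in genes.columns:
        genes["clustered"] = genes["clustered"].astype(int).astype(bool)
    dup = genes.duplicated(subset=["gene_id", "species"])
    if dup.any():
        raise ValueError(
            f"duplicate gene rows: {genes.loc[dup, ['gene_id', 'species']].values.tolist()}"
        )

    annotations = pd.read_csv(
        annotations_path, sep="\t",
        dtype={"gene_id": str, "class_label": str},
    )
    if annotations.empty and list(annotations.columns) != ["gene_id", "level", "class_label"]:
        annotations = pd.DataFrame(columns=["gene_id", "level", "class_label"])

    rates: dict[str, pd.DataFrame] = {}
    for species, path in rates_paths.items():
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "ortholog_id": str})
        dup = df.duplicated(subset=["gene_id", "ortholog_id"])
        if dup.any():
            key = df.loc[dup, ["gene_id", "ortholog_id"]].iloc[0].tolist()
            raise ValueError(f"duplicate rate row for {tuple(key)} in species {species!r}")
        rates[species] = df
    return genes, annotations, rates


def filter_disease_genes(gene_records) -> tuple[list, FilterReport]:
    """Keep genes that mapped to proteins AND fell into a cluster.

    A gene failing both filters is tallied once, as unmapped (mapping is the
    earlier pipeline stage), so the three tallies are disjoint and
    ``retained + unmapped + unclustered == total``.
    """
    retained, n_unmapped, n_unclustered = [], 0, 0
    records = list(gene_records)
    for rec in records:
        if not rec.mapped:
            n_unmapped += 1
        elif not rec.clustered:
            n_unclustered += 1
        else:
            retained.append(rec)
    report = FilterReport(
        total=len(records),
        n_unmapped=n_unmapped,
        n_unclustered=n_unclustered,
        n_retained=len(retained),
    )
    return retained, report
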