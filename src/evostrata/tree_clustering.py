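"""Phylogenetically aware ortholog clustering.

Genes start as singletons at the leaves of the species tree and are merged
bottom-up. At each internal node, two steps run:

1. *Mutual best merge.* A set (or gene) from one child is combined with a
   set from the other child when each is the other's unique best-scoring
   partner. "Best" is global: the argmax runs over every scored partner of
   the entity's member genes — other-child entities, same-child entities,
   and outgroup genes alike — so a stronger hit to an outgroup pre-empts
   the merge.

2. *Ordered scan with blocking.* Every gene-pair score with at least one
   endpoint inside the node's subtree is visited in descending score order
   (ties broken on the sorted gene-id pair). A hit from a subtree entity to
   an outgroup gene blocks that entity for the remainder of the node's
   scan; a hit joining two distinct unblocked subtree entities merges them.
   Blocked flags are cleared when the next node is visited.

The scheme assumes each family arose once (Dollo-style single origin):
membership only ever grows while ascending the tree. Note that at the root
no outgroup exists, so any chain of surviving hits merges its endpoints —
input hit tables should already be thresholded to hits worth trusting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "OrthoEntity",
    "OrthoCluster",
    "PresenceMatrix",
    "process_node",
    "cluster_orthologs",
    "build_presence_matrix",
    "write_clusters",
    "read_clusters",
    "write_presence_matrix",
    "read_presence_matrix",
]


@dataclass
class OrthoEntity:
    """A gene or merged set of putative orthologs during clustering."""

    genes: set[str]
    home_node: int  # postorder index of the node where last merged
    blocked: bool = False

    @property
    def anchor(self) -> str:
        """Deterministic representative (lexicographically least member)."""
        return min(self.genes)


@dataclass(frozen=True)
class OrthoCluster:
    cluster_id: str
    genes: tuple[str, ...]
    species: frozenset[str]


@dataclass
class PresenceMatrix:
    """Focal-gene x species boolean ortholog-presence table."""

    data: pd.DataFrame  # bool, rows = focal genes, columns = species
    missing: list[str] = field(default_factory=list)  # focal genes in no cluster


def _score_of(value) -> float:
    return value if isinstance(value, (int, float)) else value.score


def _build_adjacency(pair_scores) -> dict[str, list[tuple[str, float]]]:
    adj: dict[str, list[tuple[str, float]]] = {}
    for (a, b), v in pair_scores.items():
        s = _score_of(v)
        adj.setdefault(a, []).append((b, s))
        adj.setdefault(b, []).append((a, s))
    return adj


def _merge(ea: OrthoEntity, eb: OrthoEntity, gene_entity, node_index) -> OrthoEntity:
    if len(ea.genes) < len(eb.genes):
        ea, eb = eb, ea
    ea.genes |= eb.genes
    for g in eb.genes:
        gene_entity[g] = ea
    ea.home_node = node_index
    ea.blocked = False
    return ea


def process_node(
    node_index: int,
    left_entities: list[OrthoEntity],
    right_entities: list[OrthoEntity],
    adjacency: dict[str, list[tuple[str, float]]],
    log: list | None = None,
) -> list[OrthoEntity]:
    """Run the two merge steps at one internal node; returns surviving entities.

    Genes absent from the entity map are, by construction, outgroup genes:
    every gene of a subtree species already has an entity at this point.
    """
    entities = list(left_entities) + list(right_entities)
    gene_entity: dict[str, OrthoEntity] = {}
    side: dict[int, str] = {}
    for ent in left_entities:
        side[id(ent)] = "L"
        for g in ent.genes:
            gene_entity[g] = ent
    for ent in right_entities:
        side[id(ent)] = "R"
        for g in ent.genes:
            gene_entity[g] = ent

    # ---- Step 1: simultaneous mutual-best merges across children --------
    best: dict[int, tuple[float, object, bool]] = {}  # id(ent) -> (score, target, unique)
    for ent in entities:
        top_score, top_obj, unique = -1.0, None, True
        for g in ent.genes:
            for partner, s in adjacency.get(g, ()):  # partner may be anywhere
                if partner in ent.genes:
                    continue
                other = gene_entity.get(partner)
                obj = other if other is not None else ("out", partner)
                if s > top_score:
                    top_score, top_obj, unique = s, obj, True
                elif s == top_score and obj is not top_obj and obj != top_obj:
                    unique = False
        if top_obj is not None:
            best[id(ent)] = (top_score, top_obj, unique)

    merges: list[tuple[OrthoEntity, OrthoEntity]] = []
    for ent in left_entities:
        rec = best.get(id(ent))
        if rec is None:
            continue
        _s, target, unique = rec
        if not unique or not isinstance(target, OrthoEntity):
            continue
        if side.get(id(target)) != "R":
            continue
        back = best.get(id(target))
        if back is None:
            continue
        _s2, back_target, back_unique = back
        if back_unique and back_target is ent:
            merges.append((ent, target))

    alive = {id(e): e for e in entities}
    for ea, eb in merges:
        if log is not None:
            log.append({
                "node": node_index, "step": 1, "action": "merge",
                "a": sorted(ea.genes), "b": sorted(eb.genes),
            })
        merged = _merge(ea, eb, gene_entity, node_index)
        for dead in (ea, eb):
            if dead is not merged:
                alive.pop(id(dead))

    # ---- Step 2: descending-score scan with outgroup blocking -----------
    for ent in alive.values():
        ent.blocked = False
    subtree_genes = set(gene_entity)
    candidates: list[tuple[float, tuple[str, str]]] = []
    for g in subtree_genes:
        for partner, s in adjacency.get(g, ()):
            if partner in subtree_genes:
                if g < partner:
                    candidates.append((s, (g, partner)))
            else:
                key = (g, partner) if g < partner else (partner, g)
                candidates.append((s, key))
    candidates.sort(key=lambda t: (-t[0], t[1]))

    for score, (a, b) in candidates:
        ea = gene_entity.get(a)
        eb = gene_entity.get(b)
        if ea is not None and eb is not None:
            if ea is eb or ea.blocked or eb.blocked:
                continue
            if log is not None:
                log.append({
                    "node": node_index, "step": 2, "action": "merge",
                    "a": sorted(ea.genes), "b": sorted(eb.genes), "score": score,
                })
            merged = _merge(ea, eb, gene_entity, node_index)
            for dead in (ea, eb):
                if dead is not merged:
                    alive.pop(id(dead))
        else:
            ent = ea if ea is not None else eb
            if ent is None:  # both endpoints outside the subtree: not listed
                continue
            if not ent.blocked:
                ent.blocked = True
                if log is not None:
                    log.append({
                        "node": node_index, "step": 2, "action": "block",
                        "entity": sorted(ent.genes),
                        "outgroup_gene": b if ent is ea else a,
                        "score": score,
                    })
    return list(alive.values())


def cluster_orthologs(
    tree,
    pair_scores: dict,
    genes_by_species: dict[str, list[str]],
    *,
    log: list | None = None,
    debug: bool = False,
) -> list[OrthoCluster]:
    """Cluster all genes by post-order traversal of the species tree.

    ``pair_scores`` maps sorted (gene_a, gene_b) tuples to a score (float or
    GenePairScore); ``genes_by_species`` lists every gene per species code.
    Every input gene ends up in exactly one cluster.
    """
    tree_species = set(tree.species)
    species_of: dict[str, str] = {}
    for sp, genes in genes_by_species.items():
        if sp not in tree_species:
            raise ValueError(f"species {sp!r} is not a leaf of the species tree")
        for g in genes:
            species_of[g] = sp
    for a, b in pair_scores:
        for g in (a, b):
            if g not in species_of:
                raise ValueError(f"gene {g!r} in pair scores has no species assignment")

    adjacency = _build_adjacency(pair_scores)
    entities_at: dict[int, list[OrthoEntity]] = {}

    def leaf_entities(node):
        sp = next(iter(node.leafset))
        return [
            OrthoEntity(genes={g}, home_node=node.postorder_index)
            for g in sorted(genes_by_species.get(sp, ()))
        ]

    root_entities: list[OrthoEntity] = []
    for node in tree.root.postorder_iter():
        if node.is_leaf():
            entities_at[node.postorder_index] = leaf_entities(node)
            continue
        children = node.child_nodes()
        if len(children) == 1:  # degenerate single-leaf tree
            ents = entities_at[children[0].postorder_index]
        else:
            left, right = children
            ents = process_node(
                node.postorder_index,
                entities_at[left.postorder_index],
                entities_at[right.postorder_index],
                adjacency,
                log=log,
            )
        if debug:
            expected = {
                g for sp in node.leafset for g in genes_by_species.get(sp, ())
            }
            got: list[str] = []
            for e in ents:
                got.extend(e.genes)
            assert sorted(got) == sorted(expected), (
                f"partition violated at node {node.postorder_index}"
            )
        entities_at[node.postorder_index] = ents
        root_entities = ents

    if not root_entities:  # tree with a single leaf and no internal node
        root_entities = entities_at[tree.root.postorder_index]

    ordered = sorted(root_entities, key=lambda e: e.anchor)
    width = max(5, len(str(len(ordered))))
    clusters = []
    for i, ent in enumerate(ordered, start=1):
        genes = tuple(sorted(ent.genes))
        clusters.append(OrthoCluster(
            cluster_id=f"C{i:0{width}d}",
            genes=genes,
            species=frozenset(species_of[g] for g in genes),
        ))
    return clusters


def build_presence_matrix(
    clusters: list[OrthoCluster],
    focal_gene_list: list[str],
    tree,
    genes_by_species: dict[str, list[str]] | None = None,
) -> PresenceMatrix:
    """One boolean row per focal gene: which species its cluster spans.

    Focal genes that belong to no cluster are excluded and reported in
    ``missing`` rather than raising.
    """
    cluster_of: dict[str, OrthoCluster] = {}
    species_of_gene: dict[str, str] = {}
    if genes_by_species:
        for sp, genes in genes_by_species.items():
            for g in genes:
                species_of_gene[g] = sp
    for cl in clusters:
        for g in cl.genes:
            cluster_of[g] = cl
    cols = tree.species
    rows, index, missing = [], [], []
    for g in focal_gene_list:
        cl = cluster_of.get(g)
        if cl is None:
            missing.append(g)
            continue
        rows.append([sp in cl.species for sp in cols])
        index.append(g)
    df = pd.DataFrame(rows, index=index, columns=cols, dtype=bool)
    return PresenceMatrix(data=df, missing=missing)


# ---------------------------------------------------------------------------
# TSV round-trips
# ---------------------------------------------------------------------------

def write_clusters(clusters, species_of: dict[str, str], path) -> None:
    rows = [
        (cl.cluster_id, g, species_of[g]) for cl in clusters for g in cl.genes
    ]
    pd.DataFrame(rows, columns=["cluster_id", "gene_id", "species"]).to_csv(
        path, sep="\t", index=False
    )


def read_clusters(path) -> list[OrthoCluster]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    clusters = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        genes = tuple(sorted(grp["gene_id"]))
        clusters.append(OrthoCluster(
            cluster_id=str(cid), genes=genes,
            species=frozenset(grp["species"]),
        ))
    return clusters


def write_presence_matrix(pm: PresenceMatrix, path) -> None:
    out = pm.data.astype(int)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_presence_matrix(path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id").astype(bool)
    return PresenceMatrix(data=df)
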