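"""Naive step-logging reference for the tree-guided clustering rules.

Written independently of the package implementation: entities are plain
frozensets, best partners are recomputed from the raw pair list at every
use, and the two merge steps follow the stated rules literally. Quadratic
and slow — only for small oracle cases in tests.
"""

from __future__ import annotations


def _entity_of(entities, gene):
    for e in entities:
        if gene in e:
            return e
    return None


def _best_partner(entity, entities, pair_scores, subtree_genes):
    """(best_object, score, unique): argmax over ALL partners of the entity."""
    best_obj, best_score, unique = None, float("-inf"), True
    for (a, b), s in pair_scores.items():
        for g, p in ((a, b), (b, a)):
            if g in entity and p not in entity:
                if p in subtree_genes:
                    obj = _entity_of(entities, p)
                else:
                    obj = ("outgroup", p)
                if s > best_score:
                    best_obj, best_score, unique = obj, s, True
                elif s == best_score and obj != best_obj:
                    unique = False
    return best_obj, best_score, unique


def reference_cluster(tree, pair_scores, genes_by_species, log=None):
    """Final clusters (set of frozensets) under the two-step node rules."""
    scores = {tuple(sorted(k)): (v if isinstance(v, (int, float)) else v.score)
              for k, v in pair_scores.items()}

    def visit(node):
        if node.is_leaf():
            sp = next(iter(node.leafset))
            return [frozenset({g}) for g in genes_by_species.get(sp, ())]
        children = node.child_nodes()
        if len(children) == 1:
            return visit(children[0])
        left = visit(children[0])
        right = visit(children[1])
        entities = left + right
        subtree_genes = {g for e in entities for g in e}

        # Step 1: simultaneous mutual (global) best merges across children
        merges = []
        for e in left:
            obj, _s, unique = _best_partner(e, entities, scores, subtree_genes)
            if not unique or not isinstance(obj, frozenset) or obj not in right:
                continue
            back, _s2, back_unique = _best_partner(obj, entities, scores, subtree_genes)
            if back_unique and back == e:
                merges.append((e, obj))
        for e, f in merges:
            entities.remove(e)
            entities.remove(f)
            entities.append(e | f)
            if log is not None:
                log.append(("step1-merge", node.postorder_index,
                            tuple(sorted(e | f))))

        # Step 2: descending-score scan, outgroup hits block
        candidates = []
        for (a, b), s in scores.items():
            if a in subtree_genes or b in subtree_genes:
                candidates.append((s, (a, b)))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        blocked = []
        for s, (a, b) in candidates:
            ea = _entity_of(entities, a) if a in subtree_genes else None
            eb = _entity_of(entities, b) if b in subtree_genes else None
            if ea is not None and eb is not None:
                if ea == eb:
                    continue
                if any(ea == x for x in blocked) or any(eb == x for x in blocked):
                    continue
                entities.remove(ea)
                entities.remove(eb)
                entities.append(ea | eb)
                if log is not None:
                    log.append(("step2-merge", node.postorder_index,
                                tuple(sorted(ea | eb))))
            else:
                ent = ea if ea is not None else eb
                if ent is not None and not any(ent == x for x in blocked):
                    blocked.append(ent)
                    if log is not None:
                        log.append(("block", node.postorder_index,
                                    tuple(sorted(ent))))
        return entities

    final = visit(tree.root)
    return {frozenset(e) for e in final}
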