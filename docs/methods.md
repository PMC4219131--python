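# Methods

## The model

The package treats the origin of a gene family as a single event on a
rooted species tree (Dollo parsimony): a family is born once at an
ancestor and may be lost independently on any descendant branch, but
never regained. Under this model the *phylostratum* of a focal-species
gene — the most basal taxonomic bin containing a species with a
detectable ortholog — estimates the lineage in which the family arose.
Six bins are used, defined by the successive divergences along the path
from the filozoan ancestor (animals plus their closest unicellular
relatives) to the focal vertebrate: Filozoa, Metazoa, Parahoxozoa,
Bilateria, Deuterostomia, Vertebrata. The packaged default tree has 23
species with each bin attached as one or more monophyletic clades off
that path; any user tree passing the same validation (rooted, binary,
stratum-uniform off-path clades with non-decreasing rank) is accepted.
Genes detected only in the focal species fall in the most recent bin —
the six-bin scheme has no separate "focal-specific" category.

## Pair scores from HSPs

BLASTP reports local alignment blocks (HSPs) per gene pair. The
clustering algorithm needs a single edge weight, computed as the best
*colinear chain*: HSPs strictly increasing in both query and subject
start coordinate. Two adjacent chain members may overlap by less than 5%
— the overlap length on the worse axis divided by the shorter HSP's span
on that axis — and each admissible overlap is penalized by the score
mass of the doubly counted residues, `max` over the two HSPs of
`overlap_length * bit_score / aln_length`. The chain maximizing the
penalized total is found by dynamic programming over HSPs sorted by
query start; penalties attach only between consecutive members, so the
DP is exact (verified against exhaustive chain enumeration in the test
suite). "Overlapping less than 5%" needs a denominator; we measure
against the shorter HSP's span on the axis with the larger overlap,
which is the stricter of the plausible readings. Where hits exist in
both directions for a pair, both directed aggregates are computed and
the larger kept. Coordinates are 1-based inclusive throughout.

An alternative reading of the penalty — a literal
`overlap_fraction x score / length` — was rejected: it yields penalties
three to four orders of magnitude below the scores and makes the 5%
admissibility rule the only active constraint.

## Tree-guided clustering

Genes start as singletons at the leaves. At each internal node, two
steps:

1. **Mutual best merge.** An entity from one child merges with an entity
   from the other child when each is the other's *unique global*
   best-scoring partner. The argmax runs over every scored partner —
   entities of either child and outgroup genes alike — so a stronger hit
   to an outgroup pre-empts the merge. Entity-to-entity score is the max
   over member gene pairs (single-linkage; order-independent). Score
   ties for the best partner mean no merge (conservative). All mutual
   bests are identified simultaneously, then applied in one pass.
2. **Ordered scan with blocking.** Every pair score with at least one
   endpoint in the node's subtree is visited in descending score order,
   ties broken lexicographically on the sorted gene-id pair (making the
   whole procedure deterministic under input reordering). A hit from a
   subtree entity to an outgroup gene blocks that entity for the rest of
   this node's scan; a hit joining two distinct unblocked subtree
   entities merges them (the merged entity is unblocked). Blocked flags
   are cleared when the next node is visited. Only the subtree-side
   entity of an outgroup hit is blocked.

Entities surviving at the root are the ortholog clusters; membership
only grows while ascending the tree, and after every node the entities
partition the genes of the subtree's species (asserted in debug mode).

A structural consequence worth knowing: at the root there is no outgroup,
so no blocking is possible and any chain of surviving hits merges its
endpoints. The final partition therefore equals the connected components
of the hit graph; the tree's contribution is *which* intermediate
entities exist when blocking decisions are made below the root, and the
per-node audit log. Input hit tables should be pre-thresholded to hits
worth trusting — indiscriminate weak hits will glue families together.
The synthetic generator emits no spurious cross-family hits by default
for exactly this reason; its `cross_pair_fraction` exercises the
degradation path.

## Statistics

* **Per-bin over-representation of the disease set vs background:**
  one-tailed hypergeometric survival probability (draws ≥ observed).
* **Overall disease-vs-background shape:** χ² two-sample homogeneity on
  the 2×6 table, no continuity correction, df reduced by bins empty in
  both rows.
* **Class enrichment:** one-tailed 2×2 Fisher, Benjamini–Hochberg within
  each annotation level, adjusted p < 0.05.
* **Class deviation (2×6 Fisher):** exact by full enumeration of
  margin-conditional tables when the total is ≤ 200 and the
  feasible-table bound is ≤ 5×10⁵; otherwise Monte-Carlo conditional on
  margins (default 10⁵ tables, add-one estimator, seed recorded).
  Significant when p < 0.05/m with m = classes tested at that level.
  The null is the all-disease distribution *including* the class (the
  comparison is class vs the complete disease set); an
  `exclude_class_from_null`-style complement is a caller-side variant.
* **Per-bin calls:** two-sided 2×2 Fisher, direction from the proportion
  difference; `significant` at p < 0.05, `significant_strict` at
  p < 0.05/m.
* **Signatures** formalize the three recurring patterns. All require a
  significant under-representation in Filozoa; then: significant
  over-representation only in Vertebrata → *vertebrate-specific*; only
  in Metazoa and/or Parahoxozoa → *early metazoan*; in Vertebrata and at
  least one early-animal bin → *multi-stage metazoan*; anything else →
  *conforming*. A class is given a non-conforming signature only when
  its global 2×6 deviation test is Bonferroni-significant.
* **Selection rates:** the top ortholog per (gene, species) is chosen by
  confidence desc, percent identity desc, dN/dS asc (undefined ratios —
  dS = 0 — last), residual ties by ortholog id. Two-tailed Mann–Whitney
  U: exact tie-aware enumeration when both n ≤ 8, otherwise the normal
  approximation with tie correction and no continuity correction.
  Bonferroni divisor = classes × species (class tests) or pairs ×
  species (stratum tests), recorded in output metadata.
* **Median CIs** are distribution-free order-statistic intervals: the
  smallest symmetric interval `[x_(l), x_(n+1-l)]` with guaranteed
  coverage ≥ the nominal level (binomial computation); at n = 50 and 95%
  this interval's true coverage is 96.7%. For n < 6 no such interval
  exists and the full data range is returned, flagged approximate.
* **Concordance:** exact agreement and agreement within one bin, as
  percentages at one decimal (the package's reporting convention for all
  percentages); distribution similarity uses the χ² two-sample statistic
  divided by its df (bins non-empty in either row, minus one) for every
  ordered cross-method class pair, then a one-tailed Welch t-test that
  same-label pairs have the smaller mean. Both pair counts are computed
  from the data and reported.

## Synthetic data

The generator stands in for a curated disease-gene list plus 23
proteomes, with ground truth exported as JSON. Defaults are the study
conditions:

| parameter | default | meaning |
| --- | --- | --- |
| origin probabilities | 0.52, 0.162, 0.057, 0.057, 0.057, 0.147 | family birth per stratum, basal→recent; the three middle bins split the remainder evenly |
| `loss_prob_per_branch` | 0.05 | independent loss per tree branch below the origin |
| `dup_prob` | 0.01 | chance of a terminal-branch co-ortholog |
| `within_score_mean` / `between_score_mean` / `noise_sd` | 200 / 20 / 5 | chained-score distributions for within- and cross-family pairs |
| `cross_pair_fraction` | 0.0 | fraction of cross-family pairs receiving low-score hits |
| `unmapped_frac` / `unclustered_frac` | 0.087 / 0.032 | focal genes failing protein mapping / clustering, mirroring a 3096→2727 filter |
| planted class | n = 120 of 2000, factor 4 | members drawn with 4× weight on the target origin stratum |
| ratio medians | 0.25 (Vertebrata), 0.10 (others) | lognormal dN/dS medians per origin stratum, σ = 0.6 |
| rate decoys / missingness | 0.3 / 0.05 | confidence-0 decoy candidates; dropped (gene, species) rates |

Families are born exactly at stratum-defining ancestors so planted
labels are unambiguous; families invisible to the focal species are
redrawn (the disease list is by construction observable in the focal
genome, which slightly conditions the realized loss patterns). HSPs are
emitted as 1–3 disjoint colinear segments whose chained score equals the
drawn target; an overlap-injection mode creates admissible (< 5%)
overlaps to exercise the penalty path. E-values decrease monotonically
with bit score.

What the generator does **not** emulate: real sequence evolution (scores
are drawn, not computed from sequences), rate variation across branches
within a family, annotation noise or hierarchical class structure,
paralog interleaving between families, and genuinely ambiguous homology.
Passing tests therefore demonstrate that the algorithms recover planted
structure under the stated noise model, not that the biological
conclusions transfer to any particular real dataset.

## Problem sizes and numerical choices

The shipped configurations are desk-scale: the default pipeline config
synthesizes 300 families (seconds end-to-end), the README example 1500
(about half a minute), and the acceptance script uses 220 families for
clustering recovery and a 2000-gene background for the class and rate
recovery replicates (50 and 40 replicates respectively; 2×6 Monte-Carlo
at 2×10⁴ tables there). The generator itself defaults to 2000 families.
Exact-test tolerances: table probabilities compared with a 10⁻⁷
relative slack when accumulating the Fisher tail; Mann–Whitney exact
ties resolved by midranks with 10⁻⁹ comparison slack. All randomness
flows from explicit seeds; pipeline manifests record seeds, parameters
and row counts, and identical seeds reproduce artifacts byte-for-byte.

## Open design points, resolved

* *Chaining order vs the 5% filter:* chaining is applied per direction
  to the full HSP list with the overlap rule enforced between adjacent
  chain members; pre-filtering overlapping HSPs before chaining would
  discard admissible chains and is not done.
* *Step 1 iteration:* mutual bests are computed once per node
  (simultaneous single pass), not re-evaluated after merges; re-running
  would only add merges that Step 2 performs anyway.
* *Blocking scope:* an outgroup hit blocks only the subtree-side entity.
* *`clustered` as input:* the gene table may carry an explicit
  `clustered` flag (the synthetic generator writes one); when absent the
  pipeline derives it from cluster membership.
* *Far-outgroup control:* the control set is an input gene list, not a
  computation — any independent deep-outgroup homolog call works.

## Known limitations

Final clusters equal hit-graph connected components (see above), so
specificity is inherited from the hit threshold, not the tree. The 2×6
"class vs all-disease" tables are not independent samples (the class is
part of the null), matching the profiling convention rather than strict
test assumptions. Exact p-values from genome-scale backgrounds are not
reproducible without the original background sets and are not attempted.
dN/dS analysis assumes rates are pre-computed per ortholog pair and is
meaningful only at evolutionary distances where dS is unsaturated — for
deeper comparisons only dN would be usable, which the package does not
currently implement.
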