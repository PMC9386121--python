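# Methods

## The analysis in brief

Given two seed proteins, a PPI edge list with confidence scores, an
ontology and a gene→term annotation table, the pipeline asks: are the two
seeds' interaction partners more functionally similar than chance?  The
chain is: threshold the network at an interaction-confidence cutoff →
extract each seed's interactor set → score set-to-set GO semantic
similarity (SSS) → assess significance by resampling → intersect the two
sets → rank shared-neighbourhood hubs as mediator candidates → confirm
candidates by differential expression.

## Ontology substrate and information content

The ontology is a rooted DAG with typed `is_a`/`part_of` edges, one root
per namespace, validated at load (acyclicity, declared parents, no
cross-namespace edges).  Both relation types propagate annotations and
define ancestry by default — this matches the published treatment of the
graph-based similarity measure — and every ancestor/propagation API takes a
`relations` argument for the `is_a`-only alternative.  Obsolete terms are
parsed but excluded from all computation, since real OBO files contain
them.

Information content uses natural logs and normalises by the namespace
root's propagated count rather than the universe size, so IC(root) = 0
holds by construction (the standard Resnik convention).  Terms with zero
propagated count have undefined IC and are excluded from IC-based scoring;
genes whose annotations are all unusable are dropped from a set with a
logged count, and an entirely unusable set is a hard error rather than a
silent zero.

One namespace is used at a time (default BP, biological process).  Which
namespace — or which combination — underlies any particular published
analysis is often unstated; the namespace is therefore a config knob and
no cross-namespace aggregation is attempted.

## Similarity measures and the set score

The four IC-based measures (`resnik`, `lin`, `jiang`, `rel`) score a term
pair through its most informative common ancestor; ties on IC break to the
lexicographically smallest term id so results are order-independent.
Resnik is divided by the corpus' maximum IC so all five measures share the
[0, 1] scale — without this, Resnik sits on a different axis than the
others and set scores are not comparable across measures.  The Jiang
variant used is similarity = 1 − min(1, distance), one of several published
transforms and the one used by the widely deployed R implementation of
these measures.  A consequence worth noting: the relevance measure `rel`
multiplies Lin by (1 − p(MICA)), so even self-similarity is 1 − p(t) < 1;
the identity law sim(t, t) = 1 holds exactly for `lin`, `jiang` and `wang`
only.

The graph-based `wang` measure assigns each term an S-profile over its
ancestor closure — S of the term itself is 1, and each edge discounts by
0.8 (`is_a`) or 0.6 (`part_of`), taking the best path — and scores a pair
by the sum of both profiles over the common closure divided by the sum of
the full profiles.  Disjoint closures (cross-namespace pairs) score 0
rather than raising.

Gene-level and set-level scores both use the best-match average (BMA):
mean of row maxima and column maxima of the similarity matrix.  BMA is the
default combination rule of the standard tooling in this area; `max`,
`avg` and `rcmax` are exposed but not defaults.  Genes shared by both
interactor sets stay in both — no de-overlapping is performed, matching
how such overlaps are reported in practice.

## Monte Carlo significance

The null replaces one or both sets with uniform same-size draws from the
universe of annotated genes (a config switch substitutes the network node
set instead).  The p-value is the fraction of random scores *strictly*
greater than the observed score, so p = 0 is attainable; an add-one
(Phipson–Smyth) correction flag exists but is off by default, keeping the
strict-ratio definition primary.  Random draws exclude neither the seed
proteins nor the observed interactors — no such exclusion is part of the
procedure being modelled.

Three randomization modes exist (A only, B only, both).  Reproducibility
uses one root seed with per-mode substreams derived as
`SeedSequence(seed, spawn_key=(mode_index,))`: the modes are mutually
independent, and each mode's draw sequence is identical whether run alone
or via the all-modes convenience call.  Similarity caches
(`SimilarityEngine`) are shared freely across repetitions and calls; they
hold no random state and cannot affect results, only runtime.

## Network handling and mediator ranking

Edges are kept when their combined confidence score is strictly greater
than the cutoff (defaults 0.9 and 0.95, run as a grid).  The STRING
integer scale (0–999) is auto-detected — any score above 1 triggers
division by 1000 — and a score outside both scales is a hard error.
Duplicate pairs keep the maximum score; self-loops and malformed rows are
skipped with logged line numbers.  Identifiers are treated as already
harmonised; no ID mapping is attempted.

"Hub connecting the shared interactors" is operationalised as
max-anchor-adjacency: anchors default to the second seed protein plus the
common interactors, and every non-anchor node adjacent to at least
`min_links` (default 2) anchors is ranked by distinct-anchor count, ties
broken by id.  The search is global over the network — restricting to a
neighbourhood is a plausible alternative but needs an extra radius
parameter the procedure does not otherwise require.

## Differential expression and enrichment

Mediator candidates are tested gene-by-gene with a Wilcoxon rank-sum
(Mann–Whitney U) test of case vs control expression: exact null
distribution when |x|·|y| ≤ 400 with no ties, otherwise the normal
approximation with tie-corrected variance and continuity correction.  A
completely constant gene returns p = 1 with U at its null mean.  Being
rank-based, the test is agnostic to expression units (counts, TPM, ...),
and values are used as given — no normalisation is applied.  P-values are
reported per dataset without adjustment, and no correction is applied
across the method × cutoff grid either; both choices are deliberate
mirrors of how this analysis is typically reported, and are stated
prominently here for that reason.

Interactor-set enrichment is a plain hypergeometric over-representation
test (upper tail, terms with propagated count ≥ 3) with Benjamini–Hochberg
adjustment across tested terms — the minimal defensible choice where the
enrichment method is otherwise unspecified.

## Synthetic data: what it emulates, what it does not

The generators exist so the whole pipeline runs against known ground
truth.  `generate_dag` grows a single-root DAG by attaching each new term
to 1–2 earlier terms (20% `part_of`); `generate_corpus` gives each gene
1 + Poisson(mean − 1) distinct random terms (default mean 4).
`generate_ppi` plants the full study design: two seeds, interactors drawn
with probability `coherence` from a shared "theme" neighbourhood (the
theme term, its descendants, and terms sharing a parent — a tunable,
interpretable similarity signal), a configurable overlap wired to both
seeds, an optional hub wired to the second seed and all shared
interactors, and background noise edges.  Edge scores are uniform in
(0.9, 1.0] so both cutoffs of the grid bite: each planted edge survives
the strict cutoff with probability ~1/2, which exercises cutoff nesting
but means planted-structure guarantees (overlap size, hub adjacency) hold
only on the loose-cutoff network.  Background edges avoid the seeds, and a
decoy's total anchor adjacency is capped at two, so the planted hub is the
unique maximal mediator by construction.  `generate_expression` is
i.i.d. standard normal with one gene shifted by a chosen effect (default
2σ) in cases.

These generators make no attempt at realistic GO topology statistics,
STRING degree distributions, annotation bias, or count-data noise.
Passing tests therefore demonstrate correctness and calibration of the
*procedure* — exactness on hand-checked fixtures, null uniformity, power
against planted signal, recovery of planted structure — not performance on
real corpora, where annotation depth and network degree are far more
heterogeneous.

## Problem sizes and numerical choices

Simulation-based checks use deliberately scaled-down sizes chosen as
realistic for a desk-scale synthetic study: a 200-term ontology with a
2000-gene corpus for null calibration and power (sets of 10 and 12, 200
trials × 200 repetitions), 100 networks on a 500-gene corpus for mediator
recovery, and n = 10 + 10 samples for expression power.  The standard
synthetic study (200 terms, 300 genes, coherence 0.9, planted hub, 2σ
shift, 200 repetitions) is the fixture for end-to-end runs.  Tolerances:
hand-computed fixture values are asserted to 1e−6; oracle equivalences
(ancestors vs naive DFS, BMA vs the explicit formula, exact Wilcoxon vs
full enumeration) to 1e−12.

All randomness flows through numpy `Generator` objects seeded from
explicit integers; sets are sorted before sampling so draws depend only on
set contents.  Report output is deterministic by construction (sorted JSON
keys, fixed float formats, no timestamps), and a rerun with the same
config and seed is byte-identical.

## Known limitations

- One ontology namespace at a time; no evidence-code filtering, no GO
  release management, no full OBO 1.4 support (intersections, xrefs).
- No STRING API access or evidence-channel decomposition; only the
  combined score is consumed.
- The resampling universe choice (annotated genes vs network nodes) can
  matter on real data where the two differ strongly; both are available
  but only one default could be picked.
- Enrichment and DE results are only as meaningful as the supplied
  expression units and annotation corpus; the package deliberately does
  not normalise or batch-correct.
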