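# Methods

This note documents the models, parameter choices and numerical conventions
behind `dkb`, and what the synthetic-corpus experiments do and do not show.

## Graph model and validation

A knowledge base is `O = (G_s, G_d)`. The schema graph `G_s` carries typed
vertices (classes C, relations R, attributes A, datatypes D) and exactly
four axiom edge labels: `rdfs:domain` (source A/R, target C), `rdfs:range`
(A→D or R→C), `rdfs:subClassOf` (C→C) and `owl:disjointWith` (C→C,
symmetric by closure). The data graph `G_d` carries instances (I) and data
values (V); relation edges connect I→I, attribute edges I→V, and `rdf:type`
links instances to schema classes.

`validate()` reports violations rather than raising, because inconsistent
graphs are the *input* of the fusion stage, not an error condition. Rules:
edge-kind (wrong vertex kinds or unknown property), type-target (unknown
class), domain/range (a typed endpoint carries no class that is a subclass
of the declared constraint — untyped endpoints are not flagged, since a
missing type is an omission, not a contradiction), and disjoint (one
instance typed with two classes whose ancestors are declared disjoint),
reported once per instance and class pair.

The shipped schema has the seven leaf classes of the diabetes domain plus a
structural `Medicine` superclass over the two medicine classes. "Seven
classes" counts leaves; `Medicine` exists only to host the subclass axioms.
All 21 leaf-class pairs are declared disjoint, not just Disease/Symptom:
class membership is single-valued in this domain, and the cleansing
experiments rely on conflicts among non-disease pairs being detectable too.
The ten relation identifiers (`sign`, `complication`, `causes`,
`risk_factor`, `related_disease`, `treated_by_wm`, `treated_by_tcm`,
`checked_by_exam`, `belongs_to_dept`, `located_in_body`) are this package's
naming; all have Disease as domain, which makes the KB disease-centric by
construction.

Instance URIs follow `kb://<source>/<identifier>`, which keeps the portal
source and URL-derived identifier recoverable while remaining a valid IRI
for strict Turtle/N-Triples tooling (several portal names begin with a
digit and cannot serve as URI schemes themselves). Value vertices get the
deterministic id `value:<label>`, shared across sources, so graph unions
deduplicate equal values and serialization round trips preserve the edge
set exactly.

## Extraction

Entry routing is substring containment: an entry's topic sentence (first
line of a list, first row of a table, infobox key) is normalized
(whitespace-collapsed, case-folded) and matched against each property's
heuristic words in a fixed priority order; the first property with a hit
wins. Multi-hit behavior therefore reduces to the priority order, which is
part of the lexicon and total over its keys. Heuristic words must be chosen
to avoid accidental substring collisions across properties (e.g. a word
like "clinic" would swallow "clinical manifestations"); the shipped lexicon
is curated accordingly.

D2R materialization resolves relation objects against the *same portal's*
instance labels (exact normalized match). Unresolved objects become
attribute edges to a fresh value vertex rather than dangling instance
references: a portal that does not cover Examinations can still state that a
disease "is checked by fasting glucose" as a literal, and the information
survives fusion as an attribute. Class-table rows whose declared class
cannot be resolved are quarantined to a rejects list; the graph is still
produced. Table rows are deduplicated on (subject, object), first
occurrence winning.

## Class cleansing

Conflicts are detected per normalized label across sources: a label is
conflicting when the classes asserted by different portals contain a
disjoint pair. Resolution:

1. **Reference lookup** (absolute precedence): an exact normalized match of
   the label (or an alias) in the disease code list fixes the class to
   Disease. Exact matching is deliberate — fuzzy matching against a disease
   list would reclassify symptoms with disease-like names.
2. **Voting**: one vote per source portal per label (a portal that is
   internally inconsistent about a label is first collapsed to its
   majority, then lexicographically smallest, class). The winner is the
   class with the highest support share; ties prefer Disease when it is
   among the tied classes (the reference list having already been
   exhausted), otherwise the lexicographically smallest class —
   deterministic and recorded in the conflict report.

All `rdf:type` edges of the affected instances are rewritten to the winner,
so a second pass finds no conflicts (idempotence). The `strategy` parameter
exposes the two baselines (`lookup-only`, `vote-only`) so strategy
comparisons run the identical code path.

Because disjointness is a per-instance notion and per-portal instances have
distinct URIs, residual cross-source conflicts are audited by fusing
same-label instances (label-identity mappings) and validating the result;
after combined cleansing this count is zero.

## Instance matching and fusion

Features per instance: name set (normalized label plus alias-attribute
values), class set, neighbor-label set (relation neighbors in both
directions plus non-alias attribute values). Candidates are restricted to
pairs sharing a class and a blocking key (class, first character of any
name), keeping the pipeline sub-quadratic. Scores: syntactic = best
`1 − normalized Levenshtein` over the name-set product (edit distances via
edlib); structural = Jaccard of neighbor labels (two empty neighborhoods
count as fully similar). Aggregation is a weighted mean, 0.6 syntactic /
0.4 structural, kept at ≥ 0.85; correspondences are made one-to-one
greedily, best score first, ties broken by URI order. All three constants
are configurable (`MatchConfig`); the defaults were chosen once as
round numbers that favor the more reliable syntactic signal while letting
strong structural agreement rescue aliased labels, and are exercised — not
tuned — by the tests.

Fusion takes the transitive closure of the mapping assertions, picks the
lexicographically smallest member URI as the canonical instance, re-points
all edges and collapses duplicate triples; per-vertex provenance is the
`|`-join of member source tags. A cluster spanning disjoint classes aborts
fusion: that indicates the cleansing contract was breached upstream.

## EM topic extraction

The extraction alternates: **E-step** — induced subgraph on the current
centers and their relation neighbors (induced, not a star: edges among
neighbors are kept); **M-step** — eigenvector centrality on that subgraph,
next centers are vertices with score strictly above `φ_c`. Iteration stops
at center-set equality or `max_iterations` (default 10 — large enough to
observe the plateau, which empirically arrives by iteration 3–4). The final
KB keeps vertices whose last-iteration centrality is at least `φ_d`, with
their attribute and type edges re-attached. `φ_d`'s role as the final
membership cut is this package's interpretation: it is introduced alongside
`φ_c` with the same default (0.01) and the algorithm needs a membership
rule distinct from center selection.

Centrality conventions: instances and relation edges only, undirected,
unweighted, parallel predicates collapsed; attribute/type edges carry no
topological meaning here. Scores are computed per connected component by
power iteration on `A + I` (the shift guarantees convergence on bipartite
components without changing the Perron vector), starting from the uniform
vector, L2-normalized each step, converged when the largest per-component
change drops below 1e-8 (cap 1000 iterations). Each component's score
vector has unit Euclidean norm, so a singleton component trivially scores
1.0 — and a single-vertex graph is its own center. Inside the EM loop,
components of the induced subgraph containing no current center are dropped
before scoring; this is what keeps eigenvector mass from drifting into
off-topic islands, and it is also what zeroes out stray isolated vertices.

Determinism: the uniform start vector, sorted vertex orders and the absence
of random tie perturbation (off by default) make the extraction a pure
function of graph, seeds and config.

## Synthetic corpora

The generator emulates the study setting at desk scale; defaults are the
study conditions.

* **Master KB**: instances per class default to 600 diseases, 300 symptoms,
  80 + 80 medicines, 50 examinations, 24 departments, 66 body structures
  (≈1,200 instances — large enough for stable fusion statistics, small
  enough for second-scale runs). Labels are unique pronounceable syllable
  words; each instance gets one or two aliases by truncation/suffix
  transforms, so string similarity is informative but imperfect.
* **Edges** are directed triples: for every ordered instance pair admitting
  a relation (domain/range compatible), one Bernoulli draw at `p_in` (both
  endpoints in the topic community) or `p_out` (otherwise) decides the
  triple, with the relation drawn uniformly among the admissible ones.
  Realized within-topic density over admissible ordered pairs is binomial
  around `p_in`. Defaults `p_in = 0.2`, `p_out = 0.01`. The topic community
  (default 80 members, disease-weighted 3:1) is patched to be connected —
  a topic community is one by definition.
* **Portal views**: eight portals with a synthetic class-coverage matrix in
  which every portal carries diseases, symptoms, departments and body
  structures, two portals carry no medicines and only some describe
  examinations. Per-portal duplication is 0.25, so an instance lands in ~2
  of the 8 portals on average — real multi-portal crawls sum to roughly
  twice as many instance placements as distinct instances. This low
  multiplicity matters scientifically: it is what makes pure voting
  fallible on low-frequency instances and gives the reference-list lookup
  its role. Labels are
  replaced by an alias at rate 0.2; declared classes flip at rate 0.1, with
  90% of disease/symptom flips being the disease↔symptom swap; detail
  entries re-emit master out-edges under heuristic-word topic sentences
  (30% distractor entries exercise the unmapped path).
* **Reference code list**: a configurable fraction (default 0.6) of the
  true disease labels with their aliases, and nothing else — emulating the
  partial coverage of a standard classification over colloquial portal
  vocabulary.

What the generator does **not** emulate: real lexical variation (Chinese
medical terminology, typos, transliteration), popularity-skewed duplication,
correlated noise between portals, schema drift, and HTML/wrapper errors.
Passing tests therefore demonstrate the pipeline's contracts and its
behavior under the modeled noise, not performance on real crawls.

## Experiment design and measured behavior

* **Cleansing** (`cleansing_experiment`): restored-flip accuracy and
  conflict coverage for lookup-only, vote-only and combined strategies,
  averaged over three replicate corpora (the combined-vs-vote gap comes
  from the handful of majority-corrupted disease labels per corpus, so
  replication stabilizes a small-count effect). Combined > vote-only on
  accuracy; vote-only covers all conflicts while lookup-only covers ~30%.
* **Matching** (`matching_experiment`): F1 against planted duplicate pairs
  with and without cleansing; cleansing strictly helps because flipped
  copies are otherwise blocked by the same-class constraint.
* **EM recovery** (`em_recovery_experiment`): a 150-topic / 850-background
  planted partition generated as an all-Disease population — under the
  disease-centric schema this is the class assignment for which the
  generator's compatibility structure is homogeneous and the graph is a
  textbook planted partition. Measured at the defaults: recall 1.0,
  precision ≈ 0.70, plateau by iteration 4. The precision level is
  intrinsic to the absolute threshold: topic scores sit near
  `1/√150 ≈ 0.08` and the dominant eigenvalue near `p_in·150`, so a
  background vertex with k topic links scores ≈ `k·0.08/(p_in·150)` and the
  0.01 cut admits those with k ≥ 4 (about 7% of the background at
  `p_out = 0.01`); the ratio is invariant to overall densification. Raising
  `φ_d` would trade recall for precision, but 0.01 is the method's standard
  operating point and is kept.
* **Seed robustness** (`seed_robustness_experiment`): extractions from 2,
  3, 6 and 10 seeds coincide (pairwise Jaccard 1.0 on the planted graph) —
  the fixed point does not depend on the seed count once the seeds lie in
  the community.
* **Zero-noise identity** (`zero_noise_experiment`): with all noise rates
  at zero, duplication 1.0, full class coverage and no background edges,
  the full pipeline returns exactly the planted community's closed
  neighborhood (with `p_out = 0` the closure adds nothing, which is what
  makes exact equality a meaningful target).

## Known limitations

* Exact-match reference lookup cannot resolve paraphrased disease names;
  this mirrors the intended role of the code list but caps lookup coverage.
* The matcher is feature-based (no trained or embedding similarity); deeply
  aliased instances with divergent neighborhoods fall below the 0.85
  threshold and stay unmerged.
* Voting trusts source majorities; systematically correlated portal errors
  would defeat it, and the tie-break's Disease preference is a prior, not
  evidence.
* The EM membership cut is an absolute centrality threshold, so the
  precision/recall balance shifts with community size (see above); for
  communities much larger than ~10⁴ vertices the uniform 0.01 cut would
  need rethinking.
* Per-portal identifiers are assumed stable and unique within a portal, as
  the URL-identifier convention guarantees on the emulated sites.
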