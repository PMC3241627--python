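# Methods

## The mining model

`urimine` treats biomarker discovery as a deterministic filter cascade
over gene sets, not as a single fitted model. The object of inference is
a small set of genes that are (a) significantly up-regulated in tumors of
one target tissue, (b) *not* up-regulated in tumors of the other tissues
draining into the same body fluid, (c) annotated with ontology terms
characteristic of proteins found in that fluid, and (d) actually recorded
in a fluid proteome roster. A final graph-theoretic step ranks the
survivors by their structural importance in an interaction network.

Assumptions worth stating explicitly:

* transcript-level up-regulation is taken as a proxy for protein
  abundance in the fluid — a strong assumption, which is exactly why the
  output is a *candidate* list;
* gene identity is by normalized official symbol; no identifier mapping
  is attempted, so inputs from different sources must already share the
  symbol vocabulary;
* expression values are on log2 scale and approximately Gaussian within
  each group, which justifies the Welch t-test and the geometric fold
  change FC = 2^(Δ mean log2).

## Stage-by-stage choices

**Differential expression.** Welch's unequal-variance t-test per gene,
two-sided, with Benjamini–Hochberg step-up FDR across all genes of one
table. BH was chosen over permutation-based FDR because it is
deterministic and exactly testable against a brute-force step-up oracle;
a permutation p-value would make every downstream count seed-dependent.
Degenerate genes (zero variance in both groups, equal means) get p = 1 by
convention; p-values are clamped into (0, 1] so record invariants hold.
The filter keeps genes with q strictly below `fdr_max` (default 0.05) and
fold change ≥ `fc_min` (default 2.0), direction "up" by default. Multiple
datasets for one tissue are filtered independently and pooled by union —
a deliberately permissive choice that favors sensitivity before the
later, stricter filters.

Candidate markers can carry final fold changes below the per-dataset
cut-off: the cut is applied within each dataset, while the reported
per-gene fold change is a cross-dataset summary (`fc_summary`, default
median; mean and max are available). The two numbers answer different
questions and need not agree.

**Tissue exclusivity.** The N-way Venn partition assigns every gene to
the exact subset of tissues whose up-regulated sets contain it; the
"unique" region of the target tissue feeds the next stage. The
implementation is generalized to any N ≥ 2 tissues; region keys are
frozensets, so the partition is invariant under tissue reordering, and
region counts always sum to the size of the union (a tested
conservation law).

**Ontology filter.** Term frequencies over the fluid-proteome roster are
computed *after* true-path propagation (gene annotated to a term ⇒
annotated to all ancestors), so a frequency is "fraction of roster
proteins carrying the term or any descendant". The controlled vocabulary
is chosen by a frequency threshold, default `min_frequency = 0.019` —
the value that keeps exactly the six canonical fluid terms (frequencies
0.348, 0.255, 0.132, 0.113, 0.055, 0.019) when applied to their own
frequency table — or can be given explicitly in the config, which is
what the pipeline does when the vocabulary is already known. Matching is
by term id with label fallback, because fluid-term vocabularies are
often published as labels without stable identifiers.

**Fluid presence.** A plain roster lookup; candidates absent from the
urine roster are dropped, the blood flag is informational. No abundance
modeling — the rosters are presence/absence.

**Network prioritization.** Edge kinds are collapsed for centrality
(the scores are evidence-agnostic) but retained in the graph for
reporting. Betweenness is unnormalized Freeman betweenness over
unordered pairs. Closeness is exposed in two conventions, because the
field uses both: `closeness_farness`, the mean geodesic distance to
reachable vertices (0 for isolated vertices by convention), and
`closeness_standard`, reachable-count over summed distances scaled by
component coverage (the Wasserman–Faust correction). The combined
ranking is betweenness descending, closeness descending, symbol
ascending — the symbol tie-break makes the order total and
reproducible. Gene-set enrichment for seed selection is one-sided
hypergeometric with BH across sets; the universe is the expression
platform's gene set, and every gene set is intersected with the universe
before testing.

## The synthetic-data generator

`SynthConfig` defaults define the study conditions: 500 genes, 3
tissues, 10 tumor + 10 normal samples per tissue, per-gene baseline
N(8, 1) on log2 scale, planted log2 effect 2.0 (4-fold) with N(0, 0.5)
noise, 30 uniquely up-regulated genes per tissue (one third of them
fluid genes) plus 10 up-regulated in every tissue, a 500-protein fluid
roster whose propagated term frequencies hit the six canonical targets
to within 1/roster-size, a blood roster overlapping urine by 0.5, and a
sparse typed graph (noise density 0.05) with one planted hub of degree 5.
The 8 / 1 baseline scale mimics typical normalized two-color/oligo
microarray log intensities; the 4-fold effect at n = 10/group gives the
DE stage high but not saturating power, so recovery is informative.

What the generator deliberately does **not** emulate: probe-level
artifacts, normalization residue, batch or platform effects, correlated
genes, annotation errors in the roster, or realistic scale (real
datasets yield thousands of up-regulated genes, not dozens). Passing
recovery tests therefore demonstrates that the cascade's logic is
correct and its statistics calibrated under idealized conditions — not
that real-data candidate lists will have comparable precision. The
published at-scale counts (tens of thousands of up-regulated genes,
thousands of unique genes) depend on 2011 database snapshots and are
not recomputable from any desk-scale simulation; they are outside the
package's claims.

Two generator parameters (`roster_size`, `blood_overlap`) exist because
the ontology stage cannot be specified without them; both are ordinary
config fields with the defaults above. All generators are pure functions
of (config, seed); identical seeds give byte-identical artifacts.

## Numerical and degenerate-input conventions

* p-values clamped to `[tiny, 1]`; q ≥ p enforced after BH (true for
  step-up anyway; the clip guards floating-point rounding).
* Isolated vertices: farness 0, standard closeness 0, betweenness 0.
* Empty edge lists, empty enrichment inputs and empty candidate sets
  degrade gracefully (empty reports), but empty DE result lists and
  empty rosters are precondition errors — they signal a broken input,
  not an empty answer.
* Parsers reject malformed numerics and unknown edge kinds with row- or
  line-numbered errors rather than coercing.
* Marker-table presence flags accept `1/true/yes/y/x/•`; the bullet is
  the convention used in published marker tables.

## Test-suite problem sizes

Oracle comparisons run on graphs of ≤ 8 vertices (40 random graphs in
the unit suite, 200 in the acceptance suite) where exhaustive
shortest-path enumeration is cheap; the enumeration is pruned to paths
no longer than the BFS shortest distance, which keeps it exact. The
null-FDR check uses 50 replicates of 200 genes; the end-to-end recovery
check uses 50 seeded bundles at the default conditions. These sizes give
the binomial assertions comfortable tolerances while keeping the whole
suite in the seconds range.

## Known limitations

* No moderated-variance (empirical Bayes) testing and no effect-size
  meta-analysis across datasets; with very small sample sizes the plain
  Welch test is underpowered relative to limma-style approaches.
* No statistical test on the exclusivity overlap — uniqueness is a hard
  set operation, sensitive to the cut-offs of the DE stage.
* The ontology filter's published analogue used a clustering-based
  enrichment tool whose exact term grouping is not reproducible; direct
  propagated roster frequency is this package's proxy, and it reproduces
  the *meaning* (fraction of fluid proteins carrying a term), not that
  tool's internals.
* Published closeness scores for the worked-example subnetwork follow a
  convention that cannot be reverse-engineered without the unpublished
  edge set; the package therefore treats them strictly as ranking
  inputs and exposes its own two documented closeness variants for
  graphs it builds itself.
* Weighted, directed, and kind-specific centralities are out of scope.
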