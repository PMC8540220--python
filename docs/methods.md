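# Methods

## Model and procedure

The screen treats each (mutated gene *Q*, screened gene *K*) pair as an
independent two-sample comparison of *K*'s depletion scores between case
cells (≥1 deleterious variant of *Q*) and control cells. The test is a
two-sided two-sample *t*-test; the sign of the case−control mean difference
labels the direction (negative → sensitive, positive → resistant).
*p*-values of all *performed* tests in one screening form a single family
adjusted by Benjamini–Hochberg step-up; the two directions are one family
(direction is a post-hoc sign label, not a separate hypothesis family).
Pairs with adjusted *p* (FDR) strictly below the threshold are reported.

Assumptions: depletion scores are approximately continuous and
exchangeable across cells within a group; tests are treated as independent
for the BH adjustment (BH remains valid under positive dependence);
case/control membership is determined solely by the binary
functional-mutation call.

### Mutation calling

A variant classification is deleterious if it matches one of 12 classes
(de novo start out of frame, frame shift del/ins, in-frame del, nonsense,
nonstop, splice site, start codon del/ins, stop codon del/ins, missense)
after normalizing case and space/underscore/hyphen separators. Unknown
classes count as benign and are logged once per label. A gene is
*recurrently mutated* when its functional-mutation frequency strictly
exceeds θ = 0.03 of the profiled cell universe (a flag switches to ≥, and
the denominator can be restricted to screen-aligned cells). The in-frame
*insertion* class is deliberately absent from the default vocabulary — the
deleterious list names only the deletion — and can be added via override.

### Exclusion procedure

Before testing, a depletion entry (gene, cell) is set to missing when the
expression matrix has a value for the same pair and that value is ≤ ε
(default ε = 0: exact-zero "nonexpressed" semantics; raise ε to tolerate
TPM noise). Genes or cells absent from the expression matrix, and missing
expression entries, never mask anything — absence of evidence leaves the
depletion score in use. Group statistics are computed pairwise-complete
over the remaining values.

### Numerical choices

* **t-variant**: Welch by default — mutant groups are typically an order
  of magnitude smaller than wild-type groups and variance equality is not
  defensible; Student's pooled test is available by config.
* **Minimum group size** m = 3 non-missing values per group after masking;
  smaller pairs are *skipped* and excluded from the BH family size M, so
  degenerate tests do not dilute the adjustment. m = 2 is the floor the
  code accepts; 3 avoids two-point variance instability.
* **Degenerate comparisons**: both groups constant and equal → skipped (no
  information); constant but unequal → t = ±∞, p = 0.
* **BH**: implemented directly (min-over-tail form) because the family
  size M may exceed the number of adjusted values when a caller adjusts a
  subset of a larger family; it is cross-checked against statsmodels in the
  tests.
* **Ties/ordering**: output records are sorted lexicographically by
  (Q, K); all randomness lives in the data, not the pipeline.

### Refining process and SPNs

`refine` keeps SP *s* iff some *other* initial SP of the same mutated gene
lies within distance k (bounded BFS). Design points, each config-selectable:

* **Single pass vs fixed point**: default is one pass against the initial
  SP set — whether *s* survives depends only on the original SP
  configuration. On undirected graphs the within-k relation is symmetric
  and iteration changes nothing; under directed `forward` semantics
  iteration can cascade, so a `fixed_point` flag exposes the iterative
  variant.
* **Direction semantics** on directed (KEGG-style) networks: `either`
  (default — a directed path in either orientation confers proximity;
  partner adjacency is symmetric in spirit), `ignore` (fully undirected
  view, mixed orientations allowed along a path), `forward` (source→target
  paths only).
* **Self-GIs**: a mutated gene that is its own SP participates as an
  ordinary SP node; `exclude_self` drops it from its own SP set. Its mere
  presence as a network *node* never rescues other SPs either way, because
  proximity is only ever tested against the SP set.
* Mutated genes with fewer than two mapped SPs are flagged skipped and
  excluded from the INIT/RP2/RP1 stage tables.

The SPN at distance k contains the retained SPs (annotated with direction
and FDR), the edges between them, and — at k = 2 — connector nodes: non-SP
genes realizing a length-2 path between two retained SPs under the active
direction semantics, together with the realizing edges. For k = 1 the
connector set is empty by construction.

### Evaluation

Predicted sensitive GIs are matched to reference synthetic-lethality pairs
as unordered pairs (the reference relation is symmetric); self-GIs are
excluded from matching since reference sets contain no self-pairs. Recall
uses the full reference set by default; a parameter restricts the
denominator to pairs within a gene universe (e.g. screened genes). Because
the stage tables nest, recall is non-increasing INIT → RP2 → RP1 by
construction (asserted, not assumed); precision has no such guarantee and
is the quantity the refinement is designed to raise.

## Synthetic data generator

`gi_refine.simulate` emulates the five inputs with planted truth. Default
study conditions: 200 cell lines, 500 screened genes, 10 mutated genes at
mutation frequency π = 0.1 (exactly round(π·n) mutant cells per gene, so
the 3% recurrence filter is passed by construction), two planted sensitive
SPs per mutated gene (20 planted GIs among 5000 assessed pairs), Gaussian
depletion noise σ = 0.2 with additive effect size δ = 1.0 in mutant cells
(Student-t noise available for robustness checks), expression ~
clip(N(6, 2), 0.1) with a 5% exact-zero fraction plus designated
always-nonexpressed genes, and a reference set of 80% of the planted
sensitive pairs plus 50 noise pairs.

Network construction: each mutated gene's true SPs form a clique; every
other screened gene is attached to a dedicated dummy neighbor node
(`NBR_<gene>`), which keeps it representable in an edge-list file (an
edge-list TSV cannot carry isolated nodes) while leaving it at infinite
distance from every true SP. Designated decoy SPs are therefore ≥ 3 edges
from all other SPs, and any screen false positive is network-isolated too.
A small background component of random edges adds non-trivial topology.

The confound fixture plants a (Q, K) pair whose depletion shift occurs
exactly in the cells where K's expression is zero: without exclusion the
pair is a strong hit; with exclusion the whole case group is masked and
the pair is skipped — the signature of an expression-artifact false
positive.

What the generator does *not* emulate: DepMap's empirical score
distributions, gene–gene co-essentiality correlation, cancer-type
structure, or realistic network degree distributions. Passing tests
demonstrate the pipeline's contracts and statistical behavior under the
stated model, not performance on real screens.

### A note on "false" GIs under the default conditions

With 10 mutated genes drawn independently over the same 200 cells, mutant
sets overlap (≈2 cells per gene pair). A planted δ-shift for one mutated
gene therefore leaks a genuine mean shift of order δ·overlap/n_case into
other genes' tests, producing real secondary associations beyond the
nominal BH false-discovery load (≈ q·R/(1−q) ≈ 5 at q = 0.2 with ~20
discoveries). Replicated runs consequently show roughly 5–20 non-planted
discoveries per screen alongside perfect recovery of the planted 20; the
network refinement removes the isolated ones, which is precisely the
precision gain the RP exists to deliver.

## Problem sizes used in tests and the acceptance script

Unit and integration tests use a reduced screen (120 cells, 60 genes, 4
mutated genes); the replicated property measurements use the full default
conditions above over 20 seeds, 100 randomized graph/SP instances for the
nesting law, 200 random graphs (≤ 50 nodes) for the distance oracle, and
100 random p-vectors (lengths 1–10⁴) for the BH oracle. These sizes give
stable statistics while keeping the whole suite in the tens of seconds.

## Known limitations

* The BH family is per-screening; joint control across multiple screenings
  (e.g. CRISPR + shRNA) is not attempted.
* The RP is binary on distance; no weighting by path count, edge
  confidence, or degree correction (high-degree hubs make distance-2
  proximity nearly vacuous on dense PPI networks).
* Variant-level functional impact is vocabulary-based only; no
  per-variant effect prediction.
* Cancer-type-stratified screening is out of scope; all cell lines are
  pooled.
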