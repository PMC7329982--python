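# Methods

## CTD descriptors

A physicochemical scale partitions the 20 canonical amino acids into three
disjoint groups; a protein sequence of length N is rewritten as an index
string over {1,2,3}. From that string:

- **Composition**: `C(e) = n_e / N`, reported ×100. The three values sum to
  100 exactly before any rounding (they are rationals with denominator N).
- **Transition**: for each unordered heterogeneous pair {a,b},
  `T(a,b) = (n_ab + n_ba) / (N − 1)`, reported ×100, where n_ab counts
  adjacent occurrences of "ab". Undefined for N = 1 (no adjacent pairs);
  this is an error, not a zero.
- **Distribution**: positions are 1-based and reported as `100·p/N`. Two
  modes: `all_positions` lists every occurrence position of each group
  (strictly increasing; empty for an absent group); `five_point` reduces a
  group with k occurrences to the landmark occurrences
  `max(1, round_half_up(q·k))` for q ∈ {0, 0.25, 0.5, 0.75, 1}, the
  standard first/25/50/75/100% convention. A four-point variant omitting
  the 75% landmark is available via the `quantiles` argument for
  compatibility with sources that list only four landmarks. Absent groups
  yield all-zero landmark vectors.

Reference values for descriptors are conventionally printed with
one-decimal **truncation** (floor), e.g. 2/19 → 10.5%, 1/18 → 5.5%;
`truncate1` implements exactly that and is used only for display and
golden-value comparison. Full float precision is kept internally and in CSV.

### Grouping tables

`core7` holds seven scales (secondary structure, hydrophobicity
PRAM900101, normalized van der Waals volume, solvent accessibility,
polarizability, charge, polarity); `extended13` adds six further
hydrophobicity scales (ARGP820101, ZIMJ680101, PONP930101, CASG920101,
ENGD860101, FASG890101), giving 13 × 3 = 39 composition features. The
partitions are the canonical Tomii & Kanehisa (1996) amino-acid-index
clusters used by standard CTD implementations; published transcriptions of
these tables sometimes contain typos (a residue duplicated across groups
or missing entirely), so every row is validated at load time as a disjoint
cover of the 20-letter alphabet, and custom tables are validated the same
way.

Feature ordering is property-major (`<property>.G1, .G2, .G3`, scales in
table order) and features are addressed **by name** everywhere; positional
attribute indices are not part of any interface, because index-based
addressing is fragile against table reorderings.

### Residues outside the 20-letter alphabet

FASTA input may contain B, J, O, U, X, Z. Since the grouping scales are
defined only for the canonical residues, the default policy drops such
letters; `strict` raises instead, and `map_to_x_then_drop` mirrors
toolchains that first normalize ambiguity codes to X (net residue content
identical to `drop`). A record left empty after sanitization is an error.

### Labels

Internally the positive class is 1 and the negative class 0. Because
published feature tables use conflicting conventions (positives 0 /
negatives −1 in some, 0/1 in others), CSV export accepts
`label_style="zero_minusone"` to emit the 0/−1 coding, and import
auto-detects and maps back to the internal 1/0. The mapping is a bijection,
so export–import round-trips are exact.

## Ensemble feature selection

### Rankers

Seven methods order the features of a labeled matrix (best first). Scores
are nonincreasing along each ordering; ties are broken lexicographically by
feature name so every ranking is deterministic.

- **anova** — one-way F statistic (between-class over within-class mean
  squares). Constant features get F = 0.
- **chi2** — the standard feature-selection chi-square on nonnegative
  values: observed = per-class feature sums, expected from class priors.
  Negative input is rejected.
- **mrmd** — max-relevance-max-distance:
  `score(f) = rescale(|r(f, y)|) + rescale(mean_g ||x_f − x_g||₂)`, both
  terms min-max rescaled to [0,1] across features before summing; a
  zero-variance feature contributes correlation 0 (warned), and a term with
  zero spread across features contributes 0 for all.
- **mic** — maximal information coefficient when `minepy` is importable;
  otherwise a fallback to mutual information on equal-frequency 3-bin
  discretized features. The fallback is flagged in the ranking's `notes`
  field so reports always state which estimator ran.
- **lasso** — L1-regularized logistic regression on standardized features
  at the single operating point C = 1.0 (liblinear); ranking by
  |coefficient|, zero-coefficient ties resolved by univariate F. A fixed
  point rather than a path keeps the ranking deterministic and cheap.
- **mrmr** — greedy minimum-redundancy-maximum-relevance: relevance is
  MI(feature; label), redundancy the mean MI against already-selected
  features, both on equal-frequency 3-bin discretizations. Three bins keep
  the estimator usable at small sample sizes.
- **rfe** — recursive feature elimination, one feature per round, with the
  same random forest as the selection stage (internal consistency).

For the two sequential methods (mrmr, rfe) the reported scores are
descending rank positions (n … 1), because the greedy criterion value is
not monotone along the selection order.

### Rank aggregation

Each ranking contributes, for every consecutive pair (better, worse), one
directed edge *worse → better*; multiplicities accumulate across rankings
(so r rankings over p features give exactly r·(p−1) edge multiplicity).
Consecutive pairs — rather than all dominated pairs — keep the graph
sparse and weight local agreement between rankers; an all-pairs mode was
considered and rejected as it swamps the graph with low-information edges.

PageRank runs as explicit power iteration: damping 0.85, uniform teleport,
out-edge probabilities proportional to edge multiplicities, dangling-node
mass (the unanimous best feature has no out-edges) redistributed
uniformly, L1 convergence tolerance 1e−9, at most 1000 iterations
(non-convergence is an error, not a silent result). These are the
canonical PageRank defaults. The aggregated order is by descending score
with lexicographic tie-break. When all rankers agree, the graph is a chain
and the aggregated order provably reproduces the unanimous order; the test
suite also cross-checks the scores against the networkx implementation as
an independent oracle.

### Incremental prefix selection

For prefix lengths 1 … p of the aggregated order (optionally strided; the
full length is always evaluated), a random forest (100 trees) is evaluated
under stratified 5-fold cross-validation. One global seed drives fold
assignment and forest randomness. Metrics (precision, recall, F1, MCC,
rank-based AUC) are computed from the pooled out-of-fold predictions —
pooling gives one well-defined confusion matrix rather than an average of
five noisy ones. The chosen subset is the **shortest** prefix maximizing
the objective metric (default F1; any of the five can drive selection).
Every prefix is evaluated by default because checkpoint-only evaluation
can miss the optimum between checkpoints.

Metrics edge cases: single-class truth makes MCC/AUC undefined and is an
error; a zero confusion-matrix margin defines the affected metric as 0
with a warning.

## Synthetic data generator

Each class is an i.i.d. residue model: 20 nonnegative weights summing
to 1, sequence lengths uniform on a range (default 100–400 residues,
roughly the span of globular domains). The separable dataset moves
probability mass `bias` from the uniform background onto the hydrophobic
set {M,F,I,L,C,W,V} for positives and onto the polar set {N,Q,D,E,K,R} for
negatives — the two outer groups of the PRAM900101 hydrophobicity scale —
so the injected signal is exactly the kind of compositional difference the
composition descriptor measures, along the axis where class separation is
expected to show. `bias = 0` makes the classes identically distributed
(uniform), a clean null for leakage checks. Default simulation size is 500
sequences per class. Per-class RNG streams are spawned from one seed, so
outputs are byte-reproducible.

What the generator does **not** emulate: positional structure (membrane
topology, domains), homology/redundancy between sequences, realistic
length or composition distributions of any particular protein family.
Passing tests therefore demonstrate that the pipeline recovers
compositional signal and does not manufacture signal from none — not that
it attains any particular accuracy on real receptor data, which would
additionally face homology between splits and far subtler class
differences.

## Problem sizes used in validation

The end-to-end checks run at 500 sequences per class (five seeds at bias
0.3 and one null run at bias 0) with the 39-feature table and the full
seven-ranker ensemble; unit-level properties run on matrices of ~5–40
samples where closed-form oracles are practical. Scaled-down pipeline
variants (80 sequences per class, ranker subsets, 40-tree forests) back
the bias-monotonicity property, chosen so the whole suite stays
interactive to run.

## Known limitations

- CTDC carries no positional or order information beyond what transition/
  distribution add; two sequences with equal group composition are
  indistinguishable to the C block.
- The MIC fallback (discretized MI) is coarser than a true MIC estimate at
  small n; the `notes` flag makes runs auditable.
- mRMR's MI discretization is fixed at 3 equal-frequency bins; heavily
  tied features can collapse to fewer bins.
- The selection stage's random forest is the only classifier offered; the
  engine reports all five metrics but does not tune hyperparameters.
- Redundancy removal between near-duplicate input sequences (clustering at
  a sequence-identity threshold) is out of scope and should be done
  upstream.
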