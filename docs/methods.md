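# Methods

## Model

`taxovote` treats per-read taxonomic classification as an ensemble problem at
the *annotation* level: the unit of input is one taxon ID per read per tool,
never a sequence. The consensus is a weighted vote on a simplified taxonomy
restricted to the root plus the seven standard ranks. For a read with C
nonzero votes, every backbone node is weighted by the number of votes whose
lineage contains it (so weights are monotone non-increasing from root to
leaf and weight(root) = C). The decision is the node that (a) has weight
strictly greater than ⌊C/2⌋ and (b) maximizes the summed weight along its
root-to-node path, with ties at the maximum folded into the LCA of all tied
nodes. The confidence score is A/N for a unanimous decision (A = C) and
A/N − 1/(m·N) otherwise.

Assumptions worth stating explicitly:

* Tools are exchangeable — every vote has the same weight, and column order
  in the votes CSV is semantically irrelevant (tested as a permutation
  invariance).
* Classifier output is per-read and independent across reads; the decision
  for one read never looks at another read.
* Any taxid a tool emits can be mapped onto the backbone: merged IDs are
  remapped first, non-standard ranks (strains, "no rank" clades) are lifted
  to the nearest standard-rank ancestor, and IDs absent from every table
  degrade to an unclassified vote (0) with a logged warning rather than an
  error, so one stale ID cannot kill a run.

## Numerical and tie-breaking choices

* Scores are exact `fractions.Fraction` values internally and are rendered
  to 6 decimal places on output; score comparisons in tests are therefore
  exact, with no float-tie ambiguity.
* The path sum ("root-to-taxon" weight) excludes the root's own weight. The
  root contributes C to every candidate alike, so this cannot change any
  argmax or tie set; a test runs a brute-force referee both ways over an
  exhaustive vote enumeration to confirm decision-invariance. What remains
  is a clean depth-times-support semantics.
* The support threshold is strict (> ⌊C/2⌋). For two disjoint votes this
  forces the consensus up to their LCA; for C = 1 it admits the single
  lineage.
* The root always clears the threshold, so a vote set with no agreement at
  any rank (e.g. votes from different superkingdoms) decides *root*
  (taxon 1) with A = C. Such reads are treated as classified at no standard
  rank: they are excluded from n_c and contribute to no per-rank profile or
  metric.
* The C = 0 sentinel follows the decision scheme literally: taxon 0,
  score 1, A reported as N. The score is deliberately not meaningful as a
  confidence there; consumers filter on taxon = 0.
* LCA tie-folds are order-independent because path sums strictly increase
  along any lineage, so ties only occur between incomparable nodes; this is
  also tested directly by permuting enumeration order.
* m is validated > 1 at construction (the penalized branch is undefined
  otherwise); the CLI rejects `-m 1` as a usage error. Default m = 2 places
  a contested score exactly mid-interval.

## Abundance and evaluation

Counting at a rank is cumulative over clades: a read decided at or below
rank l contributes to its ancestor at l (reads decided above l, at root, or
unclassified contribute nothing). The genomic-based normalization divides
by all reads (n_x/n, default); the marker-based one divides by classified
reads (n_x/n_c), the convention of marker-gene profilers. The two modes
differ exactly by the factor n/n_c on every taxon, which is asserted as an
invariant.

Sensitivity and precision at rank l compare truth and prediction after
truncating both lineages at l. A prediction that stops *above* l is an
abstention — neither TP nor FP — which is what distinguishes a consensus
that retreats to a safe ancestor from a classifier that guesses wrong. A
prediction at l whose read has no truth annotation reaching l counts as FP.
Zero-denominator metrics raise rather than returning 0, so empty-level bugs
cannot hide; the stacked report renders those cells as NA.

The Hellinger distance is computed with square roots of abundances,
H = √(Σ (√P_x − √T_x)²/2), over the union of taxa with missing taxa at 0.
This is the standard form, bounded in [0, 1] for profiles each summing to
at most 1, with H = 0 iff the profiles coincide and H = 1 for disjoint
unit-mass profiles.

## Synthetic data generator

The generator emulates the study conditions the package is designed for:
a complete toy taxonomy (default branching 2,2,2,1,2,3,4 superkingdom →
species, 192 species), reads assigned uniformly to species, and per-tool
votes drawn independently given the true species from a three-part error
model — no call with probability 1 − p_classify, the true species with
probability p_correct_species, otherwise an error drawn from a distribution
over (rank, kind) pairs: "ancestor" emits the true lineage's node at that
rank (an under-resolved but correct call), "sibling" emits a uniformly
random wrong sibling at that rank (a false positive). A sibling draw at a
rank with no siblings falls back to the ancestor call.

The default three-tool panel encodes the qualitative contrast between
classifier families that motivates ensembling:

* similarity-like: p_classify 0.98, p_correct_species 0.80, errors
  70% wrong-sibling species / 10% wrong-sibling genus / 10% genus ancestor
  / 10% family ancestor — calls almost everything, errs as false positives;
* k-mer-like (×2): p_classify 0.80, p_correct_species 0.97, errors
  40% wrong-sibling species / 40% genus ancestor / 20% family ancestor —
  abstains more, errs conservatively.

These rates were fixed from the intended qualitative shape (each tool's
standalone species-level precision and sensitivity) before any ensemble
test was run, and are not tuned. The reference simulation uses 10,000 reads
and a fixed seed; under it the ensemble's species-level precision exceeds
every member tool's and its sensitivity exceeds the member mean, and
raising min-support from 1 to 2 increases precision while costing under
10 sensitivity points.

What the generator does **not** emulate: read length and sequencing-error
covariates (tool errors are i.i.d. given the true taxon, while real
classifier errors correlate across tools on hard reads), log-normal
community structure, marker-database dropout that is clade-structured, and
real taxonomies' rank gaps and inconsistencies beyond what the lifting
logic handles. Passing the simulation tests therefore demonstrates the
correctness and the qualitative precision/sensitivity mechanics of the
consensus, not field performance on real samples.

## Problem sizes in the test suite

The exhaustive oracle check enumerates all vote multisets (including the
unclassified sentinel) over a 23-node fixture taxonomy for N ∈ {2, 3, 5}
— 101,180 cases — and compares the implementation against a deliberately
naive referee that recomputes every node weight from scratch; the same
enumeration drives the score-law checks. The ensemble-behaviour tests use
10,000 reads with the default tool panel and fixed seeds. These sizes keep
the whole suite in the tens of seconds while leaving the enumeration
exhaustive rather than sampled.

## Known limitations

* Per-tool weighting is out of scope: all tools vote with weight 1.
* Marker-gene clade-ID output (clade numbers rather than taxonomy IDs)
  is not convertible without the upstream tool's lookup table; the adapter
  stub raises with that explanation.
* The `-n/--threads` flag is accepted for interface compatibility but is a
  no-op; per-read decisions are independent, so the contract is
  result-invariance, not parallel speedup.
* Evaluation requires every decided read to appear in the truth table;
  truth reads never decided are ignored rather than counted as misses.
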