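# Methods

## Problem setting

Identifying TATA-binding proteins from sequence is a narrow-positive-class
problem: a few hundred curated positives against a negative universe of every
other protein. The toolkit treats it as binary classification on fixed-length
fingerprints, with three method-specific ingredients: a redundancy-aware
feature ranking (MRMD), an explicit search for the accuracy-optimal number of
ranked features, and dedicated strategies for assembling the negative
training set.

## The 188D primary-sequence fingerprint

The fingerprint concatenates amino-acid composition (20 values) with a
composition/transition/distribution (CTD) block per physicochemical property
(8 × 21 values). For a property partitioning the residues into groups
(g1, g2, g3):

* `C_i` — percentage of residues in group i (3 values, sum 100);
* `T_ij` — percentage of adjacent pairs crossing groups i and j, denominator
  L − 1 (3 values); sequences of length 1 are rejected rather than
  special-cased;
* `D_ij` — the normalized 1-based position of the `P_j`-th group-i residue,
  for `P_0 = 1` and `P_j = ⌊N·j/4⌋` (j = 1..4, N = group occurrence count),
  clamped to a minimum of 1 (5 values per group). The clamp covers
  `⌊N·j/4⌋ = 0` when N < 4/j, falling back to the first occurrence, which
  keeps `D` non-decreasing in j. A group with no occurrences contributes five
  zeros, keeping every feature on the same [0, 100] scale.

Only the hydrophobicity partition (neutral `GASTPHY`, polar `RKEDQN`,
hydrophobic `CVLIMFW`) is intrinsic to the 188D definition. The other seven
partitions follow the standard CTD descriptor tables (the Dubchak-lineage
partitions as tabulated in PROFEAT); they ship in
`src/pretata/data/ctd_groupings.cfg`, a versioned plain-text file that can be
replaced via `load_groupings(path)` or the CLI `--groupings` flag, because
different CTD implementations in the literature differ in these tables.

## The 473D secondary-structure feature set

The predicted three-state string (H/E/C) is summarized by six descriptor
families chosen to capture global composition, local word usage, positional
layout, and run-length structure:

| block | dims | content |
|---|---|---|
| k-mers, k = 1..5 | 363 | word frequency per cent of windows |
| CTD over {H,E,C} | 21 | states act as the three groups |
| positional bins | 24 | state composition in 8 equal position bins |
| segment stats | 9 | per state: count/L, mean len/L, max len/L (×100) |
| length histograms | 54 | per state: segment lengths 1..17, ≥18 (% of segments) |
| longest runs | 2 | longest H and E run / L × 100 |

Residue r (1-based) maps to positional bin ⌈8r/L⌉. Segment mean/max lengths
are normalized by L so every feature lives on [0, 100]. Strings shorter than
the largest k-mer (5) are rejected unless the scheme is built with
`lenient=True`, which zero-fills the affected k-mer blocks. The scheme object
is parameterizable (k-mer sizes, bin count, histogram cap); the default
preset totals exactly 473 and is the one the 661D joint vector assumes.

## MRMD ranking

`score_j = w_r · |pearson(x_j, y)| + w_d · dist_j` with default weights
(1, 1). Zero-variance features get relevance 0 rather than NaN. Distances
are computed after per-column min-max scaling to [0, 1] (zero-range columns
map to the constant 0.5), and Euclidean distances are divided by √n_rows;
both terms then live in [0, 1], which is what makes a unit-weight sum
meaningful. Cosine and Tanimoto distances are available alternatives.
Ties break toward the lower original column index, so the ranking is a
deterministic function of the table.

## Two-step dimensionality search

Cross-validated SN/SP/ACC are computed on top-`d` ranked prefixes. The coarse
pass evaluates `d = initial, initial − 20, …` down to a tolerable floor; the
fine pass scans `coarse_best ± 50` (clipped to the valid range) in steps
of 2. The fine grid always includes the coarse optimum, so the combined best
accuracy can never fall below the coarse best. Ties on accuracy prefer the
smaller dimensionality. Folds are stratified and seeded; with a fixed seed
the whole search is bit-reproducible. The window half-width of 50 reproduces
a fine window of width ~100 around the coarse optimum and is configurable.

## Classifier and metrics

RBF-kernel SVM with `C = 128`, `gamma = 0.5` (the grid-optimized defaults of
the original TBP study; `grid_search` re-runs the optimization, ties toward
smaller C then smaller gamma). Decisions come from the signed margin;
probability calibration is disabled so support-vector semantics stay exact
for the sampling strategies. Features are min-max scaled with statistics
from the training split only; cross-validation refits the scaler inside
every fold, and the test suite demonstrates that an intentionally leaked
(globally fitted) scaler changes the CV confusion counts.

SP is computed as TN/(TN+FP), the standard specificity. Some descriptions of
this method print SP = TP/(TN+FP); that variant is available as
`compute_metrics(..., sp_formula="printed")` but is not the default, since
only the standard form is interpretable as a per-class rate on a balanced
design. Zero-denominator metrics are reported as NaN ("undefined"), never
coerced to 0.

## Negative-set construction

* **Random undersampling** — the baseline the other strategies are judged
  against.
* **Iterative hard-negative refinement** — each round trains on positives +
  current negatives, predicts the held-out pool, and swaps pool negatives
  predicted positive into the set (replacing uniformly chosen incumbents,
  at most `n_negatives/2` per round to prevent oscillation — the per-round
  swap count is not fixed by the method's description and is configurable).
  The swap is applied, then the loop stops if 10-fold CV accuracy failed to
  improve by more than `improvement_tol` (default 0), at `max_rounds`, or
  when nothing is misclassified (in which case the initial draw is returned
  unchanged). On a well-spread pool the procedure is a fixed point, matching
  the empirical finding that refinement does not beat random sampling when
  the negatives are already diverse.
* **Support-vector plus set** — union (deduplicated by row id) of
  negative-class support vectors over repeated random draws.
* **Distance retention** — keeps the `retain_fraction` (default 20%) of
  current negatives farthest from a reference point and refills from the
  pool without replacement until the pool cannot supply a full refill. The
  reference point is the positive-class centroid; the method description
  leaves the reference unspecified, so it is a documented, configurable
  choice.

## Synthetic data

`generate_sequences` emulates the statistical shape of the real task, not
TBP biology. All sequences draw residue frequencies from a shared 5-component
Dirichlet mixture (standing in for a pool spanning many protein families);
positives are additionally tilted — `0.6 × signal_strength` of their
frequency mass moved onto the neutral-hydrophobicity group — and their
secondary-structure strings (first-order Markov chains) get helix-richer
transition probabilities. At `signal_strength = 0` the two classes are
drawn from the identical law, so any downstream accuracy above chance is a
bug; the acceptance suite checks the mean 10-fold CV accuracy over 20 seeds
stays within 50 ± 5%. Lengths are uniform on [50, 120] by default.

What the generator does **not** emulate: real amino-acid covariation,
domain architecture, homology between train and test records, or predictor
noise in the secondary-structure strings. Passing tests therefore establish
the pipeline's correctness and calibration, not its accuracy on real
proteins.

`generate_feature_table` produces Gaussian tables (informative columns =
label × effect + unit noise) with a serialized ground-truth mask;
`generate_hard_negative_pool` plants "boundary" negatives by moving a subset
of the negative cloud most of the way toward the positive centroid, so that
a model trained on a random draw misclassifies them.

## Problem sizes and numerical choices

The test and acceptance benchmarks use 200+200 sequences (strong signal),
100+100 × 20 seeds (null calibration), 400-row/60-feature tables (search
coherence), 100 positives vs a 400-row pool with 30 planted boundary rows
(enrichment), and 50 seeds of 100-row tables (feature recovery) — sizes at
which every statistic of interest is stable while the full suite runs in
well under a minute. Feature tables round-trip through CSV/TSV/ARFF at 12
significant digits. All randomness flows through `numpy.random.default_rng`
seeded per call; nothing uses global random state.

An observation worth knowing: with all 661 features and the default
`gamma = 0.5`, scaled pairwise distances are large enough that the RBF
kernel matrix is nearly diagonal and accuracy drops sharply — the
high-dimensional regime the dimensionality search exists to escape. This is
expected behaviour, not a defect; the searched low-dimensional prefixes
restore clean kernel geometry.

## Known limitations

* The eight-property grouping tables and the 473-feature composition are
  pinned, documented choices; other implementations of the same descriptor
  families may differ feature-by-feature while agreeing in total dimension.
* PSIPRED is parsed, never run; garbage predictions in, garbage features out.
* Non-standard residues (B, J, O, U, X, Z) are rejected by default and can
  only be dropped record-wise (`--sanitize`), not imputed.
* The CV harness accepts only the built-in SVM contract
  (`fit`/`decision_function`); plugging in other classifier families is
  possible at the library level but has no CLI surface.
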