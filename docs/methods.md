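# Methods

## Model

The classifier assumes that the sequences of one class (amyloidogenic
peptides) share a *position-specific pair pattern*: inside some window of
fixed length `n`, particular residues tend to co-occur at particular
relative positions — e.g. glutamine at window position 1 entails
asparagine at position 3. The pattern is assumed to live in a single
contiguous segment per positive sequence, at an unknown offset; the rest
of the sequence is treated as background. Negative sequences are assumed
to carry no special segment, so all of their windows are treated as
exchangeable background.

All quantities are built from co-occurrence matrices indexed by
`(p, q, a, b)` with `1 ≤ p < q ≤ n` and residues `a, b` in the standard
20-letter alphabet (encoded 1..20 alphabetically, A=1 … Y=20). Only the
upper triangle `p < q` is stored; the `(q, p, b, a)` mirror is redundant.
Each length-`n` window contributes one count to each of its `C(n,2)`
cells, so an un-normalized matrix built from `W` windows has total mass
`W·C(n,2)` and every `(p, q)` plane sums to `W`. Normalization divides by
`W·C(n,2)` so the whole matrix sums to 1; a per-plane normalization would
be an equivalent global rescaling and is not used.

## Distance between classes

The separation between the positive matrix `Y` and the negative matrix
`N` (both normalized) is

    w = Σ_{cells c with Y(c) > 0}  Y(c) / (N(c) + ε)

The pseudo-mass `ε` (default `1e-6`, configurable) keeps cells that are
empty in the negative matrix finite; it is far below the smallest
occupied-cell frequency in any realistic training set, so occupied cells
are essentially undisturbed. Restricting the sum to positive-support
cells is presentational: zero-numerator cells contribute zero either way.
The alternative reading of "sum of one matrix divided by the other" — a
ratio of the two total masses — is identically 1 for normalized matrices
and cannot discriminate, so the element-wise reading is the only sensible
one.

A consequence worth stating explicitly: `w` is *linear* in `Y`. The
greedy per-sequence window selection below therefore decouples across
positive sequences (each sequence's best window maximizes the sum of
`1/(N + ε)` over its own pairs, regardless of the other selections), and
the iteration reaches its fixpoint after one improving sweep plus one
confirming sweep. The generic coordinate-ascent formulation is kept
because it is the natural home for any future non-linear distance, and
because its invariants (monotone `w`, fixpoint idempotence) are what the
tests assert.

## Training procedure

1. **Negative matrix.** All sliding windows (stride 1) of all negative
   sequences, counted and normalized. Sequences shorter than `n` are
   skipped with a warning.
2. **Initialization.** The positive selection starts with *all* windows
   of every positive sequence contributing — the same averaging used for
   negatives. This is deterministic, seed-free and unbiased toward any
   offset.
3. **Sweeps.** Sequences are revisited in input order; for each, every
   candidate window is substituted into the current selection, the
   normalized positive matrix rebuilt, and `w` evaluated; the maximizing
   window is committed immediately (sequential greedy coordinate ascent).
   Ties are broken toward the smallest start, making results independent
   of floating-point ordering accidents.
4. **Convergence.** Sweeps stop at a selection-map fixpoint, or after
   `max_iterations` (default 100) with a logged warning, or — if
   `min_improvement > 0` — when a sweep improves `w` by no more than that
   tolerance. `w` is recorded per sweep (`w_trace`, non-decreasing);
   `w_d` is its maximum, which by monotonicity is also the final value.
5. **Output.** `MatrixYES` contains exactly one window per contributing
   positive sequence. Positive sequences shorter than `n` cannot
   contribute and are skipped with a warning rather than aborting (mixed
   4–10-residue datasets contain such fragments when `n = 5`).

## Classification

"The positive matrix of a test sequence" is interpreted per window: a
single window's co-occurrence matrix has exactly one count in each of its
`C(n,2)` cells, so its distance to `MatrixNO` reduces to the sum of
ratio-matrix lookups at the window's own residue pairs. The score is
reported as `w_s = raw / w_d`, so well-matching windows score near (or
above — the ratio is not capped) the best training windows, and the
decision threshold `w_l` is a dimensionless fraction in `[0, 1]`. The
call rule is strict (`w_s > w_l`); ties at the threshold are negative.
Per-residue annotation marks a residue `1` iff it lies inside at least
one above-threshold window, which yields contiguous hot-spot blocks on
full-length proteins. Window scores are reported at the window's 1-based
start.

Pattern extraction rescales the ratio matrix by its maximum before
applying the cut-off (default 0.4): a cut-off on raw ratios would depend
on `ε` and on training-set size, whereas the rescaled value is a
dimensionless rank in `[0, 1]`.

## Parameters

| parameter        | default | meaning |
|------------------|---------|---------|
| `window_length`  | 5       | window `n`, the minimal segment assumed to carry the pattern; 4–10 is the sensible range for hot-spot work, 5 or 6 typical. With 6-residue training fragments and `n = 6` the selection stage is vacuous (one window per peptide). |
| `epsilon`        | 1e-6    | denominator pseudo-mass; must be ≪ 1/(windows·C(n,2)) to leave occupied cells undisturbed, and > 0 to keep empty cells finite. |
| `max_iterations` | 100     | sweep cap; the fixpoint is normally reached in 2 sweeps (see linearity note). |
| `w_l`            | 0.14    | decision threshold as a fraction of `w_d`; choose by the Sn/Sp trade-off wanted, e.g. from a cross-validated ROC. |
| pattern cut-off  | 0.4     | max-rescaled ratio threshold for the pair listing. |

## Evaluation choices

- ROC curves sweep the threshold over the observed score values plus
  sentinels at ±∞, giving the exact step curve; AUC is the trapezoidal
  integral of Sn against 1−Sp and equals the tie-corrected Mann–Whitney
  pairwise concordance (asserted against an independent pair-counting
  oracle and scikit-learn in the tests).
- Repeated cross-validation runs `repeats × folds` independent trials
  (default 10 × 4 = 40). Folds are stratified to preserve the
  positive:negative ratio — unstratified 4-fold splitting of a
  roughly 1:2 dataset risks degenerate folds. Fold assignment comes from
  a seeded generator; results are bit-for-bit reproducible given
  (dataset order, seed).
- Mean ROC curves average Sn at 101 fixed 1−Sp grid points with linear
  interpolation (vertical averaging). The "diagonal" operating point of a
  sweep is the point minimizing |Sn − Sp|; per-trial balanced accuracy
  (Sn+Sp)/2 at that point is summarized by its median and 0.85/0.95
  quantiles.
- `cross_test` fits on one labeled set and sweeps the ROC on another;
  the `swap_labels` option inverts the test labels to probe whether the
  *negative* class carries its own discriminative pattern (for the same
  score ordering the swapped AUC is exactly 1 − AUC).

## Synthetic data generator

The generator emulates the structure the classifier is designed to
detect. A motif is a list of `(p, q, a, b, probability)` tuples inside a
window of length `n`; the default motif plants Q–N, N–Q and N–Y pairs at
offsets (1,3), (2,4) and (3,5), which at full strength realizes the
Q/N-rich pentapeptide QNNQY — a caricature of prion-like hot spots.
Positives receive the motif at a uniformly random admissible offset, each
pair realized independently with its probability; negatives are
background only.

Background residues for *both* classes are drawn i.i.d. uniformly over
the 20 letters, rejection-sampled so that no pair induced by the full
motif assignment occurs at its relative spacing anywhere in the sequence
("pattern-free" background). This makes the planted window the *only*
systematic difference between the classes: at probability 1 every induced
pair is absent from all negatives (so the planted offset is exactly
recoverable), and at probability 0 the two classes are statistically
identical (so any downstream AUC must sit at chance). Ground-truth
planted offsets are returned with the records and can be written as a
sidecar TSV.

What the generator does **not** emulate: the compositional biases of real
amyloid datasets (Q/N- and hydrophobic-residue enrichment throughout the
sequence, not just in the hot spot), length heterogeneity of experimental
fragment collections, correlated backgrounds, label noise, and homology
between fragments. Passing the planted-motif checks therefore shows the
machinery is correct — selection, matrices, scoring, CV plumbing — not
that any particular real dataset is separable.

## Numerical and degenerate-input choices

- Dense float64 storage; the index space is ≤ `C(10,2)·400 = 18,000`
  cells, so sparsity is unnecessary.
- Deterministic throughout: training has no random element; all
  evaluation randomness flows from one integer seed.
- Degenerate inputs are rejected with informative errors: empty matrices,
  zero usable windows, folds without both classes, ROC without both
  labels, cut-offs outside `[0, 1]`. Sequences shorter than the window
  are skipped (training) or called negative with an all-zero annotation
  (classification), each with a warning.
- Non-standard residues (B, J, O, U, X, Z) are rejected by default,
  naming the offending position; a permissive mode masks them and drops
  the windows that touch them, which real-world FASTA scanning needs.

## Known limitations

- The selection stage cannot represent more than one pattern window per
  positive sequence, and the linear distance means "closeness to other
  positives" exerts no force on the selection — only distinctiveness
  from the negatives does.
- Scores are not calibrated probabilities; `w_s` is comparable across
  sequences under one model but not across models.
- Pattern listings and scores depend on `ε` wherever the negative matrix
  has empty cells; with small negative sets many cells are empty and the
  ratio matrix is dominated by them. Larger negative sets (hundreds of
  windows per position-pair plane) stabilize the estimates.
- The merged experimental fragment collections this method is typically
  applied to are not redistributed here; the cross-validation and
  cross-test protocols accept any user-supplied CSV of labeled fragments
  (`tests/test_acceptance.py` documents the expected layout and runs a
  full-scale check when such a file is placed under `data/external/`).
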