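# amypair

Amyloid hot-spot prediction from position-specific amino-acid **pair
co-occurrence** patterns.

Short peptide segments (4–10 residues, "hot spots") can confer
amyloidogenicity on a whole protein. `amypair` implements a discriminative
sequence classifier for such segments built on a simple, interpretable
statistic: how often residue *a* at window position *p* co-occurs with
residue *b* at window position *q*, counted over a sliding window of
length *n*.

## The method

Training uses labeled peptide fragments:

- **Negative matrix.** Every sliding window of every negative peptide
  contributes equally to a normalized co-occurrence matrix
  `MatrixNO(p, q, a, b)` for all position pairs `1 ≤ p < q ≤ n`; any
  accidental pattern in the negatives is averaged out by the shifting
  window.
- **Positive matrix by window selection.** Each positive peptide is
  assumed to contain *one* pattern-carrying window at an unknown offset.
  An iterative greedy procedure selects, per positive sequence, the window
  whose inclusion maximizes the distance

  `w = Σ_cells MatrixYES / (MatrixNO + ε)`

  between the normalized positive matrix and the negative matrix
  (ε is a small pseudo-mass keeping empty negative cells finite). The
  maximal distance reached, `w_d`, is stored with the model.
- **Classification.** A test window is scored by summing the ratio-matrix
  entries addressed by its own `C(n,2)` residue pairs, expressed as a
  fraction `w_s = raw / w_d`. A sequence is called positive when its best
  window satisfies `w_s > w_l` for a user threshold `w_l ∈ [0, 1]`
  (default 0.14); residues covered by at least one positive window are
  annotated `1`, giving per-residue hot-spot maps for full proteins.
- **Evaluation.** Sensitivity `Sn = TP/(TP+FN)`, specificity
  `Sp = TN/(TN+FP)`, exact step ROC curves with trapezoidal AUC, repeated
  stratified k-fold cross-validation, and train-on-one / test-on-another
  protocols including a label-swap probe for biased negative sets.

The learned pattern itself is inspectable: `extract_pattern` lists the
co-localized residue pairs whose max-rescaled ratio exceeds a cut-off
(0.4 by convention).

## Worked example

```python
import amypair as ap

# synthetic study conditions: 100 positives of length 10 carrying a
# planted pentapeptide (QNNQY) at a random offset, 200 pattern-free
# negatives
spec = ap.SyntheticSpec(n_pos=100, n_neg=200, seed=42)
records, planted = ap.generate_synthetic(spec)
seqs = ap.to_labeled_sequences(records)

results = ap.PairCooccurrenceModel(
    [s for s in seqs if s.label == "positive"],
    [s for s in seqs if s.label == "negative"],
    window_length=5,
).fit()
print(results.summary())
```

```
Pair co-occurrence hot-spot classifier
==============================================
window length n          5
position pairs C(n,2)    10
epsilon                  1e-06
positive sequences       100
negative sequences       200
negative windows         1200
selection sweeps         2
maximal distance w_d     1e+06
final training w         1e+06
==============================================
```

The fit selects one window per positive sequence (here it recovers every
planted offset: compare `results.selection` with `planted`), and the
learned pattern is exactly the planted pair structure:

```python
print(results.pattern_frame(cutoff=0.4).head(3))
#    p  q aa_p aa_q  value
# 0  1  2    Q    N    1.0
# 1  1  3    Q    N    1.0
# 2  1  4    Q    Q    1.0

query = ap.LabeledSequence.from_string("query", "ACDEFGHQNNQYACDEFGH")
pred = results.predict([query], w_l=0.14)[0]
print(pred.label, round(pred.max_ws, 3), pred.residue_annotation)
# positive 1.0 0000000111110000000
```

The annotation marks residues 8–12 — the embedded QNNQY — as the
predicted hot spot.

The package also ships the published sup35 prion fragment test table
(12 amyloidogenic and 31 non-amyloidogenic 10-mers with their `w_s`
scores); re-counting it at a decision threshold of 0.125 gives

```python
recs, scores, calls = ap.sup35_fixture()
c = ap.confusion([r.label for r in recs], [scores[r.id] > 0.125 for r in recs])
print(f"Sn = {c.sn:.2f}, Sp = {c.sp:.2f}")
# Sn = 0.75, Sp = 0.90
```

## Command line

```bash
amypair train --positive fragments.csv -o model.json
amypair predict model.json protein.fasta --w-l 0.14 -o predictions.tsv
amypair evaluate fragments.csv --folds 4 --repeats 10 -o cv.json
amypair cross-test trainset.csv testset.csv --swap-labels -o roc.tsv
amypair pattern model.json --cutoff 0.4
amypair export-matrix model.json --which ratio
```

Labeled datasets are CSV files with columns `id,sequence,label`
(labels `1/0`, `pos/neg`, `amyloid/non-amyloid`, `+/-` all accepted);
full proteins are standard FASTA.

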