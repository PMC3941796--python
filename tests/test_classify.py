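import itertools
from math import comb

import numpy as np
import pytest

import amypair as ap
from amypair.cooccur import RatioMatrix, position_pairs

from conftest import random_sequences, seqs_from_strings


def make_model(ratio_values, w_d, n=5, epsilon=1e-6):
    """Assemble a TrainedModel around a handcrafted ratio matrix."""
    placeholder = ap.normalize(ap.build_comatrix(
        ap.extract_windows(seqs_from_strings(["A" * n])[0], n), n))
    return ap.TrainedModel(
        config=ap.TrainingConfig(window_length=n, epsilon=epsilon),
        matrix_no=placeholder,
        matrix_yes=placeholder,
        ratio=RatioMatrix(window_length=n, values=ratio_values,
                          epsilon=epsilon, w=float(ratio_values.sum())),
        w_d=w_d, n_yes=1, n_no=1, iterations_run=1,
    )


def loop_score(codes, model):
    """Exhaustive pair-loop oracle for a window's raw score."""
    n = model.config.window_length
    pairs = position_pairs(n)
    total = 0.0
    for p, q in itertools.combinations(range(1, n + 1), 2):
        k = pairs.index((p, q))
        total += model.ratio.values[k, codes[p - 1] - 1, codes[q - 1] - 1]
    return total


def test_uniform_ratio_scores_cn2_v():
    model = make_model(np.full((10, 20, 20), 0.7), w_d=7.0)
    s = ap.score_window(ap.encode_sequence("QNYAK"), model)
    assert s.raw_score == pytest.approx(comb(5, 2) * 0.7)
    assert s.ws == pytest.approx(1.0)


def test_single_cell_ratio_lookup():
    values = np.zeros((10, 20, 20))
    values[0, ap.AA_TO_CODE["Q"] - 1, ap.AA_TO_CODE["Q"] - 1] = 3.0  # (1,2,Q,Q)
    model = make_model(values, w_d=30.0)
    s = ap.score_window(ap.encode_sequence("QQNYQ"), model)
    assert s.raw_score == pytest.approx(3.0)
    assert s.ws == pytest.approx(0.1)
    with pytest.raises(ValueError):
        ap.score_window(ap.encode_sequence("QQNY"), model)


def test_score_window_matches_loop_oracle(random_model):
    rng = np.random.default_rng(5)
    for _ in range(50):
        codes = rng.integers(1, 21, size=5)
        s = ap.score_window(codes, random_model)
        assert s.raw_score == pytest.approx(loop_score(codes, random_model))
        assert s.ws == pytest.approx(s.raw_score / random_model.w_d)


def test_threshold_extremes(random_model):
    seq = random_sequences(np.random.default_rng(2), 1, 12)[0]
    pred0 = ap.classify_sequence(seq, random_model, 0.0)
    assert pred0.max_ws > 0 and pred0.label == "positive"
    high = ap.classify_sequence(seq, random_model, pred0.max_ws * 1.01)
    assert high.label == "negative"
    assert set(high.residue_annotation) == {"0"}
    # ties at the threshold are negative (strict inequality)
    tie = ap.classify_sequence(seq, random_model, pred0.max_ws)
    assert tie.label == "negative"


def test_annotation_window_geometry(random_model):
    """Length n+1 with exactly one above-threshold window: n ones, one zero."""
    rng = np.random.default_rng(8)
    for _ in range(200):
        seq = random_sequences(rng, 1, 6)[0]
        pred = ap.classify_sequence(seq, random_model, 0.0)
        s1, s2 = pred.scores[0].ws, pred.scores[1].ws
        if s1 == s2:
            continue
        w_l = (min(s1, s2) + max(s1, s2)) / 2
        pred = ap.classify_sequence(seq, random_model, w_l)
        assert pred.residue_annotation.count("1") == 5
        expected = "111110" if s1 > s2 else "011111"
        assert pred.residue_annotation == expected
        break
    else:
        pytest.fail("no tie-free pair of windows found")


def test_monotone_in_threshold(random_model):
    seqs = random_sequences(np.random.default_rng(3), 10, 15)
    for seq in seqs:
        prev_pos = None
        prev_ann = None
        for w_l in np.linspace(0, 1.2, 13):
            pred = ap.classify_sequence(seq, random_model, float(w_l))
            annotated = {i for i, c in enumerate(pred.residue_annotation)
                         if c == "1"}
            if prev_ann is not None:
                assert annotated <= prev_ann
                assert not (prev_pos == "negative" and pred.label == "positive")
            prev_ann, prev_pos = annotated, pred.label


def test_translation_covariance(random_model):
    rng = np.random.default_rng(9)
    base = random_sequences(rng, 1, 10)[0]
    k = 4
    prefix = rng.integers(1, 21, size=k)
    shifted = ap.LabeledSequence(id="shift",
                                 residues=np.concatenate([prefix, base.residues]))
    p0 = ap.classify_sequence(base, random_model, 0.1)
    p1 = ap.classify_sequence(shifted, random_model, 0.1)
    scores0 = {s.start: s.ws for s in p0.scores}
    scores1 = {s.start: s.ws for s in p1.scores}
    for start, ws in scores0.items():
        assert scores1[start + k] == pytest.approx(ws)
    # residues annotated through pre-existing windows stay annotated at +k
    for i, c in enumerate(p0.residue_annotation):
        if c == "1":
            assert p1.residue_annotation[i + k] == "1"


def test_short_sequence_negative_with_warning(random_model, caplog):
    seq = seqs_from_strings(["ACD"])[0]
    with caplog.at_level("WARNING"):
        pred = ap.classify_sequence(seq, random_model, 0.1)
    assert pred.label == "negative" and pred.scores == []
    assert pred.residue_annotation == "000"
    assert "shorter than window" in caplog.text


def test_training_positives_recovered(planted_model):
    """With w_l just below their own max_ws, all training positives are
    called positive again."""
    results, _, _ = planted_model
    pos = results.model.positives
    scores = results.score(pos)
    w_l = scores.min() * 0.999
    preds = results.predict(pos, w_l=w_l)
    assert all(p.label == "positive" for p in preds)


def test_extract_pattern_cutoffs():
    values = np.zeros((10, 20, 20))
    values[0, 0, 1] = 10.0   # (1,2,A,C) -> rescaled 1.0
    values[3, 2, 3] = 5.0    # (1,5,D,E) -> 0.5
    values[9, 4, 5] = 2.0    # (4,5,F,G) -> 0.2
    model = make_model(values, w_d=1.0)
    got = ap.extract_pattern(model, 0.4)
    assert [(c.p, c.q, c.a, c.b) for c in got] == [(1, 2, "A", "C"),
                                                  (1, 5, "D", "E")]
    assert [c.value for c in got] == pytest.approx([1.0, 0.5])
    assert len(ap.extract_pattern(model, 0.0)) == 3
    top = ap.extract_pattern(model, 1.0)
    assert [(c.p, c.q) for c in top] == [(1, 2)]
    with pytest.raises(ValueError):
        ap.extract_pattern(make_model(np.zeros((10, 20, 20)), w_d=1.0), 0.4)
    with pytest.raises(ValueError):
        ap.extract_pattern(model, 1.5)


def test_predictions_tsv_format(random_model, tmp_path):
    seqs = random_sequences(np.random.default_rng(4), 2, 8)
    preds = [ap.classify_sequence(s, random_model, 0.1) for s in seqs]
    out = tmp_path / "pred.tsv"
    with open(out, "w") as fh:
        ap.classify.write_predictions_tsv(preds, fh)
    lines = out.read_text().splitlines()
    assert lines[0] == "sequence_id\twindow_start\twindow_seq\tws\tcall"
    score_rows = [l for l in lines[1:] if not l.startswith("#")]
    assert len(score_rows) == sum(len(p.scores) for p in preds)
    ann_rows = [l for l in lines if l.startswith("#") and not l.startswith("#seq")]
    assert len(ann_rows) == 2
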