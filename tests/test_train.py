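import io
import itertools
from math import comb

import numpy as np
import pytest

import amypair as ap
from amypair.train import TrainingState, select_best_window

from conftest import random_sequences, seqs_from_strings


def brute_select(seq, others_windows, no_strings, n, eps):
    """Exhaustive oracle: rebuild full matrices for every candidate start
    and compare distances computed cell by cell."""
    no = ap.normalize(ap.build_comatrix(
        [w for s in seqs_from_strings(no_strings, "negative", "bn")
         for w in ap.extract_windows(s, n)], n))
    best = None
    raw = seq.to_string()
    for start in range(1, len(seq) - n + 2):
        cand = raw[start - 1:start - 1 + n]
        strings = others_windows + [cand]
        wins = [ap.Window(parent_id="o", start=1,
                          codes=ap.encode_sequence(s)) for s in strings]
        yes = ap.normalize(ap.build_comatrix(wins, n))
        w = ap.distance_w(yes, no, eps)
        if best is None or w > best[1] + 1e-12:
            best = (start, w)
    return best[0]


def test_forced_selection_when_length_equals_window():
    """A positive of length n contributes its only window, regardless of
    the surrounding selection state (the hexapeptide/window-6 case)."""
    pos = seqs_from_strings(["QNNQY"], "positive")
    neg = seqs_from_strings(["ACDEFGH", "KLMNPQR"], "negative")
    model = ap.fit(pos, neg, ap.TrainingConfig(window_length=5))
    assert model.selection == {"s0": 1}
    assert model.converged


def test_all_length_n_positives_average_directly():
    """With no selection freedom MatrixYES is the normalized matrix of all
    positives and training converges immediately."""
    strings = ["QNNQY", "AYAYA", "QQQQQ"]
    pos = seqs_from_strings(strings, "positive")
    neg = seqs_from_strings(["ACDEFGH"], "negative")
    model = ap.fit(pos, neg, ap.TrainingConfig(window_length=5))
    expected = ap.normalize(ap.build_comatrix(
        [w for s in pos for w in ap.extract_windows(s, 5)], 5))
    assert np.allclose(model.matrix_yes.values, expected.values)
    assert model.converged and len(model.w_trace) <= 2


def test_selection_matches_exhaustive_oracle():
    rng = np.random.default_rng(3)
    neg_strings = ["".join(ap.CODE_TO_AA[c] for c in rng.integers(1, 21, 9))
                   for _ in range(12)]
    pos = random_sequences(rng, 4, 9, "positive", "p")
    neg = seqs_from_strings(neg_strings, "negative", "n")
    config = ap.TrainingConfig(window_length=5)
    model = ap.fit(pos, neg, config)
    # at the fixpoint, each chosen start must equal the exhaustive argmax
    for k, seq in enumerate(pos):
        others = [seq2.to_string()[model.selection[seq2.id] - 1:
                                   model.selection[seq2.id] + 4]
                  for seq2 in pos if seq2.id != seq.id]
        assert model.selection[seq.id] == brute_select(
            seq, others, neg_strings, 5, config.epsilon)


def test_planted_motif_start_recovered(planted_model, planted_dataset):
    results, _, planted = planted_model
    hits = sum(results.selection[i] == planted[i] for i in results.selection)
    assert hits / len(results.selection) >= 0.95


def test_w_trace_monotone_and_fixpoint(planted_model):
    results, _, _ = planted_model
    trace = results.w_trace
    assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
    assert results.w_d == max(trace)
    assert results.converged
    # re-running a selection sweep on the converged model changes nothing
    model = results.trained
    state = TrainingState(window_length=5)
    pos = results.model.positives
    for k, seq in enumerate(pos):
        start = model.selection[seq.id]
        win = ap.extract_windows(seq, 5)[start - 1]
        state.contributions[k] = ap.build_comatrix([win], 5)
        state.selection[k] = start
    for k, seq in enumerate(pos):
        win = select_best_window(seq, k, state, model.matrix_no, model.config)
        assert win.start == model.selection[seq.id]


def test_one_window_accounting_and_short_positive_skip(caplog):
    pos = seqs_from_strings(["QNNQYAGH", "AYAY", "QQQQQQ"], "positive")
    neg = seqs_from_strings(["ACDEFGH", "KLMNPQR"], "negative")
    with caplog.at_level("WARNING"):
        model = ap.fit(pos, neg, ap.TrainingConfig(window_length=5))
    assert model.n_yes == 2  # the 4-residue fragment cannot contribute
    assert model.matrix_yes.window_count == 2
    assert "skipped" in caplog.text


def test_fit_invariant_to_negative_order_and_positive_order():
    rng = np.random.default_rng(11)
    pos = random_sequences(rng, 6, 8, "positive", "p")
    neg = random_sequences(rng, 10, 8, "negative", "n")
    config = ap.TrainingConfig(window_length=5)
    base = ap.fit(pos, neg, config)
    perm = rng.permutation(len(neg))
    again = ap.fit(pos, [neg[i] for i in perm], config)
    assert np.allclose(base.matrix_no.values, again.matrix_no.values)
    assert base.w_d == pytest.approx(again.w_d)
    # shuffling positives: same selection per sequence (tie-free random data)
    perm = rng.permutation(len(pos))
    shuf = ap.fit([pos[i] for i in perm], neg, config)
    assert shuf.selection == base.selection
    assert shuf.w_d == pytest.approx(base.w_d)


def test_no_signal_limit_ratio_near_one():
    """Identical positive and negative multisets of window-length peptides:
    the two matrices coincide, supported ratios are ~1 and w ~ support."""
    strings = ["QNNQY", "AYKLM", "GHSTV", "PPLEE"]
    pos = seqs_from_strings(strings, "positive", "p")
    neg = seqs_from_strings(strings, "negative", "n")
    model = ap.fit(pos, neg, ap.TrainingConfig(window_length=5))
    support = model.matrix_yes.values > 0
    assert np.allclose(model.ratio.values[support], 1.0, atol=1e-3)


def test_negative_matrix_errors_and_uniform_limit():
    config = ap.TrainingConfig(window_length=5)
    with pytest.raises(ValueError):
        ap.build_negative_matrix(seqs_from_strings(["ACD", "EF"]), config)
    # law of large numbers: i.i.d. uniform residues -> every cell ~ 0.00025
    rng = np.random.default_rng(0)
    neg = random_sequences(rng, 2000, 54, "negative")  # 1e5 windows
    m = ap.build_negative_matrix(neg, config)
    expected = 1.0 / (comb(5, 2) * 400)
    assert np.abs(m.values - expected).max() < 6 * np.sqrt(
        expected / (2000 * 50 * comb(5, 2)))  # ~6 sigma binomial band


def test_fit_requires_usable_data():
    config = ap.TrainingConfig(window_length=5)
    with pytest.raises(ValueError):
        ap.fit([], seqs_from_strings(["ACDEFG"], "negative"), config)
    with pytest.raises(ValueError):
        ap.fit(seqs_from_strings(["ACD"], "positive"),
               seqs_from_strings(["ACDEFG"], "negative"), config)


def test_model_serialization_round_trip(planted_model, tmp_path):
    results, _, _ = planted_model
    path = tmp_path / "model.json"
    results.save(str(path))
    back = ap.TrainedModel.load(str(path))
    assert np.allclose(back.matrix_yes.values, results.trained.matrix_yes.values)
    assert np.allclose(back.matrix_no.values, results.trained.matrix_no.values)
    assert back.w_d == pytest.approx(results.w_d)
    assert back.selection == results.selection
    assert back.config == results.trained.config
    # the reloaded model scores sequences identically
    seq = results.model.positives[0]
    a = ap.classify_sequence(seq, results.trained, 0.1)
    b = ap.classify_sequence(seq, back, 0.1)
    assert a.max_ws == pytest.approx(b.max_ws)
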