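"""Scoring and classification of sequences against a trained model.

A test window is scored by contracting its own singleton co-occurrence
matrix against the model's ratio matrix: the raw score is the sum of the
C(n,2) ratio-matrix lookups addressed by the window's residue pairs, and
w_s expresses it as a fraction of the maximal training distance w_d.  A
sequence is called positive when its best window exceeds the user-chosen
threshold w_l; residues covered by at least one above-threshold window are
annotated "1".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, TextIO

import numpy as np

from .seqcore import CODE_TO_AA, LabeledSequence, extract_windows
from .cooccur import n_pairs, position_pairs
from .train import TrainedModel

logger = logging.getLogger(__name__)


@dataclass
class WindowScore:
    """Score of one window; ``start`` is 1-based in the parent sequence."""

    start: int
    raw_score: float
    ws: float
    window_seq: str = ""


@dataclass
class SequencePrediction:
    """Per-window scores, sequence-level call, and per-residue annotation."""

    id: str
    scores: List[WindowScore]
    max_ws: float
    threshold: float
    label: str  # "positive" | "negative"
    residue_annotation: str

    @property
    def positive_windows(self) -> List[WindowScore]:
        return [s for s in self.scores if s.ws > self.threshold]


def score_window(codes: np.ndarray, model: TrainedModel) -> WindowScore:
    """Score one window of exactly the model's window length.

    raw = sum over p < q of ratio(p, q, r_p, r_q); ws = raw / w_d.
    """
    codes = np.asarray(codes, dtype=np.int64)
    n = model.config.window_length
    if codes.size != n:
        raise ValueError(f"window length {codes.size} != model window {n}")
    raw = 0.0
    for j, (p, q) in enumerate(position_pairs(n)):
        raw += model.ratio.values[j, codes[p - 1] - 1, codes[q - 1] - 1]
    return WindowScore(start=0, raw_score=float(raw), ws=float(raw) / model.w_d)


def classify_sequence(seq: LabeledSequence, model: TrainedModel,
                      w_l: float) -> SequencePrediction:
    """Score every sliding window of ``seq``; call positive iff the best
    window's w_s strictly exceeds w_l (ties at the threshold are negative).

    Sequences shorter than the window yield zero windows, a negative call
    and an all-zero annotation, with a warning.
    """
    if w_l < 0:
        raise ValueError("threshold w_l must be >= 0")
    n = model.config.window_length
    length = len(seq)
    if length < n:
        logger.warning(
            "sequence %r (length %d) shorter than window %d; reported negative",
            seq.id, length, n,
        )
        return SequencePrediction(id=seq.id, scores=[], max_ws=0.0,
                                  threshold=w_l, label="negative",
                                  residue_annotation="0" * length)
    scores: List[WindowScore] = []
    covered = np.zeros(length, dtype=bool)
    for win in extract_windows(seq, n):
        s = score_window(win.codes, model)
        s.start = win.start
        s.window_seq = win.to_string()
        scores.append(s)
        if s.ws > w_l:
            covered[win.start - 1:win.start - 1 + n] = True
    max_ws = max(s.ws for s in scores)
    return SequencePrediction(
        id=seq.id,
        scores=scores,
        max_ws=max_ws,
        threshold=w_l,
        label="positive" if max_ws > w_l else "negative",
        residue_annotation="".join("1" if c else "0" for c in covered),
    )


def score_sequences(sequences: Sequence[LabeledSequence],
                    model: TrainedModel) -> np.ndarray:
    """max_ws for each sequence (0.0 for sequences shorter than the window)."""
    return np.array([classify_sequence(s, model, 0.0).max_ws for s in sequences])


@dataclass
class PatternPair:
    """One co-localized residue pair of the learned pattern.

    ``value`` is the ratio cell rescaled to [0, 1] by the matrix maximum.
    """

    p: int
    q: int
    a: str
    b: str
    value: float


def extract_pattern(model: TrainedModel, cutoff: float) -> List[PatternPair]:
    """All ratio cells whose max-rescaled value reaches ``cutoff``, sorted
    by (p, q, descending value).

    Rescaling divides by the maximum ratio cell, so a cut-off in [0, 1]
    (0.4 by convention) is scale-free.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    vmax = float(model.ratio.values.max())
    if vmax <= 0:
        raise ValueError("degenerate ratio matrix: no positive cell")
    n = model.config.window_length
    pairs: List[PatternPair] = []
    for j, (p, q) in enumerate(position_pairs(n)):
        plane = model.ratio.values[j] / vmax
        keep = np.argwhere(plane >= cutoff) if cutoff > 0 else np.argwhere(plane > 0)
        for a, b in keep:
            pairs.append(PatternPair(p=p, q=q, a=CODE_TO_AA[a + 1],
                                     b=CODE_TO_AA[b + 1],
                                     value=float(plane[a, b])))
    pairs.sort(key=lambda c: (c.p, c.q, -c.value))
    return pairs


def write_predictions_tsv(predictions: Sequence[SequencePrediction],
                          fh: TextIO) -> None:
    """Per-window score rows, then per-sequence annotation lines."""
    fh.write("sequence_id\twindow_start\twindow_seq\tws\tcall\n")
    for pred in predictions:
        for s in pred.scores:
            call = "+" if s.ws > pred.threshold else "-"
            fh.write(f"{pred.id}\t{s.start}\t{s.window_seq}\t{s.ws:.6f}\t{call}\n")
    fh.write("#sequence_id\tlabel\tannotation\n")
    for pred in predictions:
        fh.write(f"#{pred.id}\t{pred.label}\t{pred.residue_annotation}\n")
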