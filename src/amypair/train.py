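"""Training: negative-matrix averaging and discriminative window selection.

All sliding windows of every negative sequence contribute equally to the
negative co-occurrence matrix (any pattern present in the negatives is
averaged out by the shifting window).  Each positive sequence, by contrast,
contributes exactly ONE window: the iterative procedure below selects, per
positive sequence, the window whose inclusion maximizes the distance w
between the normalized positive matrix and the negative matrix.  The
maximal distance reached, w_d, is stored on the model and later serves as
the denominator of classification scores.

The selection is initialized with ALL windows of every positive sequence
contributing (the same averaging used for negatives) and then refined by
sequential greedy sweeps in input order, immediately committing each best
window, until the selection map reaches a fixpoint or the iteration cap is
hit.  The procedure is deterministic: no randomness, ties broken toward the
smallest window start.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, TextIO, Tuple, Union

import numpy as np

from .seqcore import AA_TO_CODE, CODE_TO_AA, LabeledSequence, Window, extract_windows
from .cooccur import (
    DEFAULT_EPSILON,
    CoMatrix,
    RatioMatrix,
    build_comatrix,
    distance_w,
    n_pairs,
    normalize,
    position_pairs,
    ratio_matrix,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainingConfig:
    """Hyper-parameters of the training procedure.

    window_length : int
        Length n of the sliding window (the minimal fragment assumed to
        carry the classification property; 5 or 6 in hot-spot practice).
    epsilon : float
        Pseudo-mass added to negative-matrix cells in the ratio.
    max_iterations : int
        Cap on selection sweeps over the positive set.
    min_improvement : float
        Early-stop tolerance on the gain in w between sweeps; 0 means run
        to an exact window-assignment fixpoint.
    """

    window_length: int = 5
    epsilon: float = DEFAULT_EPSILON
    max_iterations: int = 100
    min_improvement: float = 0.0

    def __post_init__(self):
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not (4 <= self.window_length <= 10):
            logger.warning(
                "window_length %d outside the usual hot-spot range 4..10",
                self.window_length,
            )
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class TrainingState:
    """Mutable state of the selection procedure.

    ``contributions[k]`` is the un-normalized co-occurrence matrix currently
    contributed by the k-th usable positive sequence (all of its windows at
    initialization, a single window once selected); ``selection[k]`` is the
    chosen 1-based window start, or None while still averaged.
    """

    window_length: int
    contributions: Dict[int, CoMatrix] = field(default_factory=dict)
    selection: Dict[int, Optional[int]] = field(default_factory=dict)
    iteration: int = 0
    w_trace: List[float] = field(default_factory=list)

    def total_counts(self) -> CoMatrix:
        m = CoMatrix.zeros(self.window_length)
        for c in self.contributions.values():
            m.values += c.values
            m.window_count += c.window_count
        return m

    @property
    def X(self) -> CoMatrix:
        """The normalized sum of all current contributions."""
        return normalize(self.total_counts())


def build_negative_matrix(negatives: Sequence[LabeledSequence],
                          config: TrainingConfig) -> CoMatrix:
    """Normalized co-occurrence matrix over every sliding window of every
    negative sequence.  Sequences shorter than the window are skipped with
    a warning; zero usable windows is an error."""
    n = config.window_length
    windows: List[Window] = []
    for seq in negatives:
        if len(seq) < n:
            logger.warning(
                "negative sequence %r (length %d) shorter than window %d; skipped",
                seq.id, len(seq), n,
            )
            continue
        windows.extend(extract_windows(seq, n))
    if not windows:
        raise ValueError("no negative sequence yields a usable window")
    return normalize(build_comatrix(windows, n))


def _candidate_scores(seq: LabeledSequence, k: int, state: TrainingState,
                      ratio_values: np.ndarray, config: TrainingConfig,
                      ) -> List[Tuple[Window, float]]:
    """w obtained by substituting each candidate window of ``seq`` for the
    k-th contribution.  ``ratio_values`` is 1/(no + eps) cell-wise."""
    n = config.window_length
    npr = n_pairs(n)
    total = state.total_counts()
    current = state.contributions.get(k)
    if current is not None:
        other_values = total.values - current.values
        other_windows = total.window_count - current.window_count
    else:
        other_values = total.values
        other_windows = total.window_count
    base = float((other_values * ratio_values).sum())
    pairs = position_pairs(n)
    out = []
    for win in extract_windows(seq, n):
        add = sum(
            ratio_values[j, win.codes[p - 1] - 1, win.codes[q - 1] - 1]
            for j, (p, q) in enumerate(pairs)
        )
        w = (base + add) / ((other_windows + 1) * npr)
        out.append((win, w))
    return out


def select_best_window(seq: LabeledSequence, k: int, state: TrainingState,
                       matrix_no: CoMatrix, config: TrainingConfig) -> Window:
    """The window of ``seq`` whose substitution into the current selection
    maximizes w; ties broken toward the smallest start."""
    if len(seq) < config.window_length:
        raise ValueError(
            f"sequence {seq.id!r} shorter than window {config.window_length}"
        )
    ratio_values = 1.0 / (matrix_no.values + config.epsilon)
    scored = _candidate_scores(seq, k, state, ratio_values, config)
    best_win, _ = max(scored, key=lambda t: (t[1], -t[0].start))
    return best_win


@dataclass
class TrainedModel:
    """A fitted co-occurrence classifier.

    Carries the normalized negative and positive matrices, their cell-wise
    ratio, and the maximal training distance w_d used as the score
    denominator in classification.
    """

    config: TrainingConfig
    matrix_no: CoMatrix
    matrix_yes: CoMatrix
    ratio: RatioMatrix
    w_d: float
    n_yes: int
    n_no: int
    iterations_run: int
    converged: bool = True
    w_trace: List[float] = field(default_factory=list)
    selection: Dict[str, int] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.w_d <= 0:
            raise ValueError("w_d must be > 0")
        if self.matrix_yes.window_count != self.n_yes:
            raise ValueError(
                "positive matrix must contain exactly one window per "
                "contributing positive sequence"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def cells(m: CoMatrix) -> list:
            out = []
            for j, (p, q) in enumerate(position_pairs(m.window_length)):
                nz = np.argwhere(m.values[j] != 0.0)
                for a, b in nz:
                    out.append([p, q, CODE_TO_AA[a + 1], CODE_TO_AA[b + 1],
                                float(m.values[j, a, b])])
            return out

        return {
            "format_version": MODEL_FORMAT_VERSION,
            "config": {
                "window_length": self.config.window_length,
                "epsilon": self.config.epsilon,
                "max_iterations": self.config.max_iterations,
                "min_improvement": self.config.min_improvement,
            },
            "matrix_no": {"cells": cells(self.matrix_no),
                          "window_count": self.matrix_no.window_count},
            "matrix_yes": {"cells": cells(self.matrix_yes),
                           "window_count": self.matrix_yes.window_count},
            "w_d": self.w_d,
            "n_yes": self.n_yes,
            "n_no": self.n_no,
            "iterations_run": self.iterations_run,
            "converged": self.converged,
            "w_trace": self.w_trace,
            "selection": self.selection,
            "provenance": self.provenance,
        }

    def save(self, fh: Union[str, TextIO]) -> None:
        if isinstance(fh, str):
            with open(fh, "w") as f:
                json.dump(self.to_dict(), f, indent=1)
        else:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {d.get('format_version')}")
        config = TrainingConfig(**d["config"])
        n = config.window_length
        pairs = {pq: j for j, pq in enumerate(position_pairs(n))}

        def matrix(entry: dict) -> CoMatrix:
            m = CoMatrix.zeros(n)
            for p, q, aa_p, aa_q, v in entry["cells"]:
                m.values[pairs[(int(p), int(q))],
                         AA_TO_CODE[aa_p] - 1, AA_TO_CODE[aa_q] - 1] = float(v)
            m.window_count = int(entry["window_count"])
            m.normalized = True
            if abs(m.total() - 1.0) > 1e-9:
                raise ValueError("stored matrix does not sum to 1")
            return m

        matrix_no = matrix(d["matrix_no"])
        matrix_yes = matrix(d["matrix_yes"])
        return cls(
            config=config,
            matrix_no=matrix_no,
            matrix_yes=matrix_yes,
            ratio=ratio_matrix(matrix_yes, matrix_no, config.epsilon),
            w_d=float(d["w_d"]),
            n_yes=int(d["n_yes"]),
            n_no=int(d["n_no"]),
            iterations_run=int(d["iterations_run"]),
            converged=bool(d["converged"]),
            w_trace=[float(x) for x in d["w_trace"]],
            selection={k: int(v) for k, v in d["selection"].items()},
            provenance=dict(d.get("provenance", {})),
        )

    @classmethod
    def load(cls, fh: Union[str, TextIO]) -> "TrainedModel":
        if isinstance(fh, str):
            with open(fh) as f:
                return cls.from_dict(json.load(f))
        return cls.from_dict(json.load(fh))


def fit(positives: Sequence[LabeledSequence],
        negatives: Sequence[LabeledSequence],
        config: Optional[TrainingConfig] = None) -> TrainedModel:
    """Fit the classifier: averaged negative matrix, one selected window per
    positive sequence, maximal distance w_d.

    Deterministic given inputs and config.  Positive sequences shorter than
    the window are skipped with a warning.  Returns an unconverged model
    with a warning if the iteration cap is reached first.
    """
    if config is None:
        config = TrainingConfig()
    n = config.window_length

    matrix_no = build_negative_matrix(negatives, config)
    ratio_values = 1.0 / (matrix_no.values + config.epsilon)

    usable: List[LabeledSequence] = []
    for seq in positives:
        if len(seq) < n:
            logger.warning(
                "positive sequence %r (length %d) shorter than window %d; skipped",
                seq.id, len(seq), n,
            )
            continue
        usable.append(seq)
    if not usable:
        raise ValueError("no positive sequence is at least as long as the window")

    state = TrainingState(window_length=n)
    for k, seq in enumerate(usable):
        state.contributions[k] = build_comatrix(extract_windows(seq, n), n)
        state.selection[k] = None

    converged = False
    for sweep in range(1, config.max_iterations + 1):
        state.iteration = sweep
        previous = dict(state.selection)
        for k, seq in enumerate(usable):
            win = select_best_window(seq, k, state, matrix_no, config)
            state.contributions[k] = build_comatrix([win], n)
            state.selection[k] = win.start
        X = state.X
        w = float((X.values * ratio_values)[X.values > 0].sum())
        state.w_trace.append(w)
        if state.selection == previous:
            converged = True
            break
        if (config.min_improvement > 0 and len(state.w_trace) >= 2
                and state.w_trace[-1] - state.w_trace[-2] <= config.min_improvement):
            converged = True
            break
    if not converged:
        logger.warning(
            "selection did not reach a fixpoint within %d sweeps",
            config.max_iterations,
        )

    matrix_yes = state.X
    ratio = ratio_matrix(matrix_yes, matrix_no, config.epsilon)
    w_d = max(state.w_trace)
    return TrainedModel(
        config=config,
        matrix_no=matrix_no,
        matrix_yes=matrix_yes,
        ratio=ratio,
        w_d=w_d,
        n_yes=len(usable),
        n_no=len(negatives),
        iterations_run=state.iteration,
        converged=converged,
        w_trace=state.w_trace,
        selection={seq.id: state.selection[k] for k, seq in enumerate(usable)},
    )
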