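"""Model/Results facade over the functional training and scoring layer.

``PairCooccurrenceModel`` is constructed from labeled sequence data
(statsmodels-style); ``fit()`` runs the discriminative window-selection
training and returns ``PairCooccurrenceResults``, which carries the fitted
matrices, the maximal training distance w_d, selection diagnostics, and
prediction / pattern-extraction / plotting methods.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .seqcore import LabeledSequence
from .cooccur import n_pairs
from .train import TrainedModel, TrainingConfig, fit as _fit
from .classify import (
    PatternPair,
    SequencePrediction,
    classify_sequence,
    extract_pattern,
    score_sequences,
)
from .datasets import DatasetRecord, to_labeled_sequences

#: Decision threshold used by the published web tool's hot-spot maps.
DEFAULT_WL = 0.14


class PairCooccurrenceModel:
    """Discriminative position-specific residue-pair co-occurrence model.

    Parameters
    ----------
    positives, negatives : sequences of LabeledSequence
        Training peptides.  Positives are assumed to contain one
        pattern-carrying window each (located by training); all windows of
        every negative contribute to the background matrix.
    window_length, epsilon, max_iterations, min_improvement :
        See :class:`~amypair.train.TrainingConfig`.
    """

    def __init__(self, positives: Sequence[LabeledSequence],
                 negatives: Sequence[LabeledSequence],
                 window_length: int = 5,
                 epsilon: float = 1e-6,
                 max_iterations: int = 100,
                 min_improvement: float = 0.0):
        self.positives = list(positives)
        self.negatives = list(negatives)
        self.config = TrainingConfig(
            window_length=window_length,
            epsilon=epsilon,
            max_iterations=max_iterations,
            min_improvement=min_improvement,
        )

    @classmethod
    def from_records(cls, records: Sequence[DatasetRecord],
                     **config) -> "PairCooccurrenceModel":
        """Build from labeled dataset records (e.g. a parsed CSV)."""
        seqs = to_labeled_sequences(records)
        return cls([s for s in seqs if s.label == "positive"],
                   [s for s in seqs if s.label == "negative"], **config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **config) -> "PairCooccurrenceModel":
        """Build from a DataFrame with columns id, sequence, label."""
        records = [DatasetRecord(id=str(r.id), sequence=str(r.sequence),
                                 label=str(r.label))
                   for r in df.itertuples(index=False)]
        return cls.from_records(records, **config)

    def fit(self) -> "PairCooccurrenceResults":
        return PairCooccurrenceResults(self, _fit(self.positives,
                                                  self.negatives, self.config))


class PairCooccurrenceResults:
    """Fitted model: matrices, w_d, diagnostics, prediction and pattern."""

    def __init__(self, model: Optional[PairCooccurrenceModel],
                 trained: TrainedModel):
        self.model = model
        self.trained = trained

    # convenient passthroughs -------------------------------------------------
    @property
    def w_d(self) -> float:
        return self.trained.w_d

    @property
    def w_trace(self) -> List[float]:
        return self.trained.w_trace

    @property
    def selection(self) -> dict:
        """Chosen window start (1-based) per contributing positive sequence."""
        return self.trained.selection

    @property
    def converged(self) -> bool:
        return self.trained.converged

    # prediction --------------------------------------------------------------
    def predict(self, sequences: Sequence[LabeledSequence],
                w_l: float = DEFAULT_WL) -> List[SequencePrediction]:
        """Classify sequences at threshold w_l (per-window scores, calls,
        per-residue annotations)."""
        return [classify_sequence(s, self.trained, w_l) for s in sequences]

    def score(self, sequences: Sequence[LabeledSequence]) -> np.ndarray:
        """max_ws per sequence (threshold-free)."""
        return score_sequences(sequences, self.trained)

    def extract_pattern(self, cutoff: float = 0.4) -> List[PatternPair]:
        """Co-localized residue pairs above the max-rescaled cut-off."""
        return extract_pattern(self.trained, cutoff)

    def pattern_frame(self, cutoff: float = 0.4) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.p, c.q, c.a, c.b, c.value) for c in self.extract_pattern(cutoff)],
            columns=["p", "q", "aa_p", "aa_q", "value"],
        )

    # persistence -------------------------------------------------------------
    def save(self, path: str) -> None:
        self.trained.save(path)

    @classmethod
    def load(cls, path: str) -> "PairCooccurrenceResults":
        return cls(None, TrainedModel.load(path))

    # reporting ---------------------------------------------------------------
    def summary(self) -> str:
        t = self.trained
        npr = n_pairs(t.config.window_length)
        lines = [
            "Pair co-occurrence hot-spot classifier",
            "=" * 46,
            f"window length n          {t.config.window_length}",
            f"position pairs C(n,2)    {npr}",
            f"epsilon                  {t.config.epsilon:g}",
            f"positive sequences       {t.n_yes}",
            f"negative sequences       {t.n_no}",
            f"negative windows         {t.matrix_no.window_count}",
            f"selection sweeps         {t.iterations_run}"
            f"{'' if t.converged else '  (NOT converged)'}",
            f"maximal distance w_d     {t.w_d:.6g}",
            f"final training w         {t.w_trace[-1]:.6g}" if t.w_trace else "",
            "=" * 46,
        ]
        return "\n".join(line for line in lines if line)

    def plot_roc(self, roc, ax=None):
        """Plot an ROCResult (Sn against 1-Sp)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr = [1 - sp for _, _, sp in roc.points][::-1]
        tpr = [sn for _, sn, _ in roc.points][::-1]
        ax.plot(fpr, tpr, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("1 - Sp")
        ax.set_ylabel("Sn")
        ax.set_title(f"AUC = {roc.auc:.3f}")
        return ax

    def plot_pattern(self, ax=None):
        """Heatmap of the max-rescaled ratio matrix, planes side by side."""
        import matplotlib.pyplot as plt

        from .cooccur import position_pairs

        t = self.trained
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        vmax = t.ratio.values.max()
        planes = t.ratio.values / vmax
        img = np.hstack(list(planes))
        im = ax.imshow(img, aspect="auto", cmap="Greys")
        ax.set_xticks([20 * k + 10 for k in range(planes.shape[0])])
        ax.set_xticklabels([f"{p},{q}" for p, q in
                            position_pairs(t.config.window_length)])
        ax.set_xlabel("position pair (p,q); residue b within each plane")
        ax.set_ylabel("residue a")
        plt.colorbar(im, ax=ax)
        return ax
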