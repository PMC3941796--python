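"""amypair: amyloid hot-spot prediction from position-specific
amino-acid pair co-occurrence patterns.

The classifier learns, from labeled peptide fragments, a position-specific
co-occurrence matrix of residue pairs inside a sliding window: the negative
class is averaged over all windows, while one most pattern-bearing window
is selected per positive sequence by an iterative distance-maximization
procedure.  New sequences are scored window by window against the ratio of
the two matrices, expressed as a fraction w_s of the maximal training
distance w_d; windows with w_s above a user threshold w_l mark predicted
hot spots.
"""

from .seqcore import (
    ALPHABET,
    AA_TO_CODE,
    CODE_TO_AA,
    LabeledSequence,
    SequenceAlphabetError,
    Window,
    decode_sequence,
    encode_sequence,
    extract_windows,
)
from .cooccur import (
    CoMatrix,
    RatioMatrix,
    build_comatrix,
    distance_w,
    normalize,
    ratio_matrix,
)
from .train import TrainedModel, TrainingConfig, build_negative_matrix, fit
from .classify import (
    PatternPair,
    SequencePrediction,
    WindowScore,
    classify_sequence,
    extract_pattern,
    score_sequences,
    score_window,
)
from .evaluate import (
    ConfusionCounts,
    CVResult,
    ROCResult,
    confusion,
    cross_test,
    cross_validate,
    roc_curve,
)
from .datasets import (
    DatasetRecord,
    SyntheticSpec,
    default_motif,
    generate_synthetic,
    read_fasta,
    read_labeled_csv,
    sup35_fixture,
    to_labeled_sequences,
    write_labeled_csv,
)
from .model import DEFAULT_WL, PairCooccurrenceModel, PairCooccurrenceResults

__version__ = "0.1.0"

__all__ = [
    "ALPHABET", "AA_TO_CODE", "CODE_TO_AA",
    "LabeledSequence", "SequenceAlphabetError", "Window",
    "encode_sequence", "decode_sequence", "extract_windows",
    "CoMatrix", "RatioMatrix", "build_comatrix", "normalize",
    "ratio_matrix", "distance_w",
    "TrainingConfig", "TrainedModel", "build_negative_matrix", "fit",
    "WindowScore", "SequencePrediction", "PatternPair",
    "score_window", "classify_sequence", "score_sequences", "extract_pattern",
    "ConfusionCounts", "ROCResult", "CVResult",
    "confusion", "roc_curve", "cross_validate", "cross_test",
    "DatasetRecord", "SyntheticSpec", "default_motif", "generate_synthetic",
    "read_labeled_csv", "write_labeled_csv", "read_fasta",
    "sup35_fixture", "to_labeled_sequences",
    "PairCooccurrenceModel", "PairCooccurrenceResults", "DEFAULT_WL",
]
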