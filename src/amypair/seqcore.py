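"""Amino-acid alphabet, integer sequence encoding, and sliding windows.

Residues are encoded as integers 1..20 in alphabetical one-letter order
(A=1, C=2, ..., Y=20).  All positions reported anywhere in the package are
1-based and inclusive, matching the fragment notation used in the amyloid
hot-spot literature (e.g. "7-17").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Literal

import numpy as np

logger = logging.getLogger(__name__)

#: The 20 standard residues in alphabetical one-letter order.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: one-letter code -> integer code 1..20
AA_TO_CODE: dict = {aa: i + 1 for i, aa in enumerate(ALPHABET)}

#: integer code 1..20 -> one-letter code
CODE_TO_AA: dict = {i + 1: aa for i, aa in enumerate(ALPHABET)}

#: Sentinel used for non-standard residues in permissive mode.
INVALID_CODE: int = 0

Label = Literal["positive", "negative", "unlabeled"]
_LABELS = ("positive", "negative", "unlabeled")


class SequenceAlphabetError(ValueError):
    """A residue outside the 20-letter standard alphabet was encountered."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position  # 1-based
        super().__init__(
            f"invalid residue {residue!r} at position {position} "
            f"(allowed: {ALPHABET})"
        )


def encode_sequence(raw: str, permissive: bool = False) -> np.ndarray:
    """Encode a one-letter amino-acid string as integer codes 1..20.

    Parsing is case-insensitive and surrounding whitespace is ignored.

    Parameters
    ----------
    raw : str
        One-letter amino-acid sequence.
    permissive : bool
        If True, non-standard residues (B, J, O, U, X, Z, ...) are encoded
        as ``INVALID_CODE`` (0) with a logged warning instead of raising;
        windows containing them are dropped by :func:`extract_windows`.

    Returns
    -------
    numpy.ndarray of int
        One code per residue, order preserved.
    """
    s = raw.strip().upper()
    if not s:
        raise ValueError("empty sequence")
    codes = np.empty(len(s), dtype=np.int64)
    for i, ch in enumerate(s):
        code = AA_TO_CODE.get(ch)
        if code is None:
            if not permissive:
                raise SequenceAlphabetError(ch, i + 1)
            logger.warning("non-standard residue %r at position %d; masked", ch, i + 1)
            code = INVALID_CODE
        codes[i] = code
    return codes


def decode_sequence(codes: Iterable[int]) -> str:
    """Inverse of :func:`encode_sequence` for valid codes (1..20)."""
    out = []
    for i, c in enumerate(codes):
        aa = CODE_TO_AA.get(int(c))
        if aa is None:
            raise ValueError(f"invalid residue code {c!r} at position {i + 1}")
        out.append(aa)
    return "".join(out)


@dataclass
class LabeledSequence:
    """An encoded peptide or protein with an optional class label."""

    id: str
    residues: np.ndarray
    label: Label = "unlabeled"

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=np.int64)
        if self.residues.size < 1:
            raise ValueError(f"sequence {self.id!r}: length must be >= 1")
        bad = (self.residues < 0) | (self.residues > 20)
        if bad.any():
            raise ValueError(f"sequence {self.id!r}: residue codes out of range")
        if self.label not in _LABELS:
            raise ValueError(f"sequence {self.id!r}: unknown label {self.label!r}")

    @classmethod
    def from_string(cls, id: str, raw: str, label: Label = "unlabeled",
                    permissive: bool = False) -> "LabeledSequence":
        return cls(id=id, residues=encode_sequence(raw, permissive=permissive),
                   label=label)

    def __len__(self) -> int:
        return int(self.residues.size)

    def to_string(self) -> str:
        return decode_sequence(self.residues)


@dataclass
class Window:
    """A length-n slice of a parent sequence; ``start`` is 1-based."""

    parent_id: str
    start: int
    codes: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.codes.size)

    def to_string(self) -> str:
        return decode_sequence(self.codes)


def extract_windows(seq: LabeledSequence, n: int,
                    drop_invalid: bool = True) -> List[Window]:
    """All contiguous length-``n`` windows of ``seq``, shifted one position
    at a time.

    Returns exactly ``len(seq) - n + 1`` windows with starts 1..L-n+1
    (fewer if ``drop_invalid`` removes windows containing masked residues
    from permissive encoding).

    Raises
    ------
    ValueError
        If ``n < 2`` or the sequence is shorter than ``n``.  Callers that
        iterate over collections may catch this and skip with a warning.
    """
    if n < 2:
        raise ValueError(f"window length must be >= 2, got {n}")
    length = len(seq)
    if length < n:
        raise ValueError(
            f"sequence {seq.id!r} of length {length} is shorter than window {n}"
        )
    windows = []
    for a in range(length - n + 1):
        codes = seq.residues[a:a + n]
        if drop_invalid and (codes == INVALID_CODE).any():
            logger.warning(
                "sequence %r: window at %d contains a masked residue; dropped",
                seq.id, a + 1,
            )
            continue
        windows.append(Window(parent_id=seq.id, start=a + 1, codes=codes))
    return windows
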