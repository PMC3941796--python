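"""Position-specific residue-pair co-occurrence matrices.

A co-occurrence matrix over a set of fixed-length-n windows counts, for
every unordered position pair (p, q) with 1 <= p < q <= n and every residue
pair (a, b), how many windows carry residue a at p together with residue b
at q.  The index space is C(n,2) x 20 x 20, stored dense (<= 18,000 reals
for n <= 10).  Only the upper triangle p < q is stored: the (q, p, b, a)
mirror cell is transpose-redundant and may be reconstructed on output.

The discriminative distance w between a positive and a negative matrix is
the sum of element-wise ratios yes / (no + epsilon) over the cells with
positive numerator; the epsilon pseudo-mass keeps the ratio finite where
the negative matrix has empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb
from typing import List, Sequence, TextIO, Tuple, Union

import numpy as np

from .seqcore import AA_TO_CODE, CODE_TO_AA, Window

#: Default pseudo-mass added to the denominator of cell-wise ratios.
DEFAULT_EPSILON: float = 1e-6


def position_pairs(n: int) -> List[Tuple[int, int]]:
    """Ordered list of 1-based position pairs (p, q), p < q, for window n."""
    return [(p, q) for p in range(1, n + 1) for q in range(p + 1, n + 1)]


def n_pairs(n: int) -> int:
    return comb(n, 2)


@dataclass
class CoMatrix:
    """Counts (or normalized frequencies) of residue pairs by position pair.

    ``values[k, a-1, b-1]`` is the cell for the k-th position pair
    ``position_pairs(window_length)[k]`` and residue codes a, b.
    """

    window_length: int
    values: np.ndarray = field(repr=False)
    window_count: int = 0
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (n_pairs(self.window_length), 20, 20)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != {expected} "
                f"for window length {self.window_length}"
            )
        if self.window_count < 0:
            raise ValueError("window_count must be >= 0")

    @classmethod
    def zeros(cls, n: int) -> "CoMatrix":
        return cls(window_length=n, values=np.zeros((n_pairs(n), 20, 20)))

    def cell(self, p: int, q: int, a: Union[int, str], b: Union[int, str]) -> float:
        """Cell value for positions (p, q), residues a, b (codes or letters)."""
        if isinstance(a, str):
            a = AA_TO_CODE[a.upper()]
        if isinstance(b, str):
            b = AA_TO_CODE[b.upper()]
        k = position_pairs(self.window_length).index((p, q))
        return float(self.values[k, a - 1, b - 1])

    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "CoMatrix":
        return replace(self, values=self.values.copy())


def build_comatrix(windows: Sequence[Window], n: int) -> CoMatrix:
    """Count residue pairs over ``windows``, all of which must have length n.

    Each window contributes one count to each of its C(n,2) cells, so the
    un-normalized total mass is ``len(windows) * C(n,2)`` and every (p, q)
    plane sums to ``len(windows)``.
    """
    for w in windows:
        if len(w) != n:
            raise ValueError(
                f"window from {w.parent_id!r} has length {len(w)}, expected {n}"
            )
    m = CoMatrix.zeros(n)
    if windows:
        codes = np.stack([w.codes for w in windows])  # (W, n), values 1..20
        for k, (p, q) in enumerate(position_pairs(n)):
            np.add.at(m.values[k], (codes[:, p - 1] - 1, codes[:, q - 1] - 1), 1.0)
    m.window_count = len(windows)
    return m


def normalize(m: CoMatrix) -> CoMatrix:
    """Scale so the whole matrix sums to 1 (divide counts by W * C(n,2)).

    Idempotent on already-normalized input; window_count is retained as
    metadata.  Raises on an empty matrix.
    """
    if m.window_count < 1:
        raise ValueError("cannot normalize a matrix built from zero windows")
    if m.normalized:
        return m.copy()
    denom = m.window_count * n_pairs(m.window_length)
    return CoMatrix(window_length=m.window_length, values=m.values / denom,
                    window_count=m.window_count, normalized=True)


@dataclass
class RatioMatrix:
    """Cell-wise yes / (no + epsilon) ratios and their sum w."""

    window_length: int
    values: np.ndarray = field(repr=False)
    epsilon: float = DEFAULT_EPSILON
    w: float = 0.0

    def cell(self, p: int, q: int, a: Union[int, str], b: Union[int, str]) -> float:
        if isinstance(a, str):
            a = AA_TO_CODE[a.upper()]
        if isinstance(b, str):
            b = AA_TO_CODE[b.upper()]
        k = position_pairs(self.window_length).index((p, q))
        return float(self.values[k, a - 1, b - 1])


def ratio_matrix(yes: CoMatrix, no: CoMatrix,
                 epsilon: float = DEFAULT_EPSILON) -> RatioMatrix:
    """Element-wise ratio of two normalized matrices with smoothing.

    ``values(c) = yes(c) / (no(c) + epsilon)``; ``w`` sums the values over
    the cells with positive numerator (cells with yes(c) = 0 contribute 0).
    """
    if yes.window_length != no.window_length:
        raise ValueError(
            f"window lengths differ: {yes.window_length} vs {no.window_length}"
        )
    if not (yes.normalized and no.normalized):
        raise ValueError("ratio_matrix expects normalized matrices")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    values = yes.values / (no.values + epsilon)
    w = float(values[yes.values > 0].sum())
    return RatioMatrix(window_length=yes.window_length, values=values,
                       epsilon=epsilon, w=w)


def distance_w(yes: CoMatrix, no: CoMatrix,
               epsilon: float = DEFAULT_EPSILON) -> float:
    """The discriminative distance w between positive and negative matrices."""
    return ratio_matrix(yes, no, epsilon).w


# ---------------------------------------------------------------------------
# Long-format TSV export / import (header: p q aa_p aa_q value)

def write_matrix_tsv(m: Union[CoMatrix, RatioMatrix], fh: TextIO,
                     include_zeros: bool = False) -> None:
    """Write a matrix as long-format TSV, one row per cell."""
    fh.write("p\tq\taa_p\taa_q\tvalue\n")
    for k, (p, q) in enumerate(position_pairs(m.window_length)):
        plane = m.values[k]
        for a in range(20):
            for b in range(20):
                v = plane[a, b]
                if v == 0.0 and not include_zeros:
                    continue
                fh.write(f"{p}\t{q}\t{CODE_TO_AA[a + 1]}\t{CODE_TO_AA[b + 1]}\t"
                         f"{float(v)!r}\n")


def read_matrix_tsv(fh: TextIO, window_length: int) -> CoMatrix:
    """Read a long-format TSV back into an (un-flagged) CoMatrix."""
    header = fh.readline().strip().split("\t")
    if header != ["p", "q", "aa_p", "aa_q", "value"]:
        raise ValueError(f"unexpected matrix TSV header: {header}")
    m = CoMatrix.zeros(window_length)
    pairs = {pq: k for k, pq in enumerate(position_pairs(window_length))}
    for line in fh:
        if not line.strip():
            continue
        p, q, aa_p, aa_q, v = line.rstrip("\n").split("\t")
        k = pairs[(int(p), int(q))]
        m.values[k, AA_TO_CODE[aa_p] - 1, AA_TO_CODE[aa_q] - 1] = float(v)
    return m
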