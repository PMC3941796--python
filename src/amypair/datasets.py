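"""Labeled peptide dataset IO, embedded fixtures, and synthetic data.

The embedded fixture is the printed sup35 prion-fragment test set: 12
positive and 31 negative 10-residue fragments with their published
classification calls and w_s scores (decimal commas in a few printed
scores are normalized to points; both raw and parsed values are kept).

The synthetic generator emulates the structure the classifier is built to
detect: positive peptides carry one planted window in which specific
residue pairs co-occur at fixed relative positions, embedded in random
background; negative peptides are pattern-free background.  Both classes
draw background residues i.i.d. (uniform by default), rejection-sampled so
that no induced motif pair occurs at its relative spacing — the planted
window is therefore the only systematic difference between the classes,
and with co-occurrence probability 0 the two classes are statistically
identical.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

from .seqcore import (
    ALPHABET,
    AA_TO_CODE,
    LabeledSequence,
    decode_sequence,
    encode_sequence,
)

logger = logging.getLogger(__name__)

_LABEL_SPELLINGS = {
    "1": "positive", "0": "negative",
    "pos": "positive", "neg": "negative",
    "positive": "positive", "negative": "negative",
    "amyloid": "positive", "non-amyloid": "negative",
    "+": "positive", "-": "negative",
    "yes": "positive", "no": "negative",
}


@dataclass
class DatasetRecord:
    """One labeled peptide fragment."""

    id: str
    sequence: str
    label: str  # "positive" | "negative"
    source: str = ""

    def __post_init__(self):
        encode_sequence(self.sequence)  # validates the alphabet
        self.sequence = self.sequence.strip().upper()
        if self.label not in ("positive", "negative"):
            raise ValueError(f"record {self.id!r}: bad label {self.label!r}")


def to_labeled_sequences(records: Sequence[DatasetRecord]) -> List[LabeledSequence]:
    return [LabeledSequence.from_string(r.id, r.sequence, r.label)
            for r in records]


def read_labeled_csv(path: Union[str, Path]) -> List[DatasetRecord]:
    """Read a labeled dataset CSV with header columns id, sequence, label
    (an optional source column is carried through).

    Accepted label spellings: 1/0, pos/neg, positive/negative,
    amyloid/non-amyloid, +/-.  Duplicate (sequence, label) rows are logged;
    the same sequence appearing with conflicting labels is an error.
    """
    path = Path(path)
    records: List[DatasetRecord] = []
    errors: List[str] = []
    seen: Dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "sequence", "label"} <= set(
                n.strip().lower() for n in reader.fieldnames):
            raise ValueError(
                f"{path}: header must contain columns id, sequence, label "
                f"(got {reader.fieldnames})"
            )
        for lineno, row in enumerate(reader, start=2):
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items()}
            label = _LABEL_SPELLINGS.get(row.get("label", "").lower())
            try:
                if label is None:
                    raise ValueError(f"unrecognized label {row.get('label')!r}")
                rec = DatasetRecord(id=row["id"], sequence=row["sequence"],
                                    label=label, source=row.get("source", ""))
            except (ValueError, KeyError) as exc:
                errors.append(f"{path}:{lineno}: {exc}")
                continue
            prev = seen.get(rec.sequence)
            if prev is not None:
                if prev != rec.label:
                    raise ValueError(
                        f"{path}:{lineno}: sequence {rec.sequence} appears "
                        f"with conflicting labels {prev} and {rec.label}"
                    )
                logger.info("%s:%d: duplicate (sequence, label) row %s",
                            path, lineno, rec.sequence)
            seen[rec.sequence] = rec.label
            records.append(rec)
    if errors:
        raise ValueError("malformed rows:\n" + "\n".join(errors))
    return records


def write_labeled_csv(records: Sequence[DatasetRecord],
                      path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "sequence", "label", "source"])
        for r in records:
            writer.writerow([r.id, r.sequence, r.label, r.source])


def read_fasta(path: Union[str, Path],
               permissive: bool = False) -> List[LabeledSequence]:
    """Read a (multi-)FASTA file as unlabeled sequences.

    Record ids are the first whitespace-delimited header token; wrapped
    sequence lines are concatenated.  Non-standard residues follow the
    encoding policy (strict rejection, or masked-with-warning when
    ``permissive``).
    """
    out: List[LabeledSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"{path}: empty FASTA record {rec.id!r}")
        out.append(LabeledSequence(
            id=rec.id,
            residues=encode_sequence(raw, permissive=permissive),
            label="unlabeled",
        ))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


# ---------------------------------------------------------------------------
# Embedded sup35 prion fragment fixture (printed test table)
#
# Columns: fragment position range (kept verbatim, 1-based inclusive),
# sequence, class label, printed call, printed w_s score (raw text; a few
# scores were printed with decimal commas).

SUP35_RAW: List[Tuple[str, str, str, str, str]] = [
    ("7-17", "GNNQQNYQQY", "positive", "+", "0.34"),
    ("16-26", "YSQNGNQQQG", "positive", "-", "0.08"),
    ("28-38", "RYQGYQAYNA", "positive", "+", "0.21"),
    ("43-53", "GGYYQNYQGY", "positive", "+", "0.53"),
    ("46-56", "YQNYQGYSGY", "positive", "+", "0.53"),
    ("52-62", "YSGYQQGGYQ", "positive", "+", "0.16"),
    ("55-65", "YQQGGYQQYN", "positive", "+", "0.13"),
    ("94-104", "PQGGRGNYKN", "positive", "-", "0.09"),
    ("103-113", "NFNYNNNLQG", "positive", "+", "0.22"),
    ("106-116", "YNNNLQGYQA", "positive", "+", "0.17"),
    ("109-119", "NLQGYQAGFQ", "positive", "+", "0.17"),
    ("127-137", "NDFQKQQKQA", "positive", "-", "0.11"),
    ("67-76", "AGYQQQYNPQ", "negative", "+", "0.17"),
    ("70-79", "QQQYNPQGGY", "negative", "-", "0.08"),
    ("73-82", "YNPQGGYQQY", "negative", "-", "0.06"),
    ("76-85", "QGGYQQYNPQ", "negative", "+", "0.13"),
    ("79-88", "YQQYNPQGGY", "negative", "+", "0.13"),
    ("82-91", "YNPQGGYQQQ", "negative", "-", "0.03"),
    ("139-148", "KPKKTLKLVS", "negative", "-", "0.09"),
    ("142-151", "KTLKLVSSSG", "negative", "-", "0.09"),
    ("145-154", "KLVSSSGIKL", "negative", "-", "0.12"),
    ("148-157", "SSSGIKLANA", "negative", "-", "0,12"),
    ("151-160", "GIKLANATKK", "negative", "-", "0,07"),
    ("154-163", "LANATKKVGT", "negative", "-", "0,07"),
    ("157-166", "ATKKVGTKPA", "negative", "-", "0,03"),
    ("160-169", "KVGTKPAESD", "negative", "-", "0,03"),
    ("163-172", "TKPAESDKKE", "negative", "-", "0,03"),
    ("166-175", "AESDKKEEEK", "negative", "-", "0.03"),
    ("169-178", "DKKEEEKSAE", "negative", "-", "0.03"),
    ("172-181", "EEEKSAETKE", "negative", "-", "0.03"),
    ("175-184", "KSAETKEPTK", "negative", "-", "0.06"),
    ("178-187", "ETKEPTKEPT", "negative", "-", "0.06"),
    ("181-190", "EPTKEPTKVE", "negative", "-", "0.06"),
    ("184-193", "KEPTKVEEPV", "negative", "-", "0.09"),
    ("187-196", "TKVEEPVKKE", "negative", "-", "0.09"),
    ("190-199", "EEPVKKEEKP", "negative", "-", "0.03"),
    ("193-202", "VKKEEKPVQT", "negative", "-", "0.03"),
    ("196-205", "EEKPVQTEEK", "negative", "-", "0.03"),
    ("199-208", "PVQTEEKTEE", "negative", "-", "0.11"),
    ("202-211", "TEEKTEEKSE", "negative", "-", "0.11"),
    ("205-214", "KTEEKSELPK", "negative", "-", "0.08"),
    ("208-217", "EKSELPKVED", "negative", "-", "0.08"),
    ("211-220", "ELPKVEDLKI", "negative", "-", "0.11"),
]


def sup35_fixture() -> Tuple[List[DatasetRecord], Dict[str, float], Dict[str, str]]:
    """The published sup35 fragment test set.

    Returns (records, printed_scores, printed_calls): 43 labeled 10-residue
    fragments, the published w_s score of each (decimal commas parsed to
    floats), and the published +/- call.
    """
    records, scores, calls = [], {}, {}
    for frag_id, seq, label, call, raw_score in SUP35_RAW:
        records.append(DatasetRecord(id=frag_id, sequence=seq, label=label,
                                     source="sup35"))
        scores[frag_id] = float(raw_score.replace(",", "."))
        calls[frag_id] = call
    return records, scores, calls


# ---------------------------------------------------------------------------
# Synthetic planted-motif generator

#: Default planted motif: three residue pairs at fixed relative positions
#: inside a 5-residue window; jointly they determine the Q/N-rich
#: pentapeptide QNNQY, a caricature of prion-like amyloid hot spots.
DEFAULT_MOTIF_PAIRS: List[Tuple[int, int, str, str]] = [
    (1, 3, "Q", "N"),
    (2, 4, "N", "Q"),
    (3, 5, "N", "Y"),
]


def default_motif(strength: float = 1.0) -> List[Tuple[int, int, str, str, float]]:
    """The default motif with every pair at co-occurrence probability
    ``strength``."""
    return [(p, q, a, b, strength) for p, q, a, b in DEFAULT_MOTIF_PAIRS]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-motif generator.

    ``motif`` lists (p, q, a, b, probability): residues a and b planted at
    window positions p < q of the chosen offset with the given
    co-occurrence probability (background residues where not realized).
    """

    n_pos: int = 100
    n_neg: int = 200
    length_range: Tuple[int, int] = (10, 10)
    motif: List[Tuple[int, int, str, str, float]] = field(
        default_factory=lambda: default_motif(1.0))
    motif_window_length: int = 5
    background: Optional[np.ndarray] = None  # 20 residue probabilities
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("bad length_range")
        if self.motif_window_length > lo:
            raise ValueError(
                "motif_window_length exceeds the minimum sequence length"
            )
        assignment: Dict[int, str] = {}
        for p, q, a, b, prob in self.motif:
            if not 1 <= p < q <= self.motif_window_length:
                raise ValueError(f"motif positions ({p},{q}) outside window")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("motif probabilities must be in [0,1]")
            for pos, aa in ((p, a), (q, b)):
                aa = aa.upper()
                if aa not in AA_TO_CODE:
                    raise ValueError(f"bad motif residue {aa!r}")
                if assignment.get(pos, aa) != aa:
                    raise ValueError(
                        f"inconsistent motif: position {pos} assigned both "
                        f"{assignment[pos]} and {aa}"
                    )
                assignment[pos] = aa
        self._assignment = assignment
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be 20 probabilities summing to 1")
            self.background = bg

    def induced_pairs(self) -> List[Tuple[int, int, str, str]]:
        """All residue pairs implied by the full motif assignment (the
        pattern that pattern-free backgrounds must avoid)."""
        pos = sorted(self._assignment)
        return [(p, q, self._assignment[p], self._assignment[q])
                for i, p in enumerate(pos) for q in pos[i + 1:]]


def _pattern_free(codes: np.ndarray,
                  forbidden: Sequence[Tuple[int, int, int]]) -> bool:
    """True if no forbidden (code_a, code_b, distance) occurs in ``codes``."""
    for ca, cb, d in forbidden:
        if d < codes.size and np.any((codes[:-d] == ca) & (codes[d:] == cb)):
            return False
    return True


def generate_synthetic(spec: SyntheticSpec,
                       ) -> Tuple[List[DatasetRecord], Dict[str, int]]:
    """Generate a labeled synthetic dataset with ground-truth offsets.

    Returns (records, planted_starts); ``planted_starts[id]`` is the
    1-based offset of the planted window in each positive sequence (drawn
    uniformly over admissible offsets; pairs are realized there with their
    stated probabilities).  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background if spec.background is not None else np.full(20, 0.05)
    forbidden = [(AA_TO_CODE[a], AA_TO_CODE[b], q - p)
                 for p, q, a, b in spec.induced_pairs()]

    def background_seq(length: int) -> np.ndarray:
        for _ in range(10000):
            codes = rng.choice(20, size=length, p=bg) + 1
            if _pattern_free(codes, forbidden):
                return codes
        raise RuntimeError(
            "could not sample a pattern-free background; the motif excludes "
            "too much of the sequence space"
        )

    lo, hi = spec.length_range
    records: List[DatasetRecord] = []
    planted: Dict[str, int] = {}
    for i in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        codes = background_seq(length)
        offset = int(rng.integers(0, length - spec.motif_window_length + 1))
        for p, q, a, b, prob in spec.motif:
            if rng.random() < prob:
                codes[offset + p - 1] = AA_TO_CODE[a]
                codes[offset + q - 1] = AA_TO_CODE[b]
        rec_id = f"pos{i:04d}"
        records.append(DatasetRecord(id=rec_id, sequence=decode_sequence(codes),
                                     label="positive", source="synthetic"))
        planted[rec_id] = offset + 1
    for i in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        codes = background_seq(length)
        records.append(DatasetRecord(id=f"neg{i:04d}",
                                     sequence=decode_sequence(codes),
                                     label="negative", source="synthetic"))
    return records, planted


def write_planted_starts(planted: Dict[str, int],
                         path: Union[str, Path]) -> None:
    """Sidecar TSV with the ground-truth planted offsets."""
    with open(path, "w") as fh:
        fh.write("id\tplanted_start\n")
        for rec_id, start in planted.items():
            fh.write(f"{rec_id}\t{start}\n")
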