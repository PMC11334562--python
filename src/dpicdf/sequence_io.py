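"""Protein sequence I/O, validation and synthetic dataset generation.

Sequences are restricted to the 20 canonical amino acids because every
downstream property table (CTD groupings, exchange groups, per-residue
scales) is defined only for those residues. Non-canonical letters (X, B, Z,
U, O, ...) either raise (strict default) or are dropped with a warning when
``sanitize=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical residues in alphabetical one-letter order.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

#: Residues with hydrophobic side chains, used by the default synthetic
#: positive-class composition bias.
HYDROPHOBIC_RESIDUES = "ACFILMVWY"

__all__ = [
    "CANONICAL_RESIDUES",
    "ProteinRecord",
    "LabeledDataset",
    "read_fasta",
    "write_fasta",
    "load_labeled_dataset",
    "load_labeled_dataset_tsv",
    "default_class_profiles",
    "generate_synthetic_dataset",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence with identifier and optional binary label.

    ``label`` is 1 for the druggable (positive) class, 0 for non-druggable,
    or ``None`` when unlabeled.
    """

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = [
            (i + 1, ch)
            for i, ch in enumerate(self.sequence)
            if ch not in _CANONICAL_SET
        ]
        if bad:
            pos, ch = bad[0]
            raise ValueError(
                f"record {self.id!r}: non-canonical residue {ch!r} at position {pos}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """An ordered collection of labeled records with per-class counts."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.label is None:
                raise ValueError(f"record {r.id!r} is unlabeled")

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _sanitize_sequence(rec_id: str, seq: str, sanitize: bool) -> str:
    seq = seq.upper()
    if all(ch in _CANONICAL_SET for ch in seq):
        return seq
    if not sanitize:
        pos = next(i + 1 for i, ch in enumerate(seq) if ch not in _CANONICAL_SET)
        raise ValueError(
            f"record {rec_id!r}: non-canonical residue {seq[pos - 1]!r} "
            f"at position {pos} (use sanitize=True to drop)"
        )
    cleaned = "".join(ch for ch in seq if ch in _CANONICAL_SET)
    dropped = len(seq) - len(cleaned)
    logger.warning(
        "record %r: dropped %d non-canonical residue(s)", rec_id, dropped
    )
    return cleaned


def read_fasta(path, sanitize: bool = False, label: int | None = None) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    With ``sanitize=True``, sequences are uppercased and non-canonical
    residues removed with a logged warning; otherwise any non-canonical
    residue raises, naming the record and the 1-based position.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        if not seq:
            raise ValueError(f"record {entry.id!r}: empty sequence in {path}")
        records.append(
            ProteinRecord(entry.id, _sanitize_sequence(entry.id, seq, sanitize), label)
        )
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_fasta(records, path) -> None:
    """Write records to FASTA (identity partner of :func:`read_fasta`)."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def load_labeled_dataset(pos_path, neg_path, sanitize: bool = False) -> LabeledDataset:
    """Load a two-class dataset from paired FASTA files (positives, negatives)."""
    pos = read_fasta(pos_path, sanitize=sanitize, label=1)
    neg = read_fasta(neg_path, sanitize=sanitize, label=0)
    dup = {r.id for r in pos} & {r.id for r in neg}
    if dup:
        raise ValueError(f"identifier(s) present in both classes: {sorted(dup)}")
    return LabeledDataset(pos + neg)


def load_labeled_dataset_tsv(fasta_path, labels_path, sanitize: bool = False) -> LabeledDataset:
    """Load a dataset from one FASTA plus a two-column ``id<TAB>label`` TSV."""
    records = read_fasta(fasta_path, sanitize=sanitize)
    labels: dict[str, int] = {}
    with open(labels_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{labels_path}: line {lineno}: expected id<TAB>label")
            rec_id, label = parts[0].strip(), parts[1].strip()
            if label not in ("0", "1"):
                raise ValueError(f"{labels_path}: line {lineno}: label must be 0 or 1")
            if rec_id in labels:
                raise ValueError(f"{labels_path}: duplicate id {rec_id!r}")
            labels[rec_id] = int(label)
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise ValueError(f"no label for record(s): {missing}")
    return LabeledDataset(
        [ProteinRecord(r.id, r.sequence, labels[r.id]) for r in records]
    )


def default_class_profiles() -> dict[int, np.ndarray]:
    """Per-class residue probability profiles for the synthetic generator.

    Negatives draw residues uniformly; positives are enriched 2:1 in
    hydrophobic residues, a coarse emulation of the compositional bias that
    separates druggable from non-druggable sequences.
    """
    uniform = np.full(20, 1 / 20)
    weights = np.array(
        [2.0 if r in HYDROPHOBIC_RESIDUES else 1.0 for r in CANONICAL_RESIDUES]
    )
    return {1: weights / weights.sum(), 0: uniform}


def _check_profile(profile: np.ndarray, cls: int) -> np.ndarray:
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (20,):
        raise ValueError(f"class {cls} profile must have 20 entries")
    if abs(profile.sum() - 1.0) > 1e-9:
        raise ValueError(f"class {cls} profile does not sum to 1 (got {profile.sum()!r})")
    return profile


def generate_synthetic_dataset(
    n_pos: int,
    n_neg: int,
    length_range: tuple[int, int] = (50, 300),
    class_bias: dict[int, np.ndarray] | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Generate a reproducible two-class synthetic dataset.

    Residues are drawn i.i.d. from the per-class profile; lengths are
    uniform on ``length_range`` (inclusive). Deterministic for a fixed seed.
    """
    lo, hi = length_range
    if lo < 8:
        raise ValueError("minimum synthetic length is 8")
    if hi < lo:
        raise ValueError("length_range must satisfy min <= max")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    profiles = class_bias if class_bias is not None else default_class_profiles()
    profiles = {cls: _check_profile(p, cls) for cls, p in profiles.items()}
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(CANONICAL_RESIDUES))
    records = []
    for cls, count, prefix in ((1, n_pos, "pos"), (0, n_neg, "neg")):
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(alphabet, size=length, p=profiles[cls]))
            records.append(ProteinRecord(f"{prefix}_{i:04d}", seq, cls))
    return LabeledDataset(records)
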