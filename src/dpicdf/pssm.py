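"""PSI-BLAST ASCII PSSM parsing, logistic normalization, and synthesis.

A position-specific scoring matrix (PSSM) is an L x 20 profile of log-odds
conservation scores produced by iterative database search. The encoder
pipeline consumes the logistic-squashed view ``f(a) = 1 / (1 + exp(-a))``,
which maps each raw log-odds score into (0, 1).

Running PSI-BLAST itself is out of scope here; :func:`synthesize_pssm`
produces a sequence-consistent stand-in profile so the full pipeline is
testable without a Swiss-Prot search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .sequence_io import ProteinRecord

#: Amino-acid column order of PSI-BLAST ``-out_ascii_pssm`` output.
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"
_COL_INDEX = {aa: i for i, aa in enumerate(PSIBLAST_COLUMN_ORDER)}

__all__ = [
    "PSIBLAST_COLUMN_ORDER",
    "PSSMatrix",
    "normalize_pssm",
    "parse_ascii_pssm",
    "write_ascii_pssm",
    "synthesize_pssm",
]


def normalize_pssm(raw: np.ndarray) -> np.ndarray:
    """Element-wise logistic squashing of raw log-odds scores.

    Strictly increasing in the raw score; output lies in (0, 1).
    Raises on non-finite input.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("PSSM contains non-finite entries")
    return expit(raw)


@dataclass
class PSSMatrix:
    """An L x 20 evolutionary profile with raw and normalized views."""

    record_id: str
    raw: np.ndarray
    sequence: str | None = None
    column_order: str = PSIBLAST_COLUMN_ORDER

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[1] != 20:
            raise ValueError(f"raw PSSM must be L x 20, got {self.raw.shape}")
        if self.sequence is not None and len(self.sequence) != self.raw.shape[0]:
            raise ValueError("sequence length does not match PSSM row count")

    @property
    def length(self) -> int:
        return int(self.raw.shape[0])

    @property
    def normalized(self) -> np.ndarray:
        return normalize_pssm(self.raw)

    def validate_against(self, record: ProteinRecord) -> None:
        """Check the retained residue column against a FASTA sequence."""
        if self.sequence is None:
            raise ValueError("PSSM carries no residue column to validate")
        if self.sequence != record.sequence:
            for i, (a, b) in enumerate(zip(self.sequence, record.sequence)):
                if a != b:
                    raise ValueError(
                        f"PSSM residue column disagrees with sequence "
                        f"{record.id!r} at position {i + 1}: {a!r} != {b!r}"
                    )
            raise ValueError(
                f"PSSM row count {self.length} != sequence length {record.length} "
                f"for {record.id!r}"
            )


def parse_ascii_pssm(path) -> PSSMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Of the two 20-column numeric blocks per row, the first (log-odds) is
    returned as ``raw``; the residue column is retained for cross-checking
    against the FASTA sequence. Rows with a malformed field count raise with
    the offending line number.
    """
    raw_rows: list[list[float]] = []
    residues: list[str] = []
    record_id = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            # residue rows start with "<position> <letter>"
            if (
                len(fields) < 2
                or not fields[0].isdigit()
                or len(fields[1]) != 1
                or not fields[1].isalpha()
            ):
                continue  # header / footer / blank
            if len(fields) < 42:
                raise ValueError(
                    f"{path}: line {lineno}: expected 40 numeric fields per "
                    f"residue row, found {len(fields) - 2}"
                )
            residue = fields[1]
            try:
                scores = [float(x) for x in fields[2:22]]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            residues.append(residue)
            raw_rows.append(scores)
    if not raw_rows:
        raise ValueError(f"{path}: no PSSM rows found (truncated or not a PSSM)")
    return PSSMatrix(record_id, np.array(raw_rows), sequence="".join(residues))


def write_ascii_pssm(pssm: PSSMatrix, path) -> None:
    """Write the per-row numeric table in the PSI-BLAST ASCII dialect.

    Headers are regenerated minimally; the percentage block is zero-filled
    (it is never consumed). ``parse_ascii_pssm(write_ascii_pssm(M)) == M``
    exactly for integer matrices.
    """
    seq = pssm.sequence or "X" * pssm.length
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        cols = " ".join(f"{aa:>3}" for aa in pssm.column_order)
        fh.write(f"          {cols}  {cols}\n")
        for i, row in enumerate(pssm.raw, start=1):
            scores = " ".join(f"{int(round(v)):>3d}" for v in row)
            pct = " ".join(f"{0:>3d}" for _ in row)
            fh.write(f"{i:>5d} {seq[i - 1]}  {scores}  {pct}  0.00 0.00\n")


def synthesize_pssm(
    record: ProteinRecord,
    sharpness: float = 8.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PSSMatrix:
    """Generate a sequence-consistent synthetic profile for ``record``.

    Row ``i`` receives an elevated score ``+sharpness`` at the column of
    residue ``i``, plus zero-mean rounded-Gaussian integer noise of standard
    deviation ``noise_sd`` in every column, so the profile reflects the
    sequence the way a conservation profile of a non-divergent family would.
    Deterministic for a fixed seed.
    """
    if sharpness < 0:
        raise ValueError("sharpness must be >= 0")
    rng = np.random.default_rng(seed)
    raw = np.zeros((record.length, 20))
    if noise_sd > 0:
        raw += np.round(rng.normal(0.0, noise_sd, size=raw.shape))
    for i, residue in enumerate(record.sequence):
        raw[i, _COL_INDEX[residue]] += sharpness
    return PSSMatrix(record.id, raw, sequence=record.sequence)


def synthesize_pssms(dataset, sharpness: float = 8.0, noise_sd: float = 1.0,
                     seed: int = 0) -> dict[str, PSSMatrix]:
    """Synthesize one PSSM per record with per-record derived seeds."""
    base = np.random.SeedSequence(seed)
    children = base.spawn(len(list(dataset)))
    return {
        r.id: synthesize_pssm(
            r, sharpness, noise_sd, seed=int(child.generate_state(1)[0] % (2**31 - 1))
        )
        for r, child in zip(dataset, children)
    }
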