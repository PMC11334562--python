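"""Composite protein sequence representation (CPSR), 71-D.

Block layout (in order):

====================================  ====
amino-acid composition                  20
sequence length L                        1
2-gram exchange-group frequencies       36
electron-group frequencies               6
rigidity (mean per-residue scale)        1
flexibility                              1
irreplaceability                         1
R-group frequencies                      5
====================================  ====

Exchange groups are the six Dayhoff-style substitutability clusters;
bigrams over the 6-letter exchange alphabet are ordered (e1e2 != e2e1),
giving exactly 36 features normalized by the L - 1 adjacent pairs.
Electron-group and R-group blocks are length-normalized frequencies by
default (raw counts via ``count_mode="count"``). The three scalar indices
are sequence means of shipped per-residue scales. The raw length feature is
z-scored later with the rest of the matrix.
"""

from __future__ import annotations

import numpy as np

from ._tables import cpsr_groupings, cpsr_scales
from .features import Block, FeatureVector
from .sequence_io import CANONICAL_RESIDUES, ProteinRecord

__all__ = [
    "aac",
    "exchange_bigram_frequencies",
    "group_frequencies",
    "scalar_indices",
    "encode_cpsr",
    "CPSR_DIM",
]

CPSR_DIM = 71


def aac(record: ProteinRecord) -> np.ndarray:
    """Amino-acid composition: residue counts / L, alphabetical order."""
    counts = np.array([record.sequence.count(r) for r in CANONICAL_RESIDUES])
    return counts / record.length


def exchange_bigram_frequencies(record: ProteinRecord,
                                groups: dict | None = None) -> np.ndarray:
    """Ordered bigram frequencies over the 6-letter exchange alphabet.

    36 values in the order (e1e1, e1e2, ..., e6e6), each the count of that
    overlapping bigram divided by L - 1.
    """
    groups = groups if groups is not None else cpsr_groupings()["exchange"]
    if record.length < 2:
        raise ValueError("exchange bigrams require length >= 2")
    labels = np.array([groups[r] - 1 for r in record.sequence])
    idx = labels[:-1] * 6 + labels[1:]
    return np.bincount(idx, minlength=36) / (record.length - 1)


def group_frequencies(record: ProteinRecord, groups: dict, n_classes: int,
                      count_mode: str = "frequency") -> np.ndarray:
    """Per-class residue counts, optionally length-normalized."""
    labels = np.array([groups[r] - 1 for r in record.sequence])
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    if count_mode == "frequency":
        counts /= record.length
    elif count_mode != "count":
        raise ValueError(f"unknown count_mode {count_mode!r}")
    return counts


def scalar_indices(record: ProteinRecord,
                   scales: dict | None = None) -> tuple[float, float, float]:
    """(rigidity, flexibility, irreplaceability): per-residue sums / L."""
    scales = scales if scales is not None else cpsr_scales()
    out = []
    for name in ("rigidity", "flexibility", "irreplaceability"):
        table = scales[name]
        out.append(sum(table[r] for r in record.sequence) / record.length)
    return tuple(out)


def encode_cpsr(record: ProteinRecord, count_mode: str = "frequency") -> FeatureVector:
    """The full 71-D composite representation of one record."""
    if record.length < 2:
        raise ValueError("CPSR requires length >= 2")
    groups = cpsr_groupings()
    rigidity, flexibility, irreplaceability = scalar_indices(record)
    parts = [
        ("aac", aac(record)),
        ("length", np.array([float(record.length)])),
        ("exchange_bigrams", exchange_bigram_frequencies(record, groups["exchange"])),
        ("electron", group_frequencies(record, groups["electron"], 6, count_mode)),
        ("rigidity", np.array([rigidity])),
        ("flexibility", np.array([flexibility])),
        ("irreplaceability", np.array([irreplaceability])),
        ("r_group", group_frequencies(record, groups["r_group"], 5, count_mode)),
    ]
    values = np.concatenate([v for _, v in parts])
    blocks, idx = [], 0
    for name, v in parts:
        blocks.append(Block(name, idx, idx + v.size))
        idx += v.size
    return FeatureVector(record.id, values, blocks, tag="CPSR")
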