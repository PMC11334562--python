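"""Composition-transition-distribution (CTD) descriptor, 147-D.

Seven physicochemical attributes (hydrophobicity, normalized van der Waals
volume, polarity, polarizability, charge, secondary-structure propensity,
solvent accessibility) each partition the 20 residues into three groups.
For each attribute the sequence is recoded as a string over {1, 2, 3} and
three index families are computed:

* **C** (composition): the fraction of residues in each group — 3 values.
* **T** (transition): the fraction of adjacent residue pairs whose two
  members fall in two *different* groups, per unordered pair — 3 values.
* **D** (distribution): for each group, the positions (as percent of the
  sequence length) at which the first occurrence and 25%, 50%, 75% and
  100% of that group's occurrences are reached — 15 values.

21 values per property x 7 properties = 147. Descriptor values depend only
on the group strings, so residue substitutions within a group leave the
vector unchanged.

Feature matrices are standardized column-wise with a z-score fitted on
training data (train-fit, test-apply); a min-max [0, 1] mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._tables import ctd_groupings
from .features import Block, FeatureVector
from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

#: Unordered group pairs, in reporting order.
TRANSITION_PAIRS = ((1, 2), (1, 3), (2, 3))
#: Distribution landmarks: first occurrence, then quartile completion points.
LANDMARKS = ("first", "q25", "q50", "q75", "q100")

__all__ = [
    "PropertyGrouping",
    "default_groupings",
    "map_to_groups",
    "ctd_indices",
    "encode_nqlc",
    "StandardizationParams",
    "fit_standardization",
    "standardize",
]


@dataclass(frozen=True)
class PropertyGrouping:
    """A three-group partition of the 20 residues for one attribute."""

    property_name: str
    groups: dict  # residue -> 1 | 2 | 3

    def __post_init__(self) -> None:
        labels = set(self.groups.values())
        if not labels <= {1, 2, 3}:
            raise ValueError(f"{self.property_name}: group labels must be 1..3")


def default_groupings() -> list[PropertyGrouping]:
    """The seven shipped attribute partitions, in canonical order."""
    return [PropertyGrouping(name, mapping) for name, mapping in ctd_groupings().items()]


def map_to_groups(sequence: str, grouping: PropertyGrouping) -> str:
    """Recode a sequence as its group-label string over {1, 2, 3}."""
    try:
        return "".join(str(grouping.groups[r]) for r in sequence)
    except KeyError as exc:
        raise ValueError(
            f"residue {exc.args[0]!r} absent from grouping "
            f"{grouping.property_name!r}"
        ) from exc


def ctd_indices(group_string: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """C (3), T (3) and D (15) indices of a group-label string.

    D landmarks of a group absent from the sequence are all zero.
    """
    L = len(group_string)
    if L < 2:
        raise ValueError("group string must have length >= 2")
    labels = np.frombuffer(group_string.encode(), dtype=np.uint8) - ord("0")

    C = np.array([(labels == g).sum() / L for g in (1, 2, 3)])

    pairs = np.stack([labels[:-1], labels[1:]], axis=1)
    T = np.empty(3)
    for k, (g, h) in enumerate(TRANSITION_PAIRS):
        crossing = ((pairs[:, 0] == g) & (pairs[:, 1] == h)) | (
            (pairs[:, 0] == h) & (pairs[:, 1] == g)
        )
        T[k] = crossing.sum() / (L - 1)

    D = np.zeros((3, 5))
    for gi, g in enumerate((1, 2, 3)):
        positions = np.flatnonzero(labels == g) + 1  # 1-based
        n_g = positions.size
        if n_g == 0:
            continue
        D[gi, 0] = positions[0] / L * 100.0
        for qi, q in enumerate((0.25, 0.5, 0.75, 1.0), start=1):
            k = max(1, int(np.ceil(q * n_g)))
            D[gi, qi] = positions[k - 1] / L * 100.0
    return C, T, D.ravel()


def encode_nqlc(
    record: ProteinRecord, groupings: list[PropertyGrouping] | None = None
) -> FeatureVector:
    """147-D CTD vector: per property, C(3) then T(3) then D(15)."""
    groupings = groupings if groupings is not None else default_groupings()
    parts, blocks, idx = [], [], 0
    for grouping in groupings:
        C, T, D = ctd_indices(map_to_groups(record.sequence, grouping))
        sub = np.concatenate([C, T, D])
        parts.append(sub)
        blocks.append(Block(grouping.property_name, idx, idx + sub.size))
        idx += sub.size
    return FeatureVector(record.id, np.concatenate(parts), blocks, tag="NQLC")


@dataclass
class StandardizationParams:
    """Column means/stds fitted on training data; constant columns flagged."""

    mean: np.ndarray
    std: np.ndarray
    constant: np.ndarray  # boolean mask of zero-variance columns
    mode: str = "zscore"


def fit_standardization(X: np.ndarray, mode: str = "zscore") -> StandardizationParams:
    """Fit per-column standardization parameters.

    ``zscore`` uses the sample standard deviation (denominator n - 1);
    ``minmax`` stores min as mean and range as std. Zero-variance columns
    are flagged and later mapped to 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardization requires a 2-D matrix with >= 2 rows")
    if mode == "zscore":
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=1)
    elif mode == "minmax":
        mean = X.min(axis=0)
        std = X.max(axis=0) - mean
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    constant = std == 0
    if constant.any():
        logger.warning(
            "%d constant feature column(s) flagged; their standardized "
            "values are set to 0", int(constant.sum()),
        )
    return StandardizationParams(mean, std, constant, mode)


def standardize(X: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Apply fitted standardization: y = (x - mean) / std, 0 where std = 0."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.mean.size:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, params expect {params.mean.size}"
        )
    safe = np.where(params.constant, 1.0, params.std)
    Y = (X - params.mean) / safe
    Y[:, params.constant] = 0.0
    return Y
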