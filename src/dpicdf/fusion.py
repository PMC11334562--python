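"""Serial feature fusion and dataset-level feature matrices.

The three encoders are fused by plain concatenation in a fixed order
(CPSR, NQLC, HOG-PSSM):

* ``Hybrid1`` = CPSR (71) + HOG-PSSM (256) = 327
* ``Hybrid2`` = NQLC (147) + HOG-PSSM (256) = 403
* ``Hybrid3`` = CPSR (71) + NQLC (147) + HOG-PSSM (256) = 474

Tree ensembles are order-invariant, but the fixed order keeps schemas and
feature-attribution audits reproducible. Block provenance is preserved so
slicing a hybrid matrix recovers the single-view matrices exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpsr import encode_cpsr
from .features import Block, FeatureVector
from .hog import HOGConfig, encode_hog
from .nqlc import StandardizationParams, encode_nqlc, fit_standardization, standardize
from .sequence_io import LabeledDataset

#: Canonical encoder tags and their hybrid compositions.
HYBRID_PARTS = {
    "hybrid1": ("cpsr", "hog"),
    "hybrid2": ("nqlc", "hog"),
    "hybrid3": ("cpsr", "nqlc", "hog"),
}
_HYBRID_TAGS = {
    ("CPSR", "HOG-PSSM"): "Hybrid1",
    ("NQLC", "HOG-PSSM"): "Hybrid2",
    ("CPSR", "NQLC", "HOG-PSSM"): "Hybrid3",
}

__all__ = ["HYBRID_PARTS", "hybridize", "FeatureMatrix", "build_feature_matrix"]


def hybridize(parts: list[FeatureVector]) -> FeatureVector:
    """Serial concatenation of encodings of the same record.

    Block names are prefixed with the source encoder tag; the result's tag
    is Hybrid1/2/3 when the part combination matches one of the named
    fusions, otherwise the '+'-joined part tags.
    """
    if not parts:
        raise ValueError("nothing to hybridize")
    ids = {p.record_id for p in parts}
    if len(ids) > 1:
        raise ValueError(f"parts encode different records: {sorted(ids)}")
    values = np.concatenate([p.values for p in parts])
    blocks, offset = [], 0
    for p in parts:
        for b in p.blocks:
            blocks.append(Block(f"{p.tag}.{b.name}", offset + b.start, offset + b.stop))
        offset += p.dim
    tag = _HYBRID_TAGS.get(tuple(p.tag for p in parts), "+".join(p.tag for p in parts))
    return FeatureVector(parts[0].record_id, values, blocks, tag=tag)


@dataclass
class FeatureMatrix:
    """Per-record feature vectors stacked into an n x d matrix."""

    X: np.ndarray
    labels: np.ndarray
    ids: list[str]
    blocks: list[Block]
    tag: str
    standardization: StandardizationParams | None = field(default=None)

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.labels.size or self.X.shape[0] != len(self.ids):
            raise ValueError("rows, labels and ids must align 1:1")

    @property
    def n(self) -> int:
        return int(self.X.shape[0])

    @property
    def dim(self) -> int:
        return int(self.X.shape[1])

    def block_matrix(self, prefix: str) -> np.ndarray:
        """Columns of all blocks whose name starts with ``prefix``."""
        cols = [b for b in self.blocks if b.name.startswith(prefix)]
        if not cols:
            raise KeyError(prefix)
        return np.hstack([self.X[:, b.start : b.stop] for b in cols])

    def to_frame(self) -> pd.DataFrame:
        names = []
        for b in self.blocks:
            names.extend(f"{b.name}.{i}" for i in range(b.size))
        return pd.DataFrame(self.X, index=self.ids, columns=names)


def _encode_record(record, tag: str, pssms, hog_config: HOGConfig) -> FeatureVector:
    if tag in ("cpsr", "nqlc"):
        return encode_cpsr(record) if tag == "cpsr" else encode_nqlc(record)
    if tag == "hog":
        return encode_hog(pssms[record.id].normalized, hog_config, record.id)
    parts = [_encode_record(record, p, pssms, hog_config) for p in HYBRID_PARTS[tag]]
    return hybridize(parts)


def build_feature_matrix(
    dataset: LabeledDataset,
    pssms: dict | None = None,
    encoder_tag: str = "hybrid3",
    hog_config: HOGConfig | None = None,
    standardization: str | StandardizationParams | None = None,
) -> FeatureMatrix:
    """Encode every record of a dataset into a feature matrix.

    ``standardization``: ``None`` (raw), ``"fit"`` (training mode — fit a
    z-score on this matrix and apply it), or fitted
    :class:`StandardizationParams` (inference mode — apply stored
    parameters). Requesting inference-mode behaviour without stored
    parameters is an error by construction.
    """
    tag = encoder_tag.lower()
    valid = {"cpsr", "nqlc", "hog", *HYBRID_PARTS}
    if tag not in valid:
        raise ValueError(f"unknown encoder tag {encoder_tag!r}; expected one of {sorted(valid)}")
    needs_pssm = tag == "hog" or "hog" in HYBRID_PARTS.get(tag, ())
    if needs_pssm:
        if pssms is None:
            raise ValueError(f"encoder {encoder_tag!r} requires PSSMs")
        missing = [r.id for r in dataset if r.id not in pssms]
        if missing:
            raise ValueError(f"missing PSSM for record(s): {missing}")
    hog_config = hog_config or HOGConfig()

    vectors = [_encode_record(r, tag, pssms, hog_config) for r in dataset]
    dims = {v.dim for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"inconsistent row dimensions: {sorted(dims)}")
    X = np.vstack([v.values for v in vectors])

    params = None
    if standardization == "fit":
        params = fit_standardization(X)
        X = standardize(X, params)
    elif isinstance(standardization, StandardizationParams):
        params = standardization
        X = standardize(X, params)
    elif standardization is not None:
        raise ValueError(
            "standardization must be None, 'fit', or fitted StandardizationParams"
        )

    return FeatureMatrix(
        X, dataset.labels, [r.id for r in dataset], vectors[0].blocks,
        vectors[0].tag, params,
    )
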