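"""Named fixed-length feature vectors shared by all encoders.

Every encoder (CPSR, NQLC, HOG-PSSM) and every hybrid fusion emits a
:class:`FeatureVector`: a flat float array plus a block schema that records
which contiguous slice came from which named feature family. The schema is
what makes hybrid matrices auditable — slicing a hybrid by its blocks
recovers the single-view encodings exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Block", "FeatureVector"]


@dataclass(frozen=True)
class Block:
    """A named contiguous slice ``[start, stop)`` of a feature vector."""

    name: str
    start: int
    stop: int

    @property
    def size(self) -> int:
        return self.stop - self.start


@dataclass
class FeatureVector:
    """Fixed-length numeric encoding of one protein record.

    Parameters
    ----------
    record_id:
        Identifier of the protein the vector encodes.
    values:
        1-D float array.
    blocks:
        Ordered, non-overlapping blocks tiling ``values`` exactly.
    tag:
        Encoder provenance, e.g. ``"CPSR"``, ``"HOG-PSSM"``, ``"Hybrid3"``.
    """

    record_id: str
    values: np.ndarray
    blocks: list[Block] = field(default_factory=list)
    tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.blocks:
            self.blocks = [Block(self.tag or "all", 0, self.values.size)]
        if self.blocks[0].start != 0 or self.blocks[-1].stop != self.values.size:
            raise ValueError("blocks do not tile the value array")
        for prev, cur in zip(self.blocks, self.blocks[1:]):
            if cur.start != prev.stop:
                raise ValueError(
                    f"blocks {prev.name!r} and {cur.name!r} are not contiguous"
                )

    @property
    def dim(self) -> int:
        return int(self.values.size)

    def block(self, name: str) -> np.ndarray:
        """Return the values of the named block."""
        for b in self.blocks:
            if b.name == name:
                return self.values[b.start : b.stop]
        raise KeyError(name)

    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]
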