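"""Histogram-of-oriented-gradients descriptor over a normalized PSSM.

The logistic-normalized L x 20 profile is treated as a grayscale image:
gradients are taken along both axes, each position gets a gradient magnitude
and direction, the matrix is tiled into a grid of cells, and each cell
contributes a magnitude-weighted orientation histogram. With the default
4 x 4 grid and 16 orientation bins the descriptor is 256-D.

Axis convention (mirrors the profile's construction): index ``i`` runs over
the 20 amino-acid columns, index ``j`` over the L sequence positions. ``Gx``
differentiates along the amino-acid axis, ``Gy`` along the sequence axis.
Boundary rows/columns use one-sided differences against an implicit zero
border: at the first index the gradient is ``P(next) - 0``, at the last it
is ``0 - P(prev)``. The direction is the two-argument arctangent of
``(Gx, Gy)`` — the angle whose tangent is Gx/Gy, well-defined when Gy = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import Block, FeatureVector

__all__ = ["HOGConfig", "GradientField", "compute_gradients",
           "partition_cells", "encode_field", "encode_hog"]


@dataclass(frozen=True)
class HOGConfig:
    """Cell-grid and binning configuration.

    ``n_cell_rows`` blocks along the 20 amino-acid columns,
    ``n_cell_cols`` blocks along the sequence, ``n_bins`` orientation bins
    per cell; output dimension = rows x cols x bins (default 4*4*16 = 256).
    ``epsilon`` is the floor below which a cell's histogram norm counts as
    zero (the cell then stays all-zero instead of being normalized).
    """

    n_cell_rows: int = 4
    n_cell_cols: int = 4
    n_bins: int = 16
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if min(self.n_cell_rows, self.n_cell_cols, self.n_bins) < 1:
            raise ValueError("grid and bin counts must be >= 1")

    @property
    def dim(self) -> int:
        return self.n_cell_rows * self.n_cell_cols * self.n_bins

    @property
    def min_length(self) -> int:
        return 2 * self.n_cell_cols


@dataclass
class GradientField:
    """Per-position gradients of an L x 20 profile."""

    Gx: np.ndarray  # gradient along the 20 amino-acid columns
    Gy: np.ndarray  # gradient along the sequence positions
    G: np.ndarray   # magnitude sqrt(Gx^2 + Gy^2)
    Theta: np.ndarray  # direction atan2(Gx, Gy), in (-pi, pi]


def compute_gradients(P: np.ndarray) -> GradientField:
    """Gradient magnitude and direction of a normalized profile.

    Central differences in the interior; one-sided differences against a
    zero border at the first/last index of each axis.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] != 20:
        raise ValueError(f"expected an L x 20 matrix, got {P.shape}")
    L = P.shape[0]
    if L < 2:
        raise ValueError("profile must have at least 2 rows")

    Gx = np.empty_like(P)
    Gx[:, 0] = P[:, 1]               # P(i+1) - 0
    Gx[:, 1:-1] = P[:, 2:] - P[:, :-2]
    Gx[:, -1] = -P[:, -2]            # 0 - P(i-1)

    Gy = np.empty_like(P)
    Gy[0, :] = P[1, :]
    Gy[1:-1, :] = P[2:, :] - P[:-2, :]
    Gy[-1, :] = -P[-2, :]

    return GradientField(Gx, Gy, np.hypot(Gx, Gy), np.arctan2(Gx, Gy))


def _axis_blocks(n: int, n_blocks: int) -> list[slice]:
    """Contiguous equal blocks of size n // n_blocks, remainder to the last."""
    size = n // n_blocks
    starts = [b * size for b in range(n_blocks)]
    stops = starts[1:] + [n]
    return [slice(a, b) for a, b in zip(starts, stops)]


def partition_cells(field: GradientField, cfg: HOGConfig | None = None):
    """Tile the gradient field into a grid of (magnitude, direction) cells.

    The 20 columns split into ``n_cell_rows`` contiguous blocks; the L
    positions split into ``n_cell_cols`` blocks of floor(L / n_cell_cols),
    the final block absorbing any remainder. Cells are yielded row-major:
    amino-acid blocks outer, sequence blocks inner. The tiling is exact —
    no overlap, no omission.
    """
    cfg = cfg or HOGConfig()
    L = field.G.shape[0]
    if L < cfg.min_length:
        raise ValueError(
            f"sequence length {L} below minimum {cfg.min_length} "
            f"for a {cfg.n_cell_rows}x{cfg.n_cell_cols} cell grid"
        )
    aa_blocks = _axis_blocks(20, cfg.n_cell_rows)
    seq_blocks = _axis_blocks(L, cfg.n_cell_cols)
    cells = []
    for aa in aa_blocks:
        for sq in seq_blocks:
            cells.append((field.G[sq, aa], field.Theta[sq, aa]))
    return cells


def _orientation_bins(theta: np.ndarray, n_bins: int) -> np.ndarray:
    # left-closed equal bins over [-pi, pi) with +pi folded into the last bin
    width = 2.0 * np.pi / n_bins
    k = np.floor((theta + np.pi) / width).astype(int)
    return np.clip(k, 0, n_bins - 1)


def encode_field(field: GradientField, cfg: HOGConfig | None = None,
                 record_id: str = "") -> FeatureVector:
    """Per-cell magnitude-weighted orientation histograms, concatenated.

    Each cell's ``n_bins`` histogram is L2-normalized; a cell whose
    magnitudes are all (numerically) zero stays all-zero.
    """
    cfg = cfg or HOGConfig()
    hists = []
    for G, theta in partition_cells(field, cfg):
        bins = _orientation_bins(theta.ravel(), cfg.n_bins)
        h = np.bincount(bins, weights=G.ravel(), minlength=cfg.n_bins)
        nrm = np.linalg.norm(h)
        hists.append(h / nrm if nrm > cfg.epsilon else np.zeros(cfg.n_bins))
    values = np.concatenate(hists)
    blocks = []
    idx = 0
    for m in range(cfg.n_cell_rows):
        for n in range(cfg.n_cell_cols):
            blocks.append(Block(f"cell_{m}{n}", idx, idx + cfg.n_bins))
            idx += cfg.n_bins
    return FeatureVector(record_id, values, blocks, tag="HOG-PSSM")


def encode_hog(P: np.ndarray, cfg: HOGConfig | None = None,
               record_id: str = "") -> FeatureVector:
    """Full HOG descriptor of a normalized L x 20 profile."""
    return encode_field(compute_gradients(P), cfg, record_id)
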