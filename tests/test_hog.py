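import math

import numpy as np
import pytest

from dpicdf.hog import (
    GradientField,
    HOGConfig,
    compute_gradients,
    encode_field,
    encode_hog,
    partition_cells,
)


def naive_hog(P, n_cell_rows=4, n_cell_cols=4, n_bins=16, epsilon=1e-12):
    """Independent brute-force descriptor: plain loops, no vectorization."""
    L = len(P)
    Gx = [[0.0] * 20 for _ in range(L)]
    Gy = [[0.0] * 20 for _ in range(L)]
    for j in range(L):
        for i in range(20):
            if i == 0:
                Gx[j][i] = P[j][i + 1]
            elif i == 19:
                Gx[j][i] = -P[j][i - 1]
            else:
                Gx[j][i] = P[j][i + 1] - P[j][i - 1]
            if j == 0:
                Gy[j][i] = P[j + 1][i]
            elif j == L - 1:
                Gy[j][i] = -P[j - 1][i]
            else:
                Gy[j][i] = P[j + 1][i] - P[j - 1][i]

    aa_size = 20 // n_cell_rows
    seq_size = L // n_cell_cols
    width = 2.0 * math.pi / n_bins
    out = []
    for m in range(n_cell_rows):
        aa_lo = m * aa_size
        aa_hi = 20 if m == n_cell_rows - 1 else (m + 1) * aa_size
        for n in range(n_cell_cols):
            sq_lo = n * seq_size
            sq_hi = L if n == n_cell_cols - 1 else (n + 1) * seq_size
            hist = [0.0] * n_bins
            for j in range(sq_lo, sq_hi):
                for i in range(aa_lo, aa_hi):
                    g = math.hypot(Gx[j][i], Gy[j][i])
                    theta = math.atan2(Gx[j][i], Gy[j][i])
                    k = int(math.floor((theta + math.pi) / width))
                    k = min(max(k, 0), n_bins - 1)
                    hist[k] += g
            nrm = math.sqrt(sum(h * h for h in hist))
            if nrm > epsilon:
                hist = [h / nrm for h in hist]
            else:
                hist = [0.0] * n_bins
            out.extend(hist)
    return np.array(out)


class TestGradients:
    def test_constant_matrix_boundary_rule(self):
        # the "- 0" border rule forces +-c at the first/last amino-acid column
        P = np.full((10, 20), 0.3)
        f = compute_gradients(P)
        assert np.allclose(f.Gx[:, 1:-1], 0) and np.allclose(f.Gy[1:-1, :], 0)
        assert np.allclose(f.Gx[:, 0], 0.3) and np.allclose(f.Gx[:, -1], -0.3)
        assert np.allclose(f.Gy[0, :], 0.3) and np.allclose(f.Gy[-1, :], -0.3)

    def test_column_ramp_has_known_interior_geometry(self):
        # P(i, j) = i: central difference 2 along the columns, pointing +pi/2
        P = np.tile(np.arange(1.0, 21.0), (6, 1))
        f = compute_gradients(P)
        interior = np.s_[1:-1, 1:-1]
        assert np.allclose(f.Gx[interior], 2.0)
        assert np.allclose(f.Gy[interior], 0.0)
        assert np.allclose(f.G[interior], 2.0)
        assert np.allclose(f.Theta[interior], np.pi / 2)

    def test_magnitude_dominates_components(self):
        P = np.random.default_rng(4).random((30, 20))
        f = compute_gradients(P)
        assert np.all(f.G >= np.abs(f.Gx) - 1e-15)
        assert np.all(f.G >= np.abs(f.Gy) - 1e-15)
        assert np.all((f.Theta > -np.pi - 1e-15) & (f.Theta <= np.pi + 1e-15))

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_gradients(np.zeros((1, 20)))


class TestPartition:
    def test_exact_division(self):
        f = compute_gradients(np.random.default_rng(0).random((100, 20)))
        cells = partition_cells(f, HOGConfig())
        assert len(cells) == 16
        assert all(c[0].shape == (25, 5) for c in cells)

    def test_remainder_goes_to_last_sequence_block(self):
        f = compute_gradients(np.random.default_rng(0).random((103, 20)))
        shapes = [c[0].shape[0] for c in partition_cells(f, HOGConfig())]
        assert shapes[:3] == [25, 25, 25] and shapes[3] == 28

    def test_cells_tile_without_overlap(self):
        L = 37
        f = compute_gradients(np.arange(L * 20, dtype=float).reshape(L, 20))
        seen = np.concatenate([c[0].ravel() for c in partition_cells(f, HOGConfig())])
        assert sorted(seen.tolist()) == sorted(f.G.ravel().tolist())

    def test_too_short_names_minimum(self):
        f = compute_gradients(np.zeros((5, 20)))
        with pytest.raises(ValueError, match="minimum 8"):
            partition_cells(f, HOGConfig())


class TestEncode:
    def test_default_dimension_is_256(self):
        P = np.random.default_rng(1).random((50, 20))
        assert encode_hog(P).dim == 256

    def test_dimension_identity_for_any_config(self):
        P = np.random.default_rng(1).random((40, 20))
        cfg = HOGConfig(n_cell_rows=2, n_cell_cols=5, n_bins=9)
        assert encode_hog(P, cfg).dim == 2 * 5 * 9

    @pytest.mark.parametrize("L,seed", [(30, 0), (30, 1), (53, 2), (200, 3)])
    def test_matches_bruteforce_oracle(self, L, seed):
        P = np.random.default_rng(seed).random((L, 20))
        vec = encode_hog(P)
        assert np.abs(vec.values - naive_hog(P.tolist())).max() < 1e-10

    def test_flat_profile_matches_oracle(self):
        # an all-zero raw PSSM normalizes to a constant 0.5 image: only the
        # implicit-zero borders generate gradient, and the encoder must agree
        # with the brute-force recount exactly
        P = np.full((24, 20), 0.5)
        assert np.abs(encode_hog(P).values - naive_hog(P.tolist())).max() < 1e-10

    def test_scale_invariance_of_normalized_histograms(self):
        P = np.random.default_rng(8).random((40, 20))
        f = compute_gradients(P)
        doubled = GradientField(f.Gx, f.Gy, 2 * f.G, f.Theta)
        assert np.allclose(encode_field(f).values, encode_field(doubled).values)

    def test_cell_norms_are_zero_or_one(self):
        P = np.random.default_rng(9).random((31, 20))
        v = encode_hog(P).values.reshape(16, 16)
        norms = np.linalg.norm(v, axis=1)
        assert np.all((np.abs(norms - 1) < 1e-9) | (norms == 0))
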