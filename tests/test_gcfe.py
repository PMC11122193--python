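import numpy as np
import pytest

from gcfeat.gcfe import (
    extract,
    gershgorin_centers,
    gershgorin_radii,
    layout_1d,
    layout_2d,
)
from gcfeat.graphs import build_graph, build_pairwise
from gcfeat.laplacian import mwl, weighted_adjacency

from conftest import random_patches

CHECKER2 = np.array([[0.0, 1.0], [1.0, 0.0]])


class TestRadiiCenters:
    def test_constant_patch_zero_radii(self):
        L = mwl(build_pairwise(np.full((2, 2), 0.3)))
        assert np.array_equal(gershgorin_radii(L), np.zeros(4))
        assert np.array_equal(gershgorin_centers(L), [3, 3, 3, 3])

    def test_checker_pairwise_values(self):
        L = mwl(build_pairwise(CHECKER2))
        assert np.allclose(gershgorin_radii(L), [2, 2, 2, 2])
        assert np.array_equal(gershgorin_centers(L), [3, 3, 3, 3])

    def test_single_node(self):
        L = mwl(build_pairwise(np.zeros((1, 1))))
        assert np.array_equal(gershgorin_radii(L), [0.0])
        assert np.array_equal(gershgorin_centers(L), [0.0])

    def test_radii_use_absolute_values(self):
        """Off-diagonals of an MWL are negative; radii sum magnitudes."""
        M = np.array([[2.0, -1.5], [-1.5, 2.0]])
        assert np.allclose(gershgorin_radii(M), [1.5, 1.5])


class TestGershgorinInclusion:
    @pytest.mark.parametrize("graph_type", ["grid2d", "pairwise", "knn"])
    def test_eigenvalues_inside_disc_union(self, graph_type):
        """Dense-eigensolver oracle: every eigenvalue of the MWL lies in
        the union of [c_i - r_i, c_i + r_i], and c_i >= r_i forces
        nonnegativity."""
        for patch in random_patches(21, seed=3):
            k = min(patch.shape[0], patch.size - 1) if graph_type == "knn" else None
            L = mwl(build_graph(patch, graph_type, k))
            r, c = gershgorin_radii(L), gershgorin_centers(L)
            assert np.all(c - r >= -1e-12)
            for lam in np.linalg.eigvalsh(L):
                assert np.any((c - r <= lam + 1e-9) & (lam - 1e-9 <= c + r))
                assert lam >= -1e-9

    def test_permutation_equivariance(self, rng):
        """Relabeling nodes permutes (r_i, c_i) pairs identically."""
        patch = rng.integers(0, 256, size=(3, 3)) / 255.0
        L = mwl(build_pairwise(patch))
        perm = rng.permutation(9)
        Lp = L[np.ix_(perm, perm)]
        assert np.allclose(gershgorin_radii(Lp), gershgorin_radii(L)[perm])
        assert np.allclose(gershgorin_centers(Lp), gershgorin_centers(L)[perm])

    @pytest.mark.parametrize("graph_type", ["grid2d", "pairwise"])
    def test_feature_sums(self, graph_type):
        """Sum of centers = 2|E|; sum of radii = total adjacency mass."""
        for patch in random_patches(6, seed=5):
            g = build_graph(patch, graph_type)
            L = mwl(g)
            assert np.isclose(gershgorin_centers(L).sum(), 2 * g.n_edges)
            assert np.isclose(gershgorin_radii(L).sum(), weighted_adjacency(g).sum())


class TestExtract:
    def test_shapes(self, rng):
        img = rng.integers(0, 256, size=(28, 28)).astype(np.uint8)
        assert extract(img, 2, "grid2d").tensor.shape == (196, 4, 2)
        assert extract(img, 28, "grid2d").tensor.shape == (1, 784, 2)
        assert extract(img, 14, "knn", knn_k=5).tensor.shape == (4, 196, 2)

    def test_4x4_pairwise_centers_all_3(self, checker4):
        feats = extract(checker4, 2, "pairwise")
        assert feats.tensor.shape == (4, 4, 2)
        assert np.all(feats.centers == 3)

    def test_constant_image_zero_radii(self):
        feats = extract(np.full((6, 6), 77, dtype=np.uint8), 3, "grid2d")
        assert np.all(feats.radii == 0)
        # 3x3 grid degrees: corners 2, edges 3, center 4
        assert sorted(feats.centers[0]) == [2, 2, 2, 2, 3, 3, 3, 3, 4]

    def test_rgb_goes_through_grayscale(self, rng):
        rgb = rng.integers(0, 256, size=(4, 4, 3)).astype(np.uint8)
        from gcfeat.preprocessing import to_grayscale

        a = extract(rgb, 2, "pairwise").tensor
        b = extract(to_grayscale(rgb), 2, "pairwise").tensor
        assert np.array_equal(a, b)

    def test_deterministic(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        t1 = extract(img, 4, "knn", knn_k=3).tensor
        t2 = extract(img, 4, "knn", knn_k=3).tensor
        assert np.array_equal(t1, t2)

    @pytest.mark.parametrize("p", [1, 2, 4, 7, 14, 28])
    def test_total_feature_count_invariant_to_patch_size(self, p, rng):
        """2*M*N features regardless of how the image is tiled."""
        img = rng.integers(0, 256, size=(28, 28)).astype(np.uint8)
        assert extract(img, p, "grid2d").tensor.size == 2 * 28 * 28


class TestLayouts:
    def test_2d_plane_shape_invariant_to_patch_size(self, rng):
        img = rng.integers(0, 256, size=(28, 28)).astype(np.uint8)
        for p in (2, 28):
            assert layout_2d(extract(img, p, "grid2d")).shape == (2, 784, 1)

    def test_2d_rows_are_radii_then_centers(self, checker4):
        feats = extract(checker4, 2, "pairwise")
        plane = layout_2d(feats)
        assert np.array_equal(plane[0, :, 0], feats.radii.ravel())
        assert np.array_equal(plane[1, :, 0], feats.centers.ravel())

    def test_1d_interleaves_per_patch(self, checker4):
        feats = extract(checker4, 2, "pairwise")
        flat = layout_1d(feats)
        assert flat.shape == (32,)  # 2 * P * N = 2 * 4 * 4
        assert np.array_equal(flat[:8].reshape(2, 4),
                              np.stack([feats.radii[0], feats.centers[0]]))

    def test_1d_length_and_permutation_of_2d(self, rng):
        img = rng.integers(0, 256, size=(28, 28)).astype(np.uint8)
        feats = extract(img, 2, "grid2d")
        flat = layout_1d(feats)
        assert flat.shape == (1568,)
        assert np.array_equal(np.sort(flat), np.sort(layout_2d(feats).ravel()))
        blocked = layout_1d(feats, order="blocked")
        assert np.array_equal(blocked, layout_2d(feats).ravel())

    def test_trivial_1x1_image(self):
        feats = extract(np.array([[42]], dtype=np.uint8), 1, "pairwise")
        assert layout_1d(feats).shape == (2,)
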