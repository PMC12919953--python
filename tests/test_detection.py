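"""Detection stages against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punctapolarity import (
    FieldSpec,
    assign_clusters_to_cells,
    cell_mean_intensity,
    filter_clusters_by_size,
    find_clusters,
    generate_field,
    log_normalize,
    otsu_threshold,
    threshold_image,
)


def brute_force_otsu(image, nbins=256):
    """Exhaustive search over all candidate splits, between-class variance
    computed directly from the pixel partition (independent of the cumulative
    -histogram implementation)."""
    flat = np.asarray(image, dtype=float).ravel()
    edges = np.linspace(0.0, 1.0, nbins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    idx = np.clip(np.digitize(flat, edges) - 1, 0, nbins - 1)
    values = centers[idx]  # pixel values quantized to bin centers
    best_var, best_t = -1.0, 0
    n = flat.size
    for t in range(nbins - 1):
        left = values[idx <= t]
        right = values[idx > t]
        if left.size == 0 or right.size == 0:
            continue
        var = left.size * right.size * (left.mean() - right.mean()) ** 2
        if var > best_var + 1e-12 * max(best_var, 1.0):
            best_var, best_t = var, t
    return float(edges[best_t + 1])


class TestLogNormalize:
    def test_log1p_minmax_endpoints(self):
        image = np.array([[0.0, np.e - 1.0]])
        out = log_normalize(image, percentiles=(0, 100))
        np.testing.assert_allclose(out, [[0.0, 1.0]], atol=1e-12)

    def test_constant_image_degenerates_to_zero(self):
        out = log_normalize(np.full((8, 8), 42.0))
        np.testing.assert_array_equal(out, np.zeros((8, 8)))

    def test_rank_preservation(self, rng):
        # sort-based oracle: distinct inputs keep their ordering exactly
        image = rng.choice(2**16, size=400, replace=False).astype(float).reshape(20, 20)
        out = log_normalize(image, percentiles=(0, 100))
        np.testing.assert_array_equal(
            np.argsort(image.ravel()), np.argsort(out.ravel())
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_normalize(np.array([[-1.0, 0.0]]))


class TestThreshold:
    def test_otsu_bimodal_separates_modes(self, rng):
        image = np.full(1000, 0.1)
        image[:100] = 0.9
        rng.shuffle(image)
        image = image.reshape(20, 50)
        mask = threshold_image(image, method="otsu")
        assert mask.sum() == 100

    @pytest.mark.parametrize("seed", range(5))
    def test_otsu_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        # mixture of dim background and bright tail, in [0, 1]
        img = np.clip(np.concatenate([
            rng.beta(2, 8, size=900), rng.beta(8, 2, size=100)
        ]), 0, 1).reshape(25, 40)
        assert otsu_threshold(img) == pytest.approx(brute_force_otsu(img), abs=1e-12)

    def test_quantile_sort_oracle(self, rng):
        values = rng.choice(10_000, size=100, replace=False).astype(float) / 10_000
        mask = threshold_image(values.reshape(10, 10), method="quantile", quantile=0.95)
        assert mask.sum() == 5
        top5 = set(np.argsort(values)[-5:])
        assert set(np.nonzero(mask.ravel())[0]) == top5

    def test_constant_image_empty_mask(self):
        for method in ("otsu", "quantile"):
            assert threshold_image(np.full((5, 5), 0.3), method=method).sum() == 0


class TestFindClusters:
    def test_symmetric_square(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10:13, 10:13] = True
        (cl,) = find_clusters(mask, intensity_image=np.ones((20, 20)))
        assert cl.area == 9
        assert cl.centroid == (11.0, 11.0)
        assert cl.integrated_intensity == 9.0

    def test_diagonal_contact_depends_on_connectivity(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(find_clusters(mask, connectivity=8)) == 1
        assert len(find_clusters(mask, connectivity=4)) == 2

    def test_empty_mask(self):
        assert find_clusters(np.zeros((5, 5), dtype=bool)) == []

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_total_area_equals_foreground(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((30, 30)) < 0.2
        clusters = find_clusters(mask)
        assert sum(c.area for c in clusters) == int(mask.sum())


class TestSizeFilter:
    def test_inclusive_bounds(self):
        mask = np.zeros((40, 120), dtype=bool)
        mask[1, 1:3] = True                  # area 2
        mask[5:7, 5:7] = True                # area 4
        mask[10:13, 10:13] = True            # area 9
        mask[15:35, 20:45] = True            # area 500
        clusters = find_clusters(mask)
        kept = filter_clusters_by_size(clusters, 4, 400)
        assert sorted(c.area for c in kept) == [4, 9]

    def test_unbounded_filter_is_identity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:4, 2:4] = True
        clusters = find_clusters(mask)
        assert filter_clusters_by_size(clusters, 1, np.inf) == clusters

    def test_all_removed(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 3] = True
        assert filter_clusters_by_size(find_clusters(mask), 4, 400) == []


class TestAssignment:
    def _cluster_on(self, rows, cols, shape=(12, 12)):
        m = np.zeros(shape, dtype=bool)
        m[rows, cols] = True
        return find_clusters(m)

    def test_fully_inside_cell(self):
        labels = np.full((12, 12), 3, dtype=np.int32)
        clusters = self._cluster_on(slice(4, 6), slice(4, 6))
        (cl,) = assign_clusters_to_cells(clusters, labels)
        assert cl.cell_id == 3

    def test_plurality_rule(self):
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[:, :6] = 2
        labels[:, 6:] = 5
        clusters = self._cluster_on(slice(0, 1), slice(1, 11))  # 5 px in 2, 5 in 5: tie -> 2
        (cl,) = assign_clusters_to_cells(clusters, labels)
        assert cl.cell_id == 2
        clusters = self._cluster_on(slice(0, 1), slice(0, 10))  # 6 px in 2, 4 in 5
        (cl,) = assign_clusters_to_cells(clusters, labels)
        assert cl.cell_id == 2

    def test_background_plurality_dropped(self):
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[0, 0:3] = 4  # 3 of 10 cluster px in cell 4, 7 on background
        clusters = self._cluster_on(slice(0, 1), slice(0, 10))
        assert assign_clusters_to_cells(clusters, labels) == []


class TestCellMeanIntensity:
    def test_constant_image(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[:5] = 1
        mask[5:] = 2
        means = cell_mean_intensity(np.full((10, 10), 7.0), mask)
        assert means.to_dict() == {1: 7.0, 2: 7.0}

    def test_small_cell_arithmetic(self):
        mask = np.zeros((4, 4), dtype=np.int32)
        image = np.zeros((4, 4))
        mask[0, 0:4] = 9
        image[0, 0:4] = [1, 2, 3, 4]
        assert cell_mean_intensity(image, mask)[9] == 2.5

    def test_empty_mask(self):
        means = cell_mean_intensity(np.ones((4, 4)), np.zeros((4, 4), dtype=np.int32))
        assert means.empty


def test_noise_free_detection_recovers_ground_truth():
    """With zero noise and well-separated spots, every true punctum is found
    within 1 px and assigned to its true cell."""
    spec = FieldSpec(
        n_cells=16, image_height=256, image_width=256, mean_puncta_per_cell=2.0,
        bias_kappa=0.0, noise_sigma=0.0, radial_fraction_range=(0.2, 0.6), seed=21,
    )
    image, mask, truth = generate_field(spec)
    norm = log_normalize(image)
    binary = threshold_image(norm, method="otsu")
    clusters = assign_clusters_to_cells(
        filter_clusters_by_size(find_clusters(binary, intensity_image=norm), 4, 400), mask
    )
    pts = np.array([(r.x, r.y) for r in truth.records])
    # separation precondition: no other punctum within 4 sigma
    sep = np.array([
        all(np.hypot(p[0] - q[0], p[1] - q[1]) >= 6.0 for j, q in enumerate(pts) if j != i)
        for i, p in enumerate(pts)
    ])
    assert sep.mean() > 0.7  # fixture sanity: most puncta are separated
    centroids = np.array([c.centroid for c in clusters])
    cells = np.array([c.cell_id for c in clusters])
    for rec, is_sep in zip(truth.records, sep):
        if not is_sep:
            continue
        d = np.hypot(centroids[:, 0] - rec.x, centroids[:, 1] - rec.y)
        nearest = int(np.argmin(d))
        assert d[nearest] <= 1.0, f"punctum at ({rec.x:.1f},{rec.y:.1f}) missed"
        assert cells[nearest] == rec.cell_id
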