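"""Polarity vectors, reference angles, pooling, circular summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from punctapolarity import (
    CellPolarity,
    ReferenceField,
    cell_centroid,
    cell_polarity_vector,
    mean_resultant,
    pool_fields,
    reference_angle_at,
    relative_angle,
)
from punctapolarity.detection import PunctaCluster


def make_cluster(x, y, area=5, intensity=5.0):
    return PunctaCluster(
        cluster_id=0, centroid=(x, y), area=area, integrated_intensity=intensity,
        rows=np.array([int(y)]), cols=np.array([int(x)]),
    )


class TestCellCentroid:
    def test_symmetric_square(self):
        mask = np.zeros((5, 5), dtype=np.int32)
        mask[0:3, 0:3] = 1
        assert cell_centroid(mask, 1) == (1.0, 1.0)

    def test_two_pixel_midpoint(self):
        mask = np.zeros((3, 3), dtype=np.int32)
        mask[0, 0] = 1  # (x=0, y=0)
        mask[0, 2] = 1  # (x=2, y=0)
        assert cell_centroid(mask, 1) == (1.0, 0.0)

    def test_l_shape(self):
        mask = np.zeros((3, 3), dtype=np.int32)
        mask[0, 0] = mask[0, 1] = mask[1, 0] = 1  # (0,0),(1,0),(0,1)
        x, y = cell_centroid(mask, 1)
        assert (x, y) == pytest.approx((1 / 3, 1 / 3))

    def test_absent_label(self):
        with pytest.raises(ValueError, match="not present"):
            cell_centroid(np.zeros((3, 3), dtype=np.int32), 2)


class TestPolarityVector:
    def test_three_four_five_unit_vector(self):
        cp = cell_polarity_vector((0.0, 0.0), [make_cluster(3.0, 4.0)])
        assert cp.polarity_vector == pytest.approx((0.6, 0.8))
        assert cp.magnitude == pytest.approx(1.0)
        assert cp.defined

    def test_antipodal_cancellation_undefined(self):
        clusters = [make_cluster(2.0, 0.0), make_cluster(-2.0, 0.0)]
        cp = cell_polarity_vector((0.0, 0.0), clusters)
        assert cp.magnitude < 1e-9
        assert not cp.defined
        assert math.isnan(cp.polarity_angle_deg)

    def test_weighted_average_direct_arithmetic(self):
        # clusters at 0 deg (w=3) and 90 deg (w=1): v = (3*(1,0)+1*(0,1))/4
        clusters = [make_cluster(5.0, 0.0, area=3), make_cluster(0.0, 5.0, area=1)]
        cp = cell_polarity_vector((0.0, 0.0), clusters, weight_mode="area")
        assert cp.polarity_vector == pytest.approx((0.75, 0.25))
        assert cp.polarity_angle_deg == pytest.approx(math.degrees(math.atan2(1, 3)))
        assert cp.polarity_angle_deg == pytest.approx(18.43494882, abs=1e-6)

    def test_cluster_at_centroid_skipped(self):
        cp = cell_polarity_vector((1.0, 1.0), [make_cluster(1.0, 1.0), make_cluster(4.0, 1.0)])
        assert cp.polarity_vector == pytest.approx((1.0, 0.0))

    def test_no_clusters_undefined(self):
        cp = cell_polarity_vector((0.0, 0.0), [])
        assert not cp.defined and cp.n_clusters == 0

    def test_weight_modes_agree_when_weights_equal(self, rng):
        clusters = [
            make_cluster(x, y, area=7, intensity=7.0)
            for x, y in rng.uniform(-10, 10, size=(6, 2))
        ]
        by_area = cell_polarity_vector((0.0, 0.0), clusters, "area")
        by_int = cell_polarity_vector((0.0, 0.0), clusters, "intensity")
        assert by_area.polarity_vector == pytest.approx(by_int.polarity_vector)

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50),
                              st.integers(1, 100)), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_magnitude_never_exceeds_one(self, offsets):
        clusters = [make_cluster(x, y, area=a) for x, y, a in offsets]
        cp = cell_polarity_vector((0.0, 0.0), clusters)
        assert cp.magnitude <= 1.0 + 1e-9


class TestReferenceField:
    def test_fixed_angle_everywhere(self):
        ref = ReferenceField.fixed(90.0)
        assert reference_angle_at(ref, (0.0, 0.0)) == 90.0
        assert reference_angle_at(ref, (123.0, -4.0)) == 90.0

    def test_target_along_plus_x(self):
        assert reference_angle_at(ReferenceField.toward((10.0, 0.0)), (0.0, 0.0)) == 0.0

    def test_target_downward_is_positive_90(self):
        # image coordinates: +y points down, so 'below' is +90 deg
        assert reference_angle_at(ReferenceField.toward((0.0, 10.0)), (0.0, 0.0)) == 90.0

    def test_target_at_centroid_undefined(self):
        assert math.isnan(reference_angle_at(ReferenceField.toward((3.0, 3.0)), (3.0, 3.0)))

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            ReferenceField(mode="fixed_angle")
        with pytest.raises(ValueError):
            ReferenceField(mode="spiral")


class TestRelativeAngle:
    @pytest.mark.parametrize(
        "pol,ref,expected",
        [(100.0, 90.0, 10.0), (-170.0, 170.0, 20.0), (45.0, 45.0, 0.0),
         (170.0, -170.0, -20.0), (-90.0, 90.0, 180.0)],
    )
    def test_wrapped_difference(self, pol, ref, expected):
        assert relative_angle(pol, ref) == pytest.approx(expected)


def _cells(angles, weight=10.0):
    out = []
    for i, a in enumerate(angles):
        cp = CellPolarity(cell_id=i, cell_centroid=(0, 0), defined=True,
                          weight_total=weight, n_clusters=1)
        cp.relative_angle_deg = a
        out.append(cp)
    return out


class TestPooling:
    def test_count_conservation(self):
        pooled = pool_fields([_cells(range(30)), _cells(range(40))])
        assert pooled.n == 70
        assert pooled.cells_per_field == [30, 40]

    def test_single_field_identity(self):
        pooled = pool_fields([_cells([10.0, 20.0])])
        np.testing.assert_allclose(pooled.angles_deg, [10.0, 20.0])

    def test_empty_field_listed_in_provenance(self):
        pooled = pool_fields([_cells([5.0]), []])
        assert pooled.cells_per_field == [1, 0]
        assert pooled.n == 1

    def test_config_mismatch_fails(self):
        from punctapolarity import AnalysisConfig

        with pytest.raises(ValueError, match="differs"):
            pool_fields(
                [_cells([0.0]), _cells([0.0])],
                configs=[AnalysisConfig(), AnalysisConfig(n_bins=12)],
            )

    def test_undefined_cells_excluded(self):
        cells = _cells([0.0, 10.0])
        cells[1].defined = False
        assert pool_fields([cells]).n == 1

    def test_mass_weighting(self):
        pooled = pool_fields([_cells([0.0, 90.0], weight=4.0)], rose_weight_mode="mass")
        np.testing.assert_allclose(pooled.weights, [4.0, 4.0])


class TestMeanResultant:
    def test_perfect_alignment(self):
        r, mean = mean_resultant([0.0, 0.0, 0.0])
        assert (r, mean) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_antipodal_cancellation(self):
        r, _ = mean_resultant([0.0, 180.0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_mean_resultant_identity(self):
        # Monte-Carlo against R = I1(kappa)/I0(kappa) at kappa = 2
        rng = np.random.default_rng(7)
        angles = np.degrees(rng.vonmises(0.0, 2.0, size=100_000))
        r, mean = mean_resultant(angles)
        expected = special.iv(1, 2.0) / special.iv(0, 2.0)
        assert r == pytest.approx(expected, abs=0.01)
        assert abs(mean) < 1.0

    def test_empty_undefined(self):
        with pytest.raises(ValueError):
            mean_resultant([])
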