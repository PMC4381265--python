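"""Out-of-field photon dose: distances, the two-Gaussian model, replacement,
the sensitivity rule and volume-weighted averaging."""

import numpy as np
import pytest

from smnrisk.grids import DoseGrid
from smnrisk.out_of_field import (
    IsodoseSurface,
    OutOfFieldModelParams,
    PointMeasurement,
    classify_field_position,
    distance_to_surface,
    distances_to_surface,
    out_of_field_model_dose,
    replace_out_of_field,
    sensitivity_analysis,
    volume_weighted_organ_dose,
)

# Independent evaluations of the two-Gaussian falloff (default fitted
# parameters, D_Rx = 23.4 Gy-RBE, w_R = 1), frozen from a hand calculation:
# H(r) = 23.4/100 * [a1/(sqrt(2 pi) s1) exp(-(r-m1)^2/(2 s1^2)) + (term 2)].
EQ_ORACLE = {
    1.0: 3.2185825254043636,
    5.0: 0.9809949439763227,
    10.0: 0.48384458802879554,
    20.0: 0.057932961410411064,
}


class TestDistanceToSurface:
    def test_point_on_vertex_is_zero(self):
        surf = IsodoseSurface(level=0.5, vertices=[[0, 0, 0], [10, 0, 0]])
        assert distance_to_surface((10, 0, 0), surf) == 0.0

    def test_converts_mm_to_cm(self):
        surf = IsodoseSurface(level=0.5, vertices=[[0, 0, 0]])
        assert distance_to_surface((30, 0, 0), surf) == pytest.approx(3.0)

    def test_matches_exhaustive_all_vertex_minimum(self, rng):
        verts = rng.uniform(-50, 50, (200, 3))
        surf = IsodoseSurface(level=0.5, vertices=verts)
        points = rng.uniform(-80, 80, (40, 3))
        got = distances_to_surface(points, surf)
        for p, g in zip(points, got):
            brute = min(np.sqrt(((v - p) ** 2).sum()) for v in verts) / 10.0
            assert g == pytest.approx(brute, rel=1e-12)
            assert distance_to_surface(p, surf) == pytest.approx(brute, rel=1e-12)

    def test_empty_vertex_list_rejected(self):
        with pytest.raises(ValueError):
            IsodoseSurface(level=0.5, vertices=np.empty((0, 3)))


class TestTwoGaussianModel:
    @pytest.mark.parametrize("r, expected", sorted(EQ_ORACLE.items()))
    def test_matches_independent_calculation(self, r, expected):
        assert out_of_field_model_dose(r) == pytest.approx(expected, rel=1e-12)

    def test_vanishes_far_from_the_field(self):
        assert out_of_field_model_dose(200.0) < 1e-80

    def test_monotone_decreasing_at_sample_points(self):
        assert (
            out_of_field_model_dose(5.0)
            > out_of_field_model_dose(10.0)
            > out_of_field_model_dose(20.0)
        )

    def test_strictly_decreasing_over_out_of_field_range(self):
        r = np.arange(1.0, 60.0 + 1e-9, 0.1)
        h = out_of_field_model_dose(r)
        assert (np.diff(h) < 0).all()
        assert (h > 0).all()

    def test_scales_linearly_with_prescription_and_weighting(self):
        base = out_of_field_model_dose(5.0, D_Rx=23.4, w_R=1.0)
        assert out_of_field_model_dose(5.0, D_Rx=46.8, w_R=1.0) == pytest.approx(
            2 * base
        )
        assert out_of_field_model_dose(5.0, D_Rx=23.4, w_R=1.1) == pytest.approx(
            1.1 * base
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            OutOfFieldModelParams(sigma1=-1.0)
        with pytest.raises(ValueError):
            OutOfFieldModelParams(alpha2=-5.0)


class TestReplaceOutOfField:
    SPACING = (10.0, 10.0, 10.0)

    def _grid(self, values):
        return DoseGrid(values=values, spacing=self.SPACING, unit="Sv")

    def test_fully_enclosed_grid_is_unchanged(self):
        values = np.full((4, 4, 4), 23.4)  # everything at prescription
        surf = IsodoseSurface(level=0.5, vertices=[[-100.0, 0.0, 0.0]])
        out = replace_out_of_field(self._grid(values), surf)
        np.testing.assert_array_equal(out.values, values)

    def test_guard_band_voxel_keeps_tps_value(self):
        # voxel centres at x = 0, 10, 20 mm; vertex at x = 5 mm: the first
        # two voxels are 0.5 cm away (inside the 1 cm guard band) and keep
        # their planning-system values; the third (1.5 cm) is replaced
        values = np.zeros((3, 1, 1)) + 0.01
        values[2, 0, 0] = 0.01
        grid = DoseGrid(values=values, spacing=(10.0, 10.0, 10.0),
                        origin=(0.0, 0.0, 0.0), unit="Sv")
        surf = IsodoseSurface(level=0.5, vertices=[[5.0, 0.0, 0.0]])
        out = replace_out_of_field(grid, surf)
        assert out.values[0, 0, 0] == 0.01
        assert out.values[1, 0, 0] == 0.01
        assert out.values[2, 0, 0] == pytest.approx(
            out_of_field_model_dose(1.5), rel=1e-12
        )

    def test_in_field_voxels_bit_identical(self, rng):
        values = rng.uniform(0, 1, (6, 6, 6))
        values[2:4] = 23.4  # an in-field slab
        surf = IsodoseSurface(level=0.5, vertices=[[25.0, 25.0, 25.0]])
        grid = self._grid(values)
        out = replace_out_of_field(grid, surf)
        infield = values >= 0.5 * 23.4
        np.testing.assert_array_equal(out.values[infield], values[infield])
        assert out.values[infield].sum() == values[infield].sum()

    def test_self_consistent_grid_unchanged_beyond_guard_band(self):
        # a grid whose out-of-field voxels already carry model values is a
        # fixed point of the replacement (outside the 1 cm band)
        shape = (8, 1, 1)
        centers = np.arange(8) * 10.0  # mm along x
        surf = IsodoseSurface(level=0.5, vertices=[[0.0, 0.0, 0.0]])
        r = centers / 10.0
        values = out_of_field_model_dose(r).reshape(shape)
        values[0, 0, 0] = 23.4  # the in-field voxel at the vertex
        out = replace_out_of_field(self._grid(values), surf)
        np.testing.assert_allclose(out.values, values, rtol=1e-12)


class TestSensitivityRule:
    SPACING = (5.0, 5.0, 5.0)

    def test_fully_in_field_organ_never_triggers(self):
        g = DoseGrid(values=np.full((3, 3, 3), 23.4), spacing=self.SPACING, unit="Sv")
        mask = np.ones((3, 3, 3), bool)
        assert sensitivity_analysis(g, mask, in_5pct=mask) is False

    def test_fully_out_of_field_organ_always_triggers(self):
        g = DoseGrid(values=np.full((3, 3, 3), 0.4), spacing=self.SPACING, unit="Sv")
        mask = np.ones((3, 3, 3), bool)
        assert sensitivity_analysis(g, mask, in_5pct=np.zeros_like(mask)) is True

    def test_in_field_dominated_partial_organ_does_not_trigger(self):
        # 12% of the volume in-field at prescription dose dominates the mean;
        # perturbing the low-dose out-of-field voxels moves it by < 5%
        values = np.full((100, 1, 1), 0.1)
        values[:12] = 23.4
        in5 = np.zeros((100, 1, 1), bool)
        in5[:12] = True
        g = DoseGrid(values=values, spacing=self.SPACING, unit="Sv")
        assert sensitivity_analysis(g, np.ones_like(in5), in5) is False

    def test_empty_mask_rejected(self):
        g = DoseGrid(values=np.ones((2, 2, 2)), spacing=self.SPACING, unit="Sv")
        with pytest.raises(ValueError):
            sensitivity_analysis(g, np.zeros((2, 2, 2), bool), np.ones((2, 2, 2), bool))


class TestVolumeWeighted:
    def test_fully_out_of_field_returns_measurement_mean(self):
        tld = [
            PointMeasurement("uterus", (0, 0, 0), 0.55),
            PointMeasurement("uterus", (5, 0, 0), 0.65),
        ]
        assert volume_weighted_organ_dose(0.0, 0.0, tld) == pytest.approx(0.60)

    def test_fully_in_field_returns_tps_value(self):
        assert volume_weighted_organ_dose(16.75, 1.0, []) == 16.75

    def test_half_in_field_midpoint(self):
        assert volume_weighted_organ_dose(2.0, 0.5, [1.0]) == pytest.approx(1.5)

    def test_missing_measurements_rejected(self):
        with pytest.raises(ValueError):
            volume_weighted_organ_dose(2.0, 0.5, [])


class TestClassifyFieldPosition:
    def test_categories_follow_volume_fraction(self):
        mask = np.ones((4, 1, 1), bool)
        none_in = np.zeros_like(mask)
        all_in = np.ones_like(mask)
        half_in = np.zeros_like(mask)
        half_in[:2] = True
        assert classify_field_position("a", mask, none_in).category == "out-of-field"
        assert classify_field_position("a", mask, all_in).category == "in-field"
        pos = classify_field_position("a", mask, half_in)
        assert pos.category == "partially-in-field"
        assert pos.fraction_in_5pct == pytest.approx(0.5)

    def test_pelvic_organs_below_spinal_field_are_out_of_field(
        self, photon_case_exact
    ):
        case = photon_case_exact
        equiv = case.dose["primary"]
        in5 = equiv.values >= 0.05 * case.config.D_Rx
        for organ in ("uterus", "ovaries", "bladder"):
            pos = classify_field_position(organ, case.structures[organ], in5)
            assert pos.category == "out-of-field", organ

    def test_thyroid_is_fully_in_field(self, photon_case_exact):
        case = photon_case_exact
        in5 = case.dose["primary"].values >= 0.05 * case.config.D_Rx
        pos = classify_field_position("thyroid", case.structures["thyroid"], in5)
        assert pos.category == "in-field"
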