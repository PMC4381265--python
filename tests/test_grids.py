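"""Dose-grid containers, organ means, truncation, density and DVHs."""

import numpy as np
import pytest

from smnrisk.grids import (
    DEFAULT_CT_CALIBRATION,
    DensityGrid,
    DoseGrid,
    StructureSet,
    TruncationInfo,
    UnitError,
    apply_truncation_correction,
    compute_dvh,
    density_from_ct,
    derive_remainder,
    equivalent_dose_voxelwise,
    mean_organ_equivalent_dose,
)

SPACING = (2.0, 2.0, 2.0)


def _grid(values, unit="Gy"):
    return DoseGrid(values=np.asarray(values, dtype=float), spacing=SPACING, unit=unit)


class TestEquivalentDose:
    def test_photon_weighting_is_identity_up_to_unit(self):
        g = _grid(np.full((3, 3, 3), 2.0))
        h = equivalent_dose_voxelwise(g, w_R=1.0)
        assert h.unit == "Sv"
        np.testing.assert_array_equal(h.values, g.values)

    def test_proton_rbe_rescales_absorbed_to_prescription(self):
        # 21.3 Gy physical x 1.1 = 23.43 Sv, the craniospinal prescription
        g = _grid(np.full((2, 2, 2), 21.3))
        h = equivalent_dose_voxelwise(g, w_R=1.1)
        np.testing.assert_allclose(h.values, 23.43)

    def test_zero_grid_stays_zero(self):
        h = equivalent_dose_voxelwise(_grid(np.zeros((2, 2, 2))), w_R=9.2)
        assert not h.values.any()

    def test_per_source_particle_unit_is_preserved(self):
        h = equivalent_dose_voxelwise(_grid(np.ones((2, 2, 2)), "Gy/sp"), w_R=9.0)
        assert h.unit == "Sv/sp"

    def test_rejects_equivalent_dose_input(self):
        with pytest.raises(UnitError):
            equivalent_dose_voxelwise(_grid(np.ones((2, 2, 2)), "Sv"), w_R=1.0)

    def test_rejects_nonpositive_weighting_factor(self):
        with pytest.raises(ValueError):
            equivalent_dose_voxelwise(_grid(np.ones((2, 2, 2))), w_R=0.0)


class TestMeanOrganDose:
    def test_uniform_field_any_density(self, rng):
        g = _grid(np.full((4, 4, 4), 2.0), "Sv")
        rho = DensityGrid(values=rng.uniform(0.5, 2, (4, 4, 4)), spacing=SPACING)
        mask = np.ones((4, 4, 4), bool)
        assert mean_organ_equivalent_dose(g, mask, rho) == pytest.approx(2.0)

    def test_two_voxel_weighted_mean(self):
        vals = np.zeros((2, 1, 1))
        vals[0, 0, 0], vals[1, 0, 0] = 1.0, 3.0
        rho = np.zeros((2, 1, 1))
        rho[0, 0, 0], rho[1, 0, 0] = 1.0, 3.0
        g = _grid(vals, "Sv")
        d = DensityGrid(values=rho, spacing=SPACING)
        # (1*1 + 3*3) / (1 + 3) = 2.5
        assert mean_organ_equivalent_dose(g, np.ones((2, 1, 1), bool), d) == 2.5

    def test_matches_bruteforce_loop_on_random_grid(self, rng):
        g = _grid(rng.uniform(0, 10, (20, 20, 20)), "Sv")
        rho = DensityGrid(values=rng.uniform(0.2, 2.0, (20, 20, 20)), spacing=SPACING)
        mask = rng.random((20, 20, 20)) < 0.3
        num = den = 0.0
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    if mask[i, j, k]:
                        num += g.values[i, j, k] * rho.values[i, j, k]
                        den += rho.values[i, j, k]
        expected = num / den
        got = mean_organ_equivalent_dose(g, mask, rho)
        assert got == pytest.approx(expected, rel=1e-12)
        assert g.values[mask].min() <= got <= g.values[mask].max()

    def test_uniform_density_equals_plain_mean(self, rng):
        g = _grid(rng.uniform(0, 5, (8, 8, 8)), "Sv")
        rho = DensityGrid(values=np.full((8, 8, 8), 1.3), spacing=SPACING)
        mask = rng.random((8, 8, 8)) < 0.5
        assert mean_organ_equivalent_dose(g, mask, rho) == pytest.approx(
            g.values[mask].mean(), rel=1e-12
        )

    def test_linearity_in_the_dose_grid(self, rng):
        x = rng.uniform(0, 3, (6, 6, 6))
        y = rng.uniform(0, 3, (6, 6, 6))
        rho = DensityGrid(values=rng.uniform(0.5, 2, (6, 6, 6)), spacing=SPACING)
        mask = rng.random((6, 6, 6)) < 0.4
        a, b = 2.0, 0.25
        lhs = mean_organ_equivalent_dose(_grid(a * x + b * y, "Sv"), mask, rho)
        rhs = a * mean_organ_equivalent_dose(
            _grid(x, "Sv"), mask, rho
        ) + b * mean_organ_equivalent_dose(_grid(y, "Sv"), mask, rho)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_empty_mask_and_shape_mismatch_are_errors(self):
        g = _grid(np.ones((3, 3, 3)), "Sv")
        with pytest.raises(ValueError, match="empty"):
            mean_organ_equivalent_dose(g, np.zeros((3, 3, 3), bool))
        with pytest.raises(ValueError, match="shape"):
            mean_organ_equivalent_dose(g, np.ones((2, 2, 2), bool))


class TestTruncationCorrection:
    def test_imaged_mass_ratio_applied_to_skin(self):
        info = TruncationInfo.from_ratio(0.726, {"skin", "remainder"})
        assert apply_truncation_correction(1.0, info, "skin") == pytest.approx(0.726)

    def test_ratio_one_is_identity(self):
        info = TruncationInfo.from_ratio(1.0, {"skin"})
        assert apply_truncation_correction(3.2, info, "skin") == 3.2

    def test_fully_imaged_organ_unchanged(self):
        info = TruncationInfo.from_ratio(0.726, {"skin", "remainder"})
        assert apply_truncation_correction(1.2, info, "thyroid") == 1.2

    def test_correction_is_invertible(self):
        info = TruncationInfo.from_ratio(0.726, {"skin"})
        h = apply_truncation_correction(2.345, info, "skin")
        assert h / info.correction_ratio == pytest.approx(2.345, rel=1e-12)

    @pytest.mark.parametrize("ratio", [0.0, -0.5, 1.2])
    def test_invalid_ratio_rejected(self, ratio):
        with pytest.raises(ValueError):
            TruncationInfo.from_ratio(ratio, {"skin"})


class TestDensityFromCT:
    def test_interpolates_at_and_between_knots(self):
        cal = ((-1000.0, 0.001), (0.0, 1.0))
        ct = np.array([[[-1000.0, -500.0, 0.0]]])
        rho = density_from_ct(ct, cal, spacing=SPACING)
        np.testing.assert_allclose(rho.values[0, 0], [0.001, 0.5005, 1.0])
        assert rho.provenance == "from-CT-calibration"

    def test_water_phantom_is_unit_density(self):
        rho = density_from_ct(
            np.zeros((3, 3, 3)), DEFAULT_CT_CALIBRATION, spacing=SPACING
        )
        np.testing.assert_allclose(rho.values, 1.0)

    def test_out_of_domain_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            rho = density_from_ct(
                np.full((1, 1, 1), 5000.0), DEFAULT_CT_CALIBRATION, spacing=SPACING
            )
        assert rho.values[0, 0, 0] == DEFAULT_CT_CALIBRATION[-1][1]

    def test_decreasing_calibration_rejected(self):
        with pytest.raises(ValueError):
            density_from_ct(
                np.zeros((1, 1, 1)), ((-1000.0, 1.0), (0.0, 0.5)), spacing=SPACING
            )


class TestRemainder:
    def test_no_specific_organs_gives_whole_body(self):
        body = np.ones((3, 3, 3), bool)
        s = StructureSet(masks={"whole body": body})
        np.testing.assert_array_equal(derive_remainder(s), body)

    def test_organs_tiling_body_leave_nothing(self):
        body = np.ones((2, 2, 2), bool)
        half = np.zeros_like(body)
        half[0] = True
        s = StructureSet(masks={"whole body": body, "a": half, "b": ~half})
        assert not derive_remainder(s).any()

    def test_matches_per_voxel_set_arithmetic(self, photon_case_exact):
        s = photon_case_exact.structures
        remainder = derive_remainder(s)
        body = s["whole body"]
        union = np.zeros_like(body)
        for organ in s.specific_organs():
            union |= s[organ]
        assert remainder.sum() == body.sum() - (union & body).sum()
        for organ in s.specific_organs():
            assert not (remainder & s[organ]).any()

    def test_remainder_organs_and_complement_partition_grid(self, photon_case_exact):
        s = photon_case_exact.structures
        body = s["whole body"]
        union = np.zeros_like(body)
        for organ in s.specific_organs():
            union |= s[organ] & body
        parts = s["remainder"].astype(int) + union.astype(int) + (~body).astype(int)
        assert (parts == 1).all()

    def test_missing_whole_body_is_an_error(self):
        with pytest.raises(ValueError, match="whole body"):
            derive_remainder(StructureSet(masks={"liver": np.ones((2, 2, 2), bool)}))


class TestDVH:
    def test_uniform_dose_occupies_single_bin(self):
        g = _grid(np.full((3, 3, 3), 2.0), "Sv")
        dvh = compute_dvh(g, np.ones((3, 3, 3), bool), n_bins=10)
        assert dvh.differential_volume.sum() == pytest.approx(1.0)
        assert (dvh.differential_volume > 0).sum() == 1

    def test_two_equal_volume_levels_split_half_half(self):
        vals = np.zeros((2, 2, 2))
        vals[0] = 1.0
        vals[1] = 3.0
        dvh = compute_dvh(_grid(vals, "Sv"), np.ones((2, 2, 2), bool), n_bins=2)
        np.testing.assert_allclose(dvh.differential_volume, [0.5, 0.5])

    def test_mean_recovered_within_bin_width(self, rng):
        vals = rng.uniform(0, 20, (10, 10, 10))
        mask = rng.random((10, 10, 10)) < 0.5
        g = _grid(vals, "Sv")
        dvh = compute_dvh(g, mask, n_bins=200)
        width = dvh.bin_edges[1] - dvh.bin_edges[0]
        assert abs(dvh.mean_dose() - vals[mask].mean()) <= width

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            compute_dvh(_grid(np.ones((2, 2, 2)), "Sv"), np.zeros((2, 2, 2), bool))
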