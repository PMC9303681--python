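"""Region masks, directional volume coefficients, calibration bands."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from golgicoloc import (
    CalibrationError,
    calibrate_bands,
    classify_coefficient,
    coloc_coefficients,
    compartment_volumes,
    full_domain_region,
    make_region_mask,
    reference_bands,
    restrict_to_region,
    surfaces_from_mask,
)
from tests.conftest import brute_force_overlap

VOXEL = (159.0, 35.0, 35.0)


def surf(mask, name="ch"):
    return surfaces_from_mask(np.asarray(mask, dtype=bool), VOXEL, channel=name)


def random_fields(seed, shape=(8, 20, 20), p=0.3):
    rng = np.random.default_rng(seed)
    return (
        rng.random(shape) < p,
        rng.random(shape) < p,
        rng.random(shape) < 0.5,
    )


class TestRegionMask:
    def test_single_marker_identity(self):
        a, _, _ = random_fields(1)
        region = make_region_mask([surf(a, "m1")], "R")
        assert np.array_equal(region.mask, a)
        assert region.markers == ["m1"]

    def test_disjoint_union_volume(self):
        m = np.zeros((4, 10, 10), dtype=bool)
        n = np.zeros((4, 10, 10), dtype=bool)
        m.ravel()[:100] = True
        n.ravel()[200:280] = True
        region = make_region_mask([surf(m), surf(n)], "R")
        assert region.volume_voxels == 180

    def test_overlapping_union_volume_oracle(self):
        a, b, _ = random_fields(5)
        region = make_region_mask([surf(a), surf(b)], "R")
        assert region.volume_voxels == int(a.sum() + b.sum() - (a & b).sum())

    def test_empty_union_flagged(self):
        z = np.zeros((4, 6, 6), dtype=bool)
        region = make_region_mask([surf(z)], "R")
        assert region.empty and region.volume_voxels == 0


class TestRestrictToRegion:
    def test_full_domain_is_identity(self):
        a, _, _ = random_fields(2)
        out = restrict_to_region(surf(a), full_domain_region(a.shape))
        assert np.array_equal(out.mask, a)

    def test_disjoint_region_gives_flagged_empty(self):
        a = np.zeros((4, 8, 8), dtype=bool)
        a[0, :2, :2] = True
        region = np.zeros_like(a)
        region[3, 5:, 5:] = True
        out = restrict_to_region(surf(a), make_region_mask([surf(region)], "R"))
        assert out.empty

    def test_partial_overlap_counts_match_oracle(self):
        a, _, r = random_fields(3)
        out = restrict_to_region(surf(a), make_region_mask([surf(r)], "R"))
        assert out.volume_voxels == int((a & r).sum())

    def test_grid_mismatch_rejected(self):
        a = np.zeros((4, 8, 8), dtype=bool)
        b = np.zeros((4, 9, 9), dtype=bool)
        with pytest.raises(ValueError):
            restrict_to_region(surf(a), make_region_mask([surf(b)], "R"))


class TestCoefficients:
    def test_identical_channels_give_unity(self):
        a, _, _ = random_fields(4)
        res = coloc_coefficients(surf(a, "A"), surf(a, "B"))
        assert res.coefficient1 == 1.0 and res.coefficient2 == 1.0

    def test_disjoint_channels_give_zero(self):
        a = np.zeros((4, 8, 8), dtype=bool)
        b = np.zeros_like(a)
        a[0] = True
        b[2] = True
        res = coloc_coefficients(surf(a), surf(b))
        assert res.coefficient1 == 0.0 and res.coefficient2 == 0.0

    def test_hand_built_counts(self):
        a = np.zeros((2, 4, 4), dtype=bool)
        b = np.zeros_like(a)
        a.ravel()[:10] = True
        b.ravel()[6:14] = True
        res = coloc_coefficients(surf(a), surf(b))
        assert (res.vol_a, res.vol_b, res.vol_ab) == (10, 8, 4)
        assert res.coefficient1 == pytest.approx(0.4)
        assert res.coefficient2 == pytest.approx(0.5)

    def test_empty_channel_reported_missing_not_zero(self):
        a = np.zeros((2, 4, 4), dtype=bool)
        b = np.zeros_like(a)
        b[0] = True
        res = coloc_coefficients(surf(a), surf(b))
        assert res.empty_a and res.coefficient1 is None
        assert res.coefficient2 == 0.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True, database=None)
    def test_exact_integer_identity_and_symmetry(self, seed):
        a, b, r = random_fields(seed, shape=(6, 12, 12))
        region = make_region_mask([surf(r)], "R")
        res = coloc_coefficients(surf(a, "A"), surf(b, "B"), region)
        assert res.vol_ab <= min(res.vol_a, res.vol_b)
        if res.coefficient1 is not None:
            assert res.coefficient1 * res.vol_a == pytest.approx(res.vol_ab, abs=1e-9)
        if res.coefficient2 is not None:
            assert res.coefficient2 * res.vol_b == pytest.approx(res.vol_ab, abs=1e-9)
        swapped = coloc_coefficients(surf(b, "B"), surf(a, "A"), region)
        assert (swapped.vol_a, swapped.vol_b) == (res.vol_b, res.vol_a)
        assert swapped.vol_ab == res.vol_ab

    def test_oracle_equivalence_brute_force(self):
        """Coefficients equal triple-loop counting exactly on random fields."""
        for seed in range(3):
            a, b, r = random_fields(seed + 50, shape=(8, 20, 20))
            region = make_region_mask([surf(r)], "R")
            res = coloc_coefficients(surf(a), surf(b), region)
            va, vb, vab = brute_force_overlap(a, b, r)
            assert (res.vol_a, res.vol_b, res.vol_ab) == (va, vb, vab)

    def test_mask_consistency_restrict_then_full_domain(self):
        a, b, r = random_fields(9)
        region = make_region_mask([surf(r)], "R")
        direct = coloc_coefficients(surf(a), surf(b), region)
        restricted = coloc_coefficients(
            restrict_to_region(surf(a), region),
            restrict_to_region(surf(b), region),
            None,
        )
        assert (direct.vol_a, direct.vol_b, direct.vol_ab) == (
            restricted.vol_a,
            restricted.vol_b,
            restricted.vol_ab,
        )


class TestCompartmentVolumes:
    def test_empty_region_gives_zeros(self):
        a, b, _ = random_fields(12)
        region = make_region_mask([surf(np.zeros_like(a))], "R")
        table = compartment_volumes([surf(a, "A"), surf(b, "B")], region)
        assert (table["voxels"] == 0).all()

    def test_subset_channel_keeps_full_volume(self):
        r = np.zeros((4, 8, 8), dtype=bool)
        r[1:3] = True
        a = np.zeros_like(r)
        a[1, 2:4, 2:4] = True
        table = compartment_volumes([surf(a, "A")], make_region_mask([surf(r)], "R"))
        assert table["voxels"].iloc[0] == int(a.sum())

    def test_arbitrary_overlap_matches_count(self):
        a, _, r = random_fields(13)
        table = compartment_volumes([surf(a, "A")], make_region_mask([surf(r)], "R"))
        assert table["voxels"].iloc[0] == int((a & r).sum())


class TestCalibration:
    def test_bands_from_published_control_values(self):
        bands = calibrate_bands([0.16, 0.22], [0.52, 0.59], [0.99, 1.0])
        assert bands.negligible_max == pytest.approx(0.19)
        assert bands.moderate_max == pytest.approx(0.555)
        assert bands.perfect_min == pytest.approx(0.995)
        ref = reference_bands()
        assert ref.negligible_max == pytest.approx(0.19)

    def test_degenerate_single_values(self):
        bands = calibrate_bands([0.1], [0.5], [1.0])
        assert (bands.negligible_max, bands.moderate_max, bands.perfect_min) == (0.1, 0.5, 1.0)

    def test_unordered_inputs_raise(self):
        with pytest.raises(CalibrationError):
            calibrate_bands([0.6], [0.5], [1.0])

    def test_classification_rules(self):
        bands = reference_bands()
        assert classify_coefficient(0.10, bands) == "negligible"
        assert classify_coefficient(0.0, bands) == "negligible"
        assert classify_coefficient(1.0, bands) == "high"
        # boundary ties are inclusive-below
        assert classify_coefficient(bands.negligible_max, bands) == "negligible"
        assert classify_coefficient(bands.moderate_max, bands) == "moderate"
        assert classify_coefficient(0.4, bands) == "moderate"

    def test_out_of_range_coefficient_rejected(self):
        with pytest.raises(ValueError):
            classify_coefficient(1.2, reference_bands())
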