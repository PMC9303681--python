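"""Ministack detection and cargo co-occurrence classification."""

import numpy as np
import pytest

from golgicoloc import (
    SceneSpec,
    build_scene,
    classify_cooccurrence,
    coloc_coefficients,
    detect_ministacks,
    make_region_mask,
    render,
    segment_channel,
    surfaces_from_mask,
)
from golgicoloc.coloc import RegionMask
from golgicoloc.ministacks import CATEGORIES
from golgicoloc.optics import bin_to_voxels, make_psf
from golgicoloc.segmentation import SegmentationParams

VOXEL = (159.0, 35.0, 35.0)
MARKERS = ("cis", "medial", "trans")


def region_of(mask):
    return RegionMask(mask=np.asarray(mask, dtype=bool), label="golgi")


def voxelized_surfaces(gt, channel):
    """Ground-truth masks on the acquisition grid, bypassing the optics."""
    binned = bin_to_voxels(
        gt.channels[channel].astype(np.float32), gt.fine_step_nm, VOXEL
    )
    return surfaces_from_mask(binned > 0, VOXEL, channel=channel)


class TestDetect:
    def test_thirty_disjoint_stacks_found(self):
        spec = SceneSpec(
            mode="ministacks",
            field_size_nm=(1431.0, 12000.0, 12000.0),
            n_ministacks=30,
        )
        gt = build_scene(spec, seed=3)
        marker_union = np.zeros(gt.grid_shape, dtype=bool)
        for m in MARKERS:
            marker_union |= gt.channels[m]
        binned = bin_to_voxels(marker_union.astype(np.float32), 10.0, VOXEL)
        det = detect_ministacks(region_of(binned > 0), voxel_nm=VOXEL)
        assert det.n_stacks == 30

    def test_face_sharing_stacks_merge_under_26_connectivity(self):
        mask = np.zeros((5, 12, 12), dtype=bool)
        mask[2, 2:5, 2:5] = True
        mask[2, 5:8, 5:8] = True  # shares a corner/edge path with the first
        det = detect_ministacks(region_of(mask), connectivity=26, min_component_voxels=1)
        assert det.n_stacks == 1
        det6 = detect_ministacks(region_of(mask), connectivity=6, min_component_voxels=1)
        assert det6.n_stacks == 2

    def test_empty_region_flagged(self):
        det = detect_ministacks(region_of(np.zeros((4, 8, 8))))
        assert det.empty and det.n_stacks == 0
        table = classify_cooccurrence(
            det,
            surfaces_from_mask(np.zeros((4, 8, 8), bool), VOXEL),
            surfaces_from_mask(np.zeros((4, 8, 8), bool), VOXEL),
        )
        assert table.empty

    def test_border_stacks_retained_and_flagged(self):
        mask = np.zeros((5, 10, 10), dtype=bool)
        mask[0, 0:3, 0:3] = True  # touches border
        mask[2, 5:8, 5:8] = True
        det = detect_ministacks(region_of(mask), min_component_voxels=1)
        assert det.n_stacks == 2
        assert det.table["touches_border"].sum() == 1


class TestClassify:
    def test_presence_threshold_boundary(self):
        stacks_mask = np.zeros((4, 10, 10), dtype=bool)
        stacks_mask[1, 1:4, 1:4] = True
        stacks_mask[1, 6:9, 6:9] = True
        det = detect_ministacks(region_of(stacks_mask), min_component_voxels=1)
        a = np.zeros_like(stacks_mask)
        a[1, 1:3, 1] = True  # 2 voxels in stack 1
        b = np.zeros_like(stacks_mask)
        b[1, 6, 6] = True  # 1 voxel in stack 2: below presence_min=2
        table = classify_cooccurrence(
            det,
            surfaces_from_mask(a, VOXEL, "A"),
            surfaces_from_mask(b, VOXEL, "B"),
            presence_min=2,
        )
        cats = dict(zip(table.table["stack_id"], table.table["category"]))
        assert cats[1] == "A_only"
        assert cats[2] == "neither"  # presence_min - 1 voxels counts as absent

    def test_fractions_partition_to_one(self):
        spec = SceneSpec(
            mode="ministacks",
            field_size_nm=(1431.0, 7000.0, 7000.0),
            n_ministacks=8,
            category_probs=(0.4, 0.25, 0.2, 0.15),
        )
        gt = build_scene(spec, seed=5)
        marker = voxelized_surfaces(gt, "cis")
        det = detect_ministacks(region_of(marker.mask), voxel_nm=VOXEL)
        table = classify_cooccurrence(
            det, voxelized_surfaces(gt, "cargoA"), voxelized_surfaces(gt, "cargoB")
        )
        assert sum(table.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(table.table["category"]) <= set(CATEGORIES)

    def test_binomial_recovery_of_generator_probabilities(self):
        """Category fractions over 300 stacks recover the generator's category
        probabilities within 3 binomial standard errors."""
        probs = dict(zip(CATEGORIES, (0.5, 0.15, 0.15, 0.2)))
        counts = {c: 0 for c in CATEGORIES}
        total = 0
        for seed in range(50):
            spec = SceneSpec(
                mode="ministacks",
                field_size_nm=(1431.0, 5200.0, 5200.0),
                n_ministacks=6,
                category_probs=tuple(probs.values()),
            )
            gt = build_scene(spec, seed=seed)
            markers = [voxelized_surfaces(gt, m) for m in MARKERS]
            region = make_region_mask(markers, "golgi")
            det = detect_ministacks(region, voxel_nm=VOXEL)
            table = classify_cooccurrence(
                det, voxelized_surfaces(gt, "cargoA"), voxelized_surfaces(gt, "cargoB")
            )
            for cat, k in table.table["category"].value_counts().items():
                counts[cat] += int(k)
            total += det.n_stacks
        assert total == 300
        for cat, p in probs.items():
            se = np.sqrt(p * (1 - p) / total)
            assert abs(counts[cat] / total - p) <= 3 * se, (cat, counts)

    def test_noiseless_render_recovers_true_categories_exactly(self):
        """Through the full optics + segmentation chain, noiseless scenes give
        100% per-stack category agreement with the ground truth."""
        psf = make_psf(150.0, 400.0)
        params = SegmentationParams()
        n_checked = 0
        for seed in (1, 2):
            spec = SceneSpec(
                mode="ministacks",
                field_size_nm=(1431.0, 7000.0, 7000.0),
                n_ministacks=10,
                category_probs=(0.4, 0.25, 0.2, 0.15),
            )
            gt = build_scene(spec, seed=seed)
            stack = render(
                gt, psf, gain=4.0, background=0.0, noiseless=True,
                channels=[*MARKERS, "cargoA", "cargoB"],
            )
            surf = {n: segment_channel(stack, n, params) for n in stack.channel_names}
            region = make_region_mask([surf[m] for m in MARKERS], "golgi")
            det = detect_ministacks(region, voxel_nm=VOXEL)
            table = classify_cooccurrence(det, surf["cargoA"], surf["cargoB"])
            assert det.n_stacks == 10
            # match detected stacks to generated ones by lateral centroid
            truth = gt.ministack_table
            for _, row in table.table.iterrows():
                d = np.hypot(
                    truth["center_y_nm"] - row["y_nm"], truth["center_x_nm"] - row["x_nm"]
                )
                j = int(np.argmin(d))
                assert d.iloc[j] < 500.0
                assert row["category"] == truth["category"].iloc[j]
                n_checked += 1
        assert n_checked == 20

    def test_dispersal_preserves_coloc_coefficient(self):
        """Coefficients inside a dispersed-stack region track the ribbon-scene
        coefficients at matched mixing: breaking up the ribbon does not by
        itself create or destroy cargo segregation."""
        psf = make_psf(150.0, 400.0)
        params = SegmentationParams()

        def mean_c1(mode, seeds, **kw):
            vals = []
            for seed in seeds:
                spec = SceneSpec(mode=mode, mixing=0.5, **kw)
                gt = build_scene(spec, seed=seed)
                stack = render(gt, psf, gain=4.0, background=2.0, read_noise_sd=2.0,
                               seed=seed + 100, channels=["trans", "cargoA", "cargoB"])
                surf = {n: segment_channel(stack, n, params) for n in stack.channel_names}
                region = make_region_mask([surf["trans"]], "golgi")
                res = coloc_coefficients(surf["cargoA"], surf["cargoB"], region)
                vals.append(res.coefficient1)
            return np.array(vals)

        ribbon = mean_c1(
            "ribbon", range(6),
            field_size_nm=(1431.0, 5000.0, 5000.0),
            ribbon_radius_nm=1300.0,
        )
        dispersed = mean_c1(
            "ministacks", range(6),
            field_size_nm=(1431.0, 7000.0, 7000.0),
            n_ministacks=10,
        )
        sem = np.sqrt(ribbon.std(ddof=1) ** 2 / 6 + dispersed.std(ddof=1) ** 2 / 6)
        assert abs(ribbon.mean() - dispersed.mean()) <= 3 * max(sem, 0.02)
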