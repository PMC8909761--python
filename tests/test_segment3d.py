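"""Segmentation chain: upper-Otsu thresholding against a brute-force
between-class-variance oracle, erosion/speckle conventions, labeling and
volumetry arithmetic, and recovery of generator truth."""

import numpy as np
import pandas as pd
import pytest

from mitomorph.scene import VolumeFrame
from mitomorph.segment3d import (
    calibrate_shell_correction,
    erode3d,
    label_and_measure,
    remove_speckles,
    run_segmentation,
    surface_areas,
    upper_otsu_threshold,
)
from mitomorph.synth import SceneSpec3D, make_volume_series


def brute_force_multiotsu_upper(values, counts):
    """Exhaustive 3-class Otsu on a discrete histogram: maximize
    between-class variance over all threshold pairs, return the upper one."""
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    best, best_pair = -np.inf, None
    for i in range(len(values) - 2):
        for j in range(i + 1, len(values) - 1):
            groups = [slice(0, i + 1), slice(i + 1, j + 1), slice(j + 1, None)]
            var = 0.0
            for g in groups:
                w = counts[g].sum()
                if w == 0:
                    continue
                mu = (values[g] * counts[g]).sum() / w
                var += w / total * mu**2
            if var > best:
                best, best_pair = var, (values[i], values[j])
    return best_pair[1]


def _frame(arr, voxel=0.2):
    return VolumeFrame(intensity=np.asarray(arr, float), voxel_size=(voxel,) * 3)


class TestUpperOtsu:
    def test_three_level_scene_keeps_core_only(self):
        rng = np.random.default_rng(0)
        vol = np.zeros((20, 20, 20))
        flat = vol.reshape(-1)
        idx = rng.permutation(flat.size)
        flat[idx[:500]] = 50.0  # halo
        flat[idx[500:700]] = 200.0  # core
        binary, thr = upper_otsu_threshold(_frame(vol))
        counts = [int((vol == v).sum()) for v in (0.0, 50.0, 200.0)]
        oracle_upper = brute_force_multiotsu_upper([0.0, 50.0, 200.0], counts)
        assert 50.0 <= thr < 200.0 and thr >= oracle_upper - 1e-9
        assert binary.sum() == 200
        assert np.all(vol[binary] == 200.0)

    def test_binary_volume_falls_back_with_warning(self):
        vol = np.zeros((10, 10, 10))
        vol[:2] = 80.0
        with pytest.warns(UserWarning, match="single Otsu"):
            binary, thr = upper_otsu_threshold(_frame(vol))
        assert np.array_equal(binary, vol == 80.0)

    def test_intensity_rescaling_preserves_mask(self, static_volume_scene):
        _, series, _ = static_volume_scene
        f = series.frame(0)
        b1, _ = upper_otsu_threshold(f)
        b2, _ = upper_otsu_threshold(_frame(f.intensity * 10.0, voxel=0.15))
        assert np.array_equal(b1, b2)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            upper_otsu_threshold(_frame(np.ones((5, 5, 5))))


class TestErode3D:
    def test_cube_eroded_by_cube(self):
        vol = np.zeros((9, 9, 9), bool)
        vol[2:7, 2:7, 2:7] = True
        out = erode3d(vol, 3)
        assert out.sum() == 27
        assert out[3:6, 3:6, 3:6].all()

    def test_thin_slab_vanishes(self):
        vol = np.zeros((9, 9, 9), bool)
        vol[4:6, 1:8, 1:8] = True  # 2 voxels thick
        assert erode3d(vol, 3).sum() == 0

    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(1)
        vol = rng.random((6, 6, 6)) > 0.5
        assert np.array_equal(erode3d(vol, 1), vol)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            erode3d(np.ones((4, 4, 4), bool), 2)


class TestRemoveSpeckles:
    def test_size_threshold_is_exactly_ten(self):
        # components of sizes {5, 9, 10, 30}: only 10 and 30 survive
        lab = np.zeros((4, 10, 40), int)
        lab[0, 0, :5] = 1
        lab[1, 1, :9] = 2
        lab[2, 2, :10] = 3
        lab[3, 3, :30] = 4
        out = remove_speckles(lab, min_voxels=10)
        sizes = np.bincount(out.ravel())[1:]
        assert sorted(sizes.tolist()) == [10, 30]
        # renumbered consecutively by decreasing size
        assert (out == 1).sum() == 30 and (out == 2).sum() == 10

    def test_all_large_identity_up_to_renumbering(self):
        lab = np.zeros((3, 5, 20), int)
        lab[0, 0, :12] = 5
        lab[1, 1, :15] = 9
        out = remove_speckles(lab)
        assert set(np.unique(out)) == {0, 1, 2}
        assert (out > 0).sum() == 27

    def test_single_small_component_empties_volume(self):
        lab = np.zeros((3, 3, 9), int)
        lab[1, 1, :9] = 1
        assert remove_speckles(lab).max() == 0


class TestLabelAndMeasure:
    def test_two_cubes_volume_arithmetic(self):
        vol = np.zeros((10, 10, 20), int)
        vol[2:6, 2:6, 2:6] = 1
        vol[2:6, 2:6, 12:16] = 1
        labeled, table = label_and_measure(vol, voxel_size=(0.2, 0.2, 0.2))
        assert len(table) == 2
        assert np.allclose(table["volume_um3"], 64 * 0.008)
        assert np.allclose(table["voxel_count"], 64)

    def test_connectivity_convention(self):
        vol = np.zeros((4, 4, 4), int)
        vol[0, 0, 0] = 1
        vol[1, 1, 1] = 1  # diagonal touch
        _, t26 = label_and_measure(vol, (1, 1, 1), connectivity=26)
        _, t6 = label_and_measure(vol, (1, 1, 1), connectivity=6)
        assert len(t26) == 1 and len(t6) == 2

    def test_total_voxel_count_matches_foreground(self, static_volume_scene):
        spec, _, truth = static_volume_scene
        binary = (truth.labels[0] > 0).astype(int)
        labeled, table = label_and_measure(binary, spec.voxel_size)
        assert table["voxel_count"].sum() == binary.sum()

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            label_and_measure(np.full((3, 3, 3), 7), (1, 1, 1))

    def test_enlarging_objects_increases_measured_volumes(self, static_volume_scene):
        from scipy import ndimage as ndi

        spec, _, truth = static_volume_scene
        binary = truth.labels[0] > 0
        dilated = ndi.binary_dilation(binary, ndi.generate_binary_structure(3, 1))
        _, t0 = label_and_measure(binary.astype(int), spec.voxel_size)
        _, t1 = label_and_measure(dilated.astype(int), spec.voxel_size)
        m0 = t0.set_index(
            t0[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].round(0)
            .apply(tuple, axis=1)
        )["volume_um3"]
        m1 = t1.set_index(
            t1[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].round(0)
            .apply(tuple, axis=1)
        )["volume_um3"]
        common = m0.index.intersection(m1.index)
        assert len(common) >= 10
        assert (m1[common].to_numpy() > m0[common].to_numpy()).all()


class TestSurfaceAreas:
    def test_cube_surface_exact(self):
        lab = np.zeros((8, 8, 8), int)
        lab[2:6, 2:6, 2:6] = 1
        areas = surface_areas(lab, (0.5, 0.5, 0.5))
        assert areas[1] == pytest.approx(6 * 16 * 0.25)


class TestRunSegmentation:
    def test_noise_only_volume_yields_no_objects(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(10, 2, size=(24, 48, 48)).clip(0)
        _, table = run_segmentation(_frame(vol))
        assert len(table) == 0

    def test_determinism(self, static_volume_scene):
        _, series, _ = static_volume_scene
        _, t1 = run_segmentation(series.frame(0))
        _, t2 = run_segmentation(series.frame(0))
        pd.testing.assert_frame_equal(t1, t2)

    def test_count_recovery_on_separated_scene(self, static_volume_scene):
        spec, series, truth = static_volume_scene
        _, table = run_segmentation(series.frame(0))
        assert len(table) == spec.n_objects

    def test_fragmentation_signature(self, static_volume_scene):
        # splitting every object in two doubles the count and halves the
        # mean volume — the operational signature of a fragmented network
        spec, _, truth = static_volume_scene
        lab = truth.labels[0]
        binary = lab > 0
        split = binary.copy()
        for oid in np.unique(lab)[1:]:
            zz, yy, xx = np.nonzero(lab == oid)
            # cut perpendicular to the longer lateral axis so the removed
            # one-voxel plane is a small fraction of the object
            if np.ptp(xx) >= np.ptp(yy):
                mid = int(np.round(xx.mean()))
                sel = (lab == oid) & (np.arange(lab.shape[2])[None, None, :] == mid)
            else:
                mid = int(np.round(yy.mean()))
                sel = (lab == oid) & (np.arange(lab.shape[1])[None, :, None] == mid)
            split &= ~sel
        _, t_whole = label_and_measure(binary.astype(int), spec.voxel_size)
        _, t_split = label_and_measure(split.astype(int), spec.voxel_size)
        assert len(t_split) == 2 * len(t_whole)
        ratio = t_split["volume_um3"].mean() / t_whole["volume_um3"].mean()
        assert ratio == pytest.approx(0.5, rel=0.10)

    def test_shell_corrected_volumes_match_truth(self, static_volume_scene):
        spec, series, truth = static_volume_scene
        delta = calibrate_shell_correction(
            spec.voxel_size, spec.volume_mean_um3, seed=777
        )
        _, table = run_segmentation(series.frame(0), shell_correction_um=delta)
        tt = truth.table.sort_values("centroid_x_um").reset_index(drop=True)
        mt = table.sort_values("centroid_x_um").reset_index(drop=True)
        assert len(mt) == len(tt)
        # per-object corrected volume within 15 % of the generator truth
        rel = np.abs(
            mt["volume_corrected_um3"].to_numpy() - tt["true_volume_um3"].to_numpy()
        ) / tt["true_volume_um3"].to_numpy()
        assert np.median(rel) < 0.10 and rel.max() < 0.15

    def test_measure_on_eroded_gives_smaller_volumes(self, static_volume_scene):
        _, series, _ = static_volume_scene
        _, t_pre = run_segmentation(series.frame(0), measure_on="threshold")
        _, t_ero = run_segmentation(series.frame(0), measure_on="eroded")
        assert t_ero["volume_um3"].mean() < t_pre["volume_um3"].mean()

    def test_provenance_recorded(self, static_volume_scene):
        _, series, _ = static_volume_scene
        labeled, _ = run_segmentation(series.frame(0))
        prov = labeled.provenance
        assert prov["erosion_kernel"] == 3
        assert prov["min_voxels"] == 10
        assert prov["connectivity"] == 26
        assert prov["threshold"] > 0
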