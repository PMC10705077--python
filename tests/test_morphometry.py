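"""Morphometry: TV mask, volumes, distances, thickness, VOI metrics."""

from dataclasses import replace

import numpy as np
import pytest
from conftest import (
    brute_closing,
    brute_distance_map,
    brute_local_thickness,
    random_mask,
)

from osteovasc.morphometry import (
    compartment_volumes,
    distance_transform,
    local_metrics,
    local_thickness,
    total_volume_mask,
    vmi,
    voi_mask,
)
from osteovasc.phantom import (
    GroupEffect,
    MetastasisSpec,
    PhantomSpec,
    VesselSpec,
    generate_labels,
    voxelize_capsule,
    voxelize_sphere,
)
from osteovasc.volume import BONE, METASTASIS, VESSEL, LabelVolume


def labelize(bone=None, vessel=None, met=None, shape=(16, 16, 16), vs=3.5):
    arr = np.zeros(shape, np.uint8)
    if bone is not None:
        arr[bone] = BONE
    if vessel is not None:
        arr[vessel] = VESSEL
    if met is not None:
        arr[met] = METASTASIS
    return LabelVolume(arr, vs)


class TestTotalVolumeMask:
    def test_solid_cuboid_maps_to_itself(self):
        bone = np.zeros((20, 20, 20), bool)
        bone[5:15, 5:15, 5:15] = True
        labels = labelize(bone=bone, shape=(20, 20, 20))
        tv = total_volume_mask(labels, closing_radius_um=10.5)
        assert np.array_equal(tv, bone)

    def test_hollow_shell_cavity_counts_as_interior(self):
        """Flood-fill-from-border oracle: the enclosed cavity is interior."""
        bone = np.zeros((20, 20, 20), bool)
        bone[4:16, 4:16, 4:16] = True
        bone[6:14, 6:14, 6:14] = False  # closed cavity
        labels = labelize(bone=bone, shape=(20, 20, 20))
        tv = total_volume_mask(labels, closing_radius_um=3.5)
        # oracle: voxels not reachable from the border through background
        from scipy import ndimage as ndi

        outside = np.pad(~bone, 1, constant_values=True)
        lab, _ = ndi.label(outside, structure=ndi.generate_binary_structure(3, 1))
        reach = lab == lab[0, 0, 0]
        interior_oracle = ~reach[1:-1, 1:-1, 1:-1]
        assert np.array_equal(tv, interior_oracle)

    def test_disjoint_blocks_not_bridged(self):
        """Blocks farther apart than the closing diameter stay separate."""
        bone = np.zeros((16, 32, 16), bool)
        bone[4:10, 2:8, 4:10] = True
        bone[4:10, 24:30, 4:10] = True
        labels = labelize(bone=bone, shape=(16, 32, 16), vs=1.0)
        tv = total_volume_mask(labels, closing_radius_um=4.0)
        assert np.array_equal(tv, bone)

    @pytest.mark.parametrize("radius_um", [3.3, 7.7])
    def test_matches_explicit_closing_oracle(self, radius_um):
        rng = np.random.default_rng(8)
        blob = np.zeros((20, 20, 20), bool)
        for _ in range(6):
            c = rng.integers(4, 16, size=3)
            blob |= voxelize_sphere((20, 20, 20), 1.0, c + rng.uniform(-0.5, 0.5, 3), rng.uniform(2, 4))
        labels = labelize(bone=blob, shape=(20, 20, 20), vs=1.0)
        tv = total_volume_mask(labels, closing_radius_um=radius_um)
        from scipy import ndimage as ndi

        closed = brute_closing(blob, radius_um, 1.0) | blob
        # hole filling with capped axial faces, mirroring the crop convention
        capped = np.pad(closed, ((1, 1), (0, 0), (0, 0)), constant_values=True)
        oracle = ndi.binary_fill_holes(capped)[1:-1]
        assert np.array_equal(tv, oracle)

    def test_superset_of_bone_always(self, default_phantom):
        labels, _ = default_phantom
        tv = total_volume_mask(labels)
        assert not (labels.mask(BONE) & ~tv).any()

    def test_empty_bone_is_an_error(self):
        labels = labelize(shape=(8, 8, 8))
        with pytest.raises(ValueError, match="bone"):
            total_volume_mask(labels)


class TestCompartmentVolumes:
    def test_direct_count_ratio(self):
        bone = np.zeros((10, 10, 10), bool)
        bone[:5, :5, :10] = True  # 250 voxels
        labels = labelize(bone=bone, shape=(10, 10, 10))
        tv = np.ones((10, 10, 10), bool)
        rep = compartment_volumes(labels, tv)
        assert rep.bv_tv == 0.25
        assert rep.mev_tv == 0.0
        assert rep.tv_um3 == pytest.approx(1000 * 3.5**3)

    def test_phantom_volumes_equal_ground_truth_exactly(self, default_phantom):
        labels, truth = default_phantom
        tv = total_volume_mask(labels)
        rep = compartment_volumes(labels, tv)
        vv = labels.voxel_volume_um3
        assert rep.bv_um3 == truth.class_counts[BONE] * vv
        assert rep.vv_um3 == truth.class_counts[VESSEL] * vv
        assert rep.mev_um3 == truth.class_counts[METASTASIS] * vv

    def test_compartments_fit_inside_tv(self, default_phantom):
        labels, _ = default_phantom
        rep = compartment_volumes(labels, total_volume_mask(labels))
        assert rep.bv_voxels + rep.vv_voxels + rep.mev_voxels <= rep.tv_voxels
        for ratio in (rep.bv_tv, rep.vv_tv, rep.mev_tv):
            assert 0.0 <= ratio <= 1.0

    def test_empty_tv_rejected(self):
        labels = labelize(bone=(slice(2, 4),), shape=(8, 8, 8))
        with pytest.raises(ValueError, match="TV"):
            compartment_volumes(labels, np.zeros((8, 8, 8), bool))


class TestDistanceTransform:
    def test_axis_aligned_distance_in_physical_units(self):
        ref = np.zeros((16, 16, 16), bool)
        ref[0, 0, 0] = True
        dmap = distance_transform(ref, 3.5)
        assert dmap.values[10, 0, 0] == pytest.approx(35.0)
        assert dmap.values[0, 0, 0] == 0.0

    @pytest.mark.parametrize("vs", [(1.0, 1.0, 1.0), (3.5, 3.5, 3.5), (1.0, 2.5, 0.7)])
    def test_equals_brute_force_all_pairs(self, vs):
        rng = np.random.default_rng(5)
        ref = random_mask(rng, (16, 16, 16), p=0.03)
        ref[3, 3, 3] = True
        dmap = distance_transform(ref, vs)
        oracle = brute_distance_map(ref, vs)
        np.testing.assert_allclose(dmap.values, oracle, rtol=1e-9, atol=1e-9)

    def test_neighboring_voxels_satisfy_lipschitz_bound(self):
        rng = np.random.default_rng(6)
        ref = random_mask(rng, (12, 12, 12), p=0.05)
        ref[0, 0, 0] = True
        d = distance_transform(ref, (2.0, 1.0, 1.5)).values
        for axis, h in zip(range(3), (2.0, 1.0, 1.5)):
            diff = np.abs(np.diff(d, axis=axis))
            assert diff.max() <= h + 1e-9

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_transform(np.zeros((8, 8, 8), bool), 3.5)


class TestVMI:
    def test_adjacent_voxel_distance(self):
        vessel = np.zeros((8, 8, 8), bool)
        met = np.zeros((8, 8, 8), bool)
        vessel[4, 4, 4] = True
        met[5, 4, 4] = True
        mean, dmap = vmi(vessel, met, 3.5)
        assert mean == pytest.approx(3.5)

    def test_vessels_inside_metastases_give_zero(self):
        met = np.zeros((8, 8, 8), bool)
        met[2:6, 2:6, 2:6] = True
        vessel = np.zeros((8, 8, 8), bool)
        vessel[3:5, 3:5, 3:5] = True
        mean, _ = vmi(vessel, met, 3.5)
        assert mean == 0.0

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(7)
        vessel = random_mask(rng, (14, 14, 14), p=0.1)
        met = random_mask(rng, (14, 14, 14), p=0.05)
        vessel[2, 2, 2] = met[10, 10, 10] = True
        mean, dmap = vmi(vessel, met, (3.5, 3.0, 2.5))
        oracle = brute_distance_map(met, (3.5, 3.0, 2.5))
        assert mean == pytest.approx(oracle[vessel].mean(), rel=1e-12)
        np.testing.assert_allclose(dmap.values[vessel], oracle[vessel])

    def test_no_metastases_flagged_undefined_not_zero(self):
        vessel = np.zeros((8, 8, 8), bool)
        vessel[4, 4, 4] = True
        mean, dmap = vmi(vessel, np.zeros((8, 8, 8), bool), 3.5)
        assert mean is None and dmap is None

    def test_empty_vessel_mask_is_an_error(self):
        met = np.zeros((8, 8, 8), bool)
        met[1, 1, 1] = True
        with pytest.raises(ValueError, match="vessel"):
            vmi(np.zeros((8, 8, 8), bool), met, 3.5)


class TestLocalThickness:
    @pytest.mark.parametrize("r", [3, 5, 8])
    def test_sphere_recovery_within_one_voxel(self, r):
        n = 2 * r + 13
        mask = voxelize_sphere((n, n, n), 1.0, (n // 2,) * 3, float(r))
        _, mean = local_thickness(mask, 1.0)
        assert 2 * r - 1 <= mean <= 2 * r + 1

    @pytest.mark.parametrize("r", [3, 5])
    def test_cylinder_median_recovery(self, r):
        n = 2 * r + 12
        mask = voxelize_capsule((40, n, n), 1.0, (2, r + 6, r + 6), (38, r + 6, r + 6), float(r))
        tmap, _ = local_thickness(mask, 1.0)
        mid = tmap.values[12:28][mask[12:28]]
        assert abs(np.median(mid) - 2 * r) <= 1.0

    def test_single_voxel_has_one_voxel_diameter(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[4, 4, 4] = True
        tmap, mean = local_thickness(mask, 3.5)
        assert mean == pytest.approx(3.5)

    @pytest.mark.parametrize("vs", [(1.0, 1.0, 1.0), (1.0, 1.5, 0.8)])
    def test_matches_brute_force_inscribed_sphere_oracle(self, vs):
        rng = np.random.default_rng(9)
        mask = voxelize_sphere((18, 18, 18), vs, (8.2, 7.9, 8.4), 5.5)
        mask |= voxelize_capsule((18, 18, 18), vs, (2, 3, 3), (15, 14, 12), 2.2)
        tmap, _ = local_thickness(mask, vs)
        oracle = brute_local_thickness(mask, vs)
        h_min = min(vs)
        assert np.abs(tmap.values[mask] - oracle[mask]).max() <= h_min + 1e-9

    def test_bounded_by_bounding_box_diagonal(self, default_phantom):
        labels, _ = default_phantom
        mask = labels.mask(VESSEL)
        tmap, _ = local_thickness(mask, labels.voxel_size_um)
        diag = np.linalg.norm(np.array(labels.shape) * np.array(labels.voxel_size_um))
        assert tmap.values.max() <= diag
        assert (tmap.values[mask] > 0).all()

    @pytest.mark.parametrize("r_vox", [3.0, 5.0])
    def test_parameter_recovery_on_cylinder_tree(self, r_vox):
        """Mean V.Th on a lattice-aligned cylinder tree of known radius falls
        within one voxel of the true tube diameter.  (Obliquely oriented tubes
        read up to about one voxel lower under the half-voxel surface
        convention; see the methods note.)"""
        h = 3.5
        r = r_vox * h
        shape = (48, 48, 48)
        tree = voxelize_capsule(shape, h, (4 * h, 24 * h, 24 * h), (44 * h, 24 * h, 24 * h), r)
        tree |= voxelize_capsule(shape, h, (24 * h, 6 * h, 24 * h), (24 * h, 42 * h, 24 * h), r)
        tree |= voxelize_capsule(shape, h, (14 * h, 24 * h, 8 * h), (14 * h, 24 * h, 40 * h), r)
        _, mean = local_thickness(tree, h)
        assert 2 * r - h <= mean <= 2 * r + h

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            local_thickness(np.zeros((8, 8, 8), bool), 1.0)


class TestVoiMask:
    @pytest.fixture()
    def met_tv(self):
        met = np.zeros((20, 20, 20), bool)
        met[9:11, 9:11, 9:11] = True
        tv = np.zeros((20, 20, 20), bool)
        tv[2:18, 2:18, 2:18] = True
        return met, tv

    def test_sub_voxel_threshold_keeps_only_metastasis(self, met_tv):
        met, tv = met_tv
        voi = voi_mask(met, tv, 1.0, 3.5)
        assert np.array_equal(voi, met & tv)

    def test_huge_threshold_recovers_tv(self, met_tv):
        met, tv = met_tv
        voi = voi_mask(met, tv, 1e6, 3.5)
        assert np.array_equal(voi, tv)

    def test_monotone_in_threshold(self, met_tv):
        met, tv = met_tv
        counts = [voi_mask(met, tv, t, 3.5).sum() for t in (5, 20, 40, 80, 200)]
        assert counts == sorted(counts)

    def test_counts_match_brute_force_strict_inequality(self, met_tv):
        met, tv = met_tv
        oracle = brute_distance_map(met, 3.5)
        for t in (10.0, 35.0, 70.0):
            voi = voi_mask(met, tv, t, 3.5)
            assert voi.sum() == ((oracle < t) & tv).sum()
            assert np.array_equal(voi, (oracle < t) & tv)

    def test_no_metastases_is_undefined(self, met_tv):
        _, tv = met_tv
        with pytest.raises(ValueError, match="undefined"):
            voi_mask(np.zeros_like(tv), tv, 700.0, 3.5)


class TestLocalMetrics:
    def test_voi_equal_to_tv_reproduces_global_metrics(self, default_phantom):
        labels, _ = default_phantom
        tv = total_volume_mask(labels)
        thickness, vth = local_thickness(labels.mask(VESSEL), labels.voxel_size_um)
        rep_global = compartment_volumes(labels, tv, vth_um=vth)
        rep_local = local_metrics(labels, tv, thickness=thickness)
        assert rep_local.vv_tv == pytest.approx(
            (labels.mask(VESSEL) & tv).sum() / tv.sum()
        )
        vessel_in_tv = labels.mask(VESSEL) & tv
        assert rep_local.vth_um == pytest.approx(thickness.values[vessel_in_tv].mean())
        # the phantom keeps vessels inside the envelope, so this equals global
        assert rep_local.vv_voxels == rep_global.vv_voxels

    def test_voi_without_vessels_flags_undefined_thickness(self):
        bone = np.zeros((12, 12, 12), bool)
        bone[2:10, 2:10, 2:10] = True
        vessel = np.zeros_like(bone)
        vessel[0, 0, 0] = True
        labels = labelize(bone=bone & ~vessel, vessel=vessel, shape=(12, 12, 12))
        voi = np.zeros_like(bone)
        voi[4:8, 4:8, 4:8] = True
        rep = local_metrics(labels, voi)
        assert rep.vv_tv == 0.0
        assert rep.vth_um is None
        assert "vth" in rep.undefined

    def test_local_thinning_effect_detected(self):
        """Vessel radii shrunk 0.6x within 700 µm of lesions lower the local
        V.Th inside the VOI below the global mean (14 µm voxels make the
        700 µm VOI a strict sub-volume of the grid)."""
        spec = PhantomSpec(
            seed=13,
            voxel_size_um=(14.0, 14.0, 14.0),
            grid_shape=(96, 64, 64),
            shell=replace(PhantomSpec().shell, outer_radius_um=360.0, wall_thickness_um=100.0),
            trabeculae=replace(PhantomSpec().trabeculae, rod_radius_um=24.0),
            vessels=VesselSpec(branch_count=8, radius_range_um=(28.0, 48.0), min_length_um=500.0),
            metastases=MetastasisSpec(lesion_count=1, semi_axis_range_um=(72.0, 152.0)),
        )
        effect = GroupEffect("C", 2, vessel_radius_factor=0.6, effect_distance_um=700.0)
        labels, truth = generate_labels(spec, effect=effect)
        assert any(s["in_effect"] for s in truth.segments)
        assert not all(s["in_effect"] for s in truth.segments)
        tv = total_volume_mask(labels)
        thickness, vth_global = local_thickness(labels.mask(VESSEL), labels.voxel_size_um)
        voi = voi_mask(labels.mask(METASTASIS), tv, 700.0, labels.voxel_size_um)
        assert voi.sum() < tv.sum()
        rep = local_metrics(labels, voi, thickness=thickness)
        assert rep.vth_um < vth_global

    def test_translation_invariance(self):
        """Shifting all structures by a whole-voxel offset leaves every
        reported value unchanged."""
        spec = PhantomSpec(seed=17, grid_shape=(40, 48, 48))
        labels, _ = generate_labels(spec)
        volumes = []
        for off in ((2, 3, 2), (6, 1, 4)):
            big = np.zeros((52, 56, 58), np.uint8)
            sl = tuple(slice(o, o + s) for o, s in zip(off, labels.shape))
            big[sl] = labels.data
            volumes.append(LabelVolume(big, labels.voxel_size_um))
        reports = []
        for vol in volumes:
            tv = total_volume_mask(vol)
            th, vth = local_thickness(vol.mask(VESSEL), vol.voxel_size_um)
            m, _ = vmi(vol.mask(VESSEL), vol.mask(METASTASIS), vol.voxel_size_um)
            rep = compartment_volumes(vol, tv, vth_um=vth, vmi_um=m)
            reports.append(rep.as_dict())
        a, b = reports
        for key in a:
            if isinstance(a[key], float):
                assert a[key] == pytest.approx(b[key], rel=1e-6), key
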