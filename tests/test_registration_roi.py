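import numpy as np
import pytest

import phantomcal as pc
from phantomcal.errors import GeometryError, ParameterError
from phantomcal.synthetic_ct import CORTICAL, IMPLANT, MARROW, TRABECULAR

from conftest import label_volume


def rotation_z(deg):
    a = np.radians(deg)
    return np.array(
        [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
    )


class TestFCS:
    def test_canonical_landmarks_give_identity_frame(self):
        fcs = pc.define_fcs([100.0, 0, 0], [0.0, 0, 0], [0.0, 0, 50.0])
        np.testing.assert_allclose(fcs.si, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fcs.ml_axis, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(np.cross(fcs.ml_axis, fcs.ap), fcs.si, atol=1e-12)

    def test_rotated_landmarks_give_the_applied_rotation(self):
        R = rotation_z(30.0)
        head, cond, lat = [100.0, 0, 0], [0.0, 0, 0], [0.0, 0, 50.0]
        fcs = pc.define_fcs(R @ head, R @ cond, R @ lat)
        ref = pc.define_fcs(head, cond, lat)
        np.testing.assert_allclose(fcs.rotation, ref.rotation @ R.T, atol=1e-6)

    def test_side_flag_flips_the_lateral_direction_sign(self):
        args = ([100.0, 0, 0], [0.0, 0, 0], [0.0, 0, 50.0])
        right = pc.define_fcs(*args, side="right")
        left = pc.define_fcs(*args, side="left")
        np.testing.assert_allclose(left.lateral_direction, -right.lateral_direction)
        np.testing.assert_allclose(left.ml_axis, right.ml_axis)

    def test_collinear_landmarks_rejected(self):
        with pytest.raises(GeometryError):
            pc.define_fcs([100.0, 0, 0], [0.0, 0, 0], [50.0, 0, 0])


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ParameterError):
            pc.RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_inverse_round_trips_points(self):
        t = pc.RigidTransform(rotation_z(17.0), [1.0, -2.0, 3.0])
        pts = np.random.default_rng(0).normal(size=(10, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)


class TestICP:
    @pytest.fixture(scope="class")
    def surface_points(self, femur_gt):
        from scipy import ndimage

        cort = femur_gt.labels.voxels == CORTICAL
        surf = cort & ~ndimage.binary_erosion(cort)
        idx = np.argwhere(surf)[::7].astype(float)
        return idx * np.array(femur_gt.labels.spacing)

    def test_identical_point_sets_give_identity(self, surface_points):
        res = pc.icp_rigid_register(surface_points, surface_points)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.transform.translation, 0.0, atol=1e-9)
        assert res.rms_mm < 1e-9

    def test_recovers_a_five_degree_two_millimetre_motion(self, surface_points):
        R = rotation_z(5.0)
        t = np.array([2.0, 1.0, 0.0])
        target = surface_points @ R.T + t
        res = pc.icp_rigid_register(surface_points, target)
        cos_angle = np.clip((np.trace(res.transform.rotation @ R.T) - 1) / 2, -1, 1)
        assert np.degrees(np.arccos(cos_angle)) < 0.1
        assert np.linalg.norm(res.transform.translation - t) < 0.05

    def test_pure_translation_with_exact_correspondences_is_closed_form(self):
        pts = np.random.default_rng(1).normal(size=(50, 3))
        res = pc.icp_rigid_register(pts, pts + [3.0, -1.0, 0.5])
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.transform.translation, [3.0, -1.0, 0.5], atol=1e-9)

    def test_collinear_point_sets_rejected(self):
        line = np.outer(np.arange(10.0), [1.0, 0, 0])
        with pytest.raises(GeometryError):
            pc.icp_rigid_register(line, line + [1.0, 0, 0])


class TestTransferROI:
    def test_identity_transform_same_grid_is_identity(self, femur_small):
        roi = femur_small.labels
        out = pc.transfer_roi(
            roi, pc.RigidTransform.identity(), roi.shape, roi.spacing, roi.origin
        )
        assert np.array_equal(out.voxels, roi.voxels)

    def test_round_trip_translation_preserves_in_grid_labels(self, femur_small):
        # content that leaves the grid is documented to become 0, so the
        # round-trip claim applies to voxels whose image stays in-grid
        roi = femur_small.labels
        t = pc.RigidTransform(np.eye(3), [0.37, -0.21, 0.09])
        fwd = pc.transfer_roi(roi, t, roi.shape, roi.spacing, roi.origin)
        back = pc.transfer_roi(fwd, t.inverse(), roi.shape, roi.spacing, roi.origin)
        nonzero = roi.voxels > 0
        moved = t.apply(
            np.argwhere(nonzero).astype(float) * np.array(roi.spacing)
            + np.array(roi.origin)
        )
        sp = np.array(roi.spacing)
        lo = np.array(roi.origin) + sp  # one-pitch margin absorbs NN rounding
        hi = np.array(roi.origin) + (np.array(roi.shape) - 2) * sp
        in_grid = np.all((moved >= lo) & (moved <= hi), axis=1)
        preserved = (back.voxels == roi.voxels)[nonzero][in_grid].mean()
        assert preserved >= 0.99

    def test_rotation_round_trip_errors_confined_to_the_roi_boundary(self, femur_small):
        from scipy import ndimage

        solid = label_volume(femur_small.labels.voxels > 0, femur_small.labels.spacing)
        center = (np.array(solid.shape) - 1) / 2 * np.array(solid.spacing)
        R = rotation_z(5.0)
        t = pc.RigidTransform(R, center - R @ center + [0.4, 0.3, -0.2])
        fwd = pc.transfer_roi(solid, t, solid.shape, solid.spacing, solid.origin)
        back = pc.transfer_roi(fwd, t.inverse(), solid.shape, solid.spacing, solid.origin)
        mismatch = back.voxels != solid.voxels
        b = solid.voxels > 0
        boundary = ndimage.binary_dilation(b) & ~ndimage.binary_erosion(b)
        near_boundary = ndimage.binary_dilation(boundary, iterations=2)
        # ignore content clipped at the grid faces
        interior = np.zeros_like(b)
        interior[4:-4, 4:-4, 4:-4] = True
        assert not (mismatch & interior & ~near_boundary).any()

    def test_volume_preserved_on_a_coarser_grid(self, femur_small):
        roi = label_volume(
            femur_small.labels.voxels == CORTICAL, femur_small.labels.spacing
        )
        coarse_shape = tuple(s // 2 for s in roi.shape)
        coarse_spacing = tuple(s * 2 for s in roi.spacing)
        coarse_origin = tuple(o + s / 2 for o, s in zip(roi.origin, roi.spacing))
        out = pc.transfer_roi(
            roi, pc.RigidTransform.identity(), coarse_shape, coarse_spacing, coarse_origin
        )
        vol_fine = (roi.voxels > 0).sum() * roi.voxel_volume_mm3
        vol_coarse = (out.voxels > 0).sum() * out.voxel_volume_mm3
        assert vol_coarse == pytest.approx(vol_fine, rel=0.05)


@pytest.fixture(scope="module")
def implanted(femur_gt, stage_params):
    broached = pc.apply_broaching(femur_gt, stage_params)
    return pc.insert_implant(broached, stage_params)


@pytest.fixture(scope="module")
def fcs():
    # shaft axis = array axis 0; lateral = +x
    return pc.define_fcs([60.0, 8.0, 8.0], [-300.0, 8.0, 8.0], [-300.0, 8.0, 40.0])


@pytest.fixture(scope="module")
def zone_inputs(implanted):
    spacing = implanted.labels.spacing
    implant_mask = label_volume(implanted.labels.voxels == IMPLANT, spacing)
    domain = label_volume(
        implanted.labels.mask(MARROW, TRABECULAR, CORTICAL), spacing
    )
    return implant_mask, domain


class TestGruenZones:
    def test_boundaries_at_exact_thirds_of_implant_length(self, implanted, fcs, zone_inputs):
        implant_mask, domain = zone_inputs
        rois = pc.define_gruen_zones(implant_mask, fcs, domain)
        spacing = implanted.labels.spacing
        imp_z = np.argwhere(implant_mask.voxels > 0)[:, 0] * spacing[0]
        z_min, z_max = imp_z.min(), imp_z.max()
        length = z_max - z_min
        # zone 2 (lateral middle) should span exactly the middle third in z
        z2 = np.argwhere(rois.zones.voxels == 2)[:, 0] * spacing[0]
        assert z2.min() == pytest.approx(z_min + length / 3, abs=2 * spacing[0])
        assert z2.max() == pytest.approx(z_min + 2 * length / 3, abs=2 * spacing[0])
        # zone 4 lies distal to the implant tip (the tilted principal axis can
        # place same-slice voxels marginally below the tip)
        z4 = np.argwhere(rois.zones.voxels == 4)[:, 0] * spacing[0]
        assert z4.max() <= z_min + spacing[0]

    def test_zones_partition_the_periprosthetic_domain(self, fcs, zone_inputs):
        implant_mask, domain = zone_inputs
        rois = pc.define_gruen_zones(implant_mask, fcs, domain)
        inside = domain.voxels > 0
        imp_z = np.argwhere(implant_mask.voxels > 0)[:, 0]
        covered = rois.zones.voxels > 0
        # within the implant's axial extent every domain voxel has a zone
        span = np.zeros_like(inside)
        span[imp_z.min() + 1 : imp_z.max()] = True  # interior slices of the implant span
        assert np.all(covered[inside & span])
        assert not covered[~inside].any()

    def test_mirroring_the_side_swaps_lateral_and_medial_zones(self, fcs, zone_inputs):
        implant_mask, domain = zone_inputs
        right = pc.define_gruen_zones(implant_mask, fcs, domain)
        left_fcs = pc.define_fcs(
            [60.0, 8.0, 8.0], [-300.0, 8.0, 8.0], [-300.0, 8.0, 40.0], side="left"
        )
        left = pc.define_gruen_zones(implant_mask, left_fcs, domain)
        swap = {1: 7, 2: 6, 3: 5, 5: 3, 6: 2, 7: 1, 4: 4, 0: 0}
        remapped = np.vectorize(swap.get)(right.zones.voxels)
        assert np.array_equal(remapped, left.zones.voxels)

    def test_empty_implant_mask_rejected(self, zone_inputs, fcs):
        _, domain = zone_inputs
        empty = label_volume(np.zeros(domain.shape), domain.spacing)
        with pytest.raises(ParameterError):
            pc.define_gruen_zones(empty, fcs, domain)


class TestInterfaceShell:
    def test_one_pitch_thickness_gives_a_one_voxel_rind(self):
        mask = np.zeros((9, 9, 9))
        mask[3:6, 3:6, 3:6] = 1
        m = label_volume(mask, (1.0, 1.0, 1.0))
        dom = label_volume(np.ones((9, 9, 9)), (1.0, 1.0, 1.0))
        shell = pc.interface_shell(m, 1.0, dom)
        from scipy.ndimage import binary_dilation

        expected = binary_dilation(mask > 0) & ~(mask > 0)
        assert np.array_equal(shell.voxels > 0, expected)

    def test_cylindrical_annulus_volume_matches_analytic_formula(self):
        # fine spacing keeps the voxel-center distance bias (~0.3 voxel pitch)
        # well inside the tolerance
        shape, spacing = (30, 170, 170), (0.08, 0.08, 0.08)
        yy, xx = np.meshgrid(np.arange(170) * 0.08, np.arange(170) * 0.08, indexing="ij")
        c = (169 * 0.08) / 2
        cyl = np.broadcast_to(np.hypot(yy - c, xx - c) <= 5.0, shape).copy()
        m = label_volume(cyl, spacing)
        dom = label_volume(np.ones(shape), spacing)
        shell = pc.interface_shell(m, 1.0, dom)
        # ignore the axial end caps by restricting to inner slices
        inner = slice(5, 25)
        got = (shell.voxels[inner] > 0).sum() * np.prod(spacing)
        h = 20 * spacing[0]
        analytic = np.pi * ((5.0 + 1.0) ** 2 - 5.0**2) * h
        assert got == pytest.approx(analytic, rel=0.03)

    def test_non_positive_thickness_rejected(self):
        m = label_volume(np.ones((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ParameterError):
            pc.interface_shell(m, 0.0, m)


class TestBVTV:
    def test_all_bone_roi_is_one(self):
        ones = label_volume(np.ones((4, 4, 4)), (1, 1, 1))
        assert pc.bv_tv(ones, ones) == 1.0

    def test_half_bone_roi_is_half(self):
        bone = np.zeros((4, 4, 4))
        bone[:2] = 1
        assert pc.bv_tv(label_volume(bone, (1, 1, 1)),
                        label_volume(np.ones((4, 4, 4)), (1, 1, 1))) == 0.5

    def test_empty_roi_rejected(self):
        ones = label_volume(np.ones((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ParameterError):
            pc.bv_tv(ones, label_volume(np.zeros((4, 4, 4)), (1, 1, 1)))

    def test_shell_bvtv_increases_iff_debris_is_retained(self, femur_gt, stage_params):
        from dataclasses import replace

        spacing = femur_gt.labels.spacing
        for retention, cmp in ((0.0, "eq"), (0.6, "gt")):
            stage = replace(stage_params, debris_retention=retention)
            broached = pc.apply_broaching(femur_gt, stage)
            cav = label_volume(broached.labels.voxels == pc.synthetic_ct.CAVITY, spacing)
            dom_pre = label_volume(femur_gt.labels.mask(MARROW, TRABECULAR), spacing)
            dom_post = label_volume(broached.labels.mask(MARROW, TRABECULAR), spacing)
            shell = pc.interface_shell(cav, stage.shell_thickness_mm, dom_post)
            shell_pre = pc.interface_shell(cav, stage.shell_thickness_mm, dom_pre)
            bv_pre = pc.bv_tv(
                label_volume(femur_gt.labels.voxels == TRABECULAR, spacing), shell_pre
            )
            bv_post = pc.bv_tv(
                label_volume(broached.labels.voxels == TRABECULAR, spacing), shell
            )
            if cmp == "eq":
                assert bv_post == pytest.approx(bv_pre, abs=1e-12)
            else:
                assert bv_post > bv_pre


class TestZoneSummary:
    def test_uniform_density_gives_equal_zone_means(self, fcs, zone_inputs):
        implant_mask, domain = zone_inputs
        rois = pc.define_gruen_zones(implant_mask, fcs, domain)
        uniform = pc.VolumeImage(
            np.full(domain.shape, 1.5), domain.spacing, unit_tag="g/cc"
        )
        summ = pc.zone_density_summary(uniform, rois, domain)
        assert np.allclose(summ["mean_density_roi_gcc"], 1.5)

    def test_zone_means_match_voxel_list_oracle(self, implanted, fcs, zone_inputs):
        implant_mask, domain = zone_inputs
        rois = pc.define_gruen_zones(implant_mask, fcs, domain)
        bone = label_volume(implanted.labels.mask(TRABECULAR, CORTICAL),
                            implanted.labels.spacing)
        summ = pc.zone_density_summary(implanted.density, rois, bone)
        for z in (1, 4, 6):
            zm = rois.zones.voxels == z
            oracle = implanted.density.voxels[zm & (bone.voxels > 0)].mean()
            assert summ.loc[z, "mean_density_bone_gcc"] == pytest.approx(oracle, rel=1e-9)

    def test_zones_invariant_to_rigid_motion_up_to_resampling(self, fcs, zone_inputs):
        """Defining zones after a rigid motion equals moving the zones, away
        from a 2-voxel boundary shell (1 voxel of nearest-neighbour
        resampling + 1 voxel of implant-tip quantisation)."""
        from scipy import ndimage

        implant_mask, domain = zone_inputs
        rois = pc.define_gruen_zones(implant_mask, fcs, domain)
        shape, spacing, origin = domain.shape, domain.spacing, domain.origin
        center = (np.array(shape) - 1) / 2 * np.array(spacing)
        R = rotation_z(10.0)
        t = pc.RigidTransform(R, center - R @ center + [0.5, 0.4, -0.3])
        imp_t = pc.transfer_roi(implant_mask, t, shape, spacing, origin)
        dom_t = pc.transfer_roi(domain, t, shape, spacing, origin)
        fcs_t = pc.define_fcs(
            t.apply([60.0, 8.0, 8.0])[0],
            t.apply([-300.0, 8.0, 8.0])[0],
            t.apply([-300.0, 8.0, 40.0])[0],
        )
        zones_of_transformed = pc.define_gruen_zones(imp_t, fcs_t, dom_t).zones
        transformed_zones = pc.transfer_roi(rois.zones, t, shape, spacing, origin)
        both = (zones_of_transformed.voxels > 0) & (transformed_zones.voxels > 0)
        shell = ndimage.grey_dilation(transformed_zones.voxels, size=5) != (
            ndimage.grey_erosion(transformed_zones.voxels, size=5)
        )
        interior = both & ~shell
        agree = (zones_of_transformed.voxels == transformed_zones.voxels)[interior].mean()
        assert agree >= 0.995
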