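"""Surrogate generator, ground-truth cases, perturbations, CT phantoms."""

import numpy as np
import pytest

from oipf import (
    ICPParams,
    Perturbations,
    RigidTransform,
    SurrogateParams,
    generate_surrogate,
    icp_register,
    make_case,
    reflect_case,
    sample_surface,
    specimen_pose,
    voxelize_phantom,
)
from oipf.errors import InvalidArgumentError
from oipf.synthetic import transform_from_pose_in_frame


class TestSurrogate:
    def test_deterministic(self):
        a, _ = generate_surrogate(seed=1)
        b, _ = generate_surrogate(seed=1)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_regions_labelled(self, implant_mesh):
        assert set(implant_mesh.face_labels) == {
            "body",
            "lateral_extension",
            "appendage",
        }

    def test_shell_is_watertight_and_outward(self, implant_mesh):
        shell = implant_mesh.submesh(
            np.isin(implant_mesh.face_labels, ["body", "lateral_extension"])
        )
        tm = shell.to_trimesh()
        assert tm.is_watertight
        assert tm.is_winding_consistent
        assert tm.volume > 0  # outward normals

    def test_frame_attached_to_geometry(self, surrogate):
        mesh, frame = surrogate
        assert frame.side == "left"
        assert np.allclose(frame.x_axis, [1, 0, 0])
        lo, hi = mesh.bounds()
        for p in frame.key_points.values():
            assert np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9)
        # dorsal tip sits at the far end of the long axis
        assert frame.key_points["dorsal_tip"][0] == pytest.approx(hi[0], abs=1e-9)

    def test_no_rotational_self_symmetry(self, implant_mesh):
        """A 180-degree flip about any centroid axis must not re-register."""
        centroid = implant_mesh.vertices.mean(axis=0)
        src = sample_surface(implant_mesh, 1500, seed=4)
        params = ICPParams(n_samples=1500, max_iterations=60, rms_rel_tolerance=1e-7)
        for angles in [(180, 0, 0), (0, 180, 0), (0, 0, 180)]:
            R = RigidTransform.from_euler_translation(angles, (0, 0, 0))
            shift = centroid - R.rotation @ centroid
            flip = RigidTransform.from_rotation_translation(R.rotation, shift)
            res = icp_register(flip.apply(src.points), implant_mesh, params)
            assert res.rms_residual > 1.0

    def test_area_stable_under_refinement(self):
        coarse, _ = generate_surrogate(SurrogateParams(resolution=1.0))
        fine, _ = generate_surrogate(SurrogateParams(resolution=0.5))
        assert fine.area() == pytest.approx(coarse.area(), rel=0.01)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SurrogateParams(floor_length=0.0)
        with pytest.raises(InvalidArgumentError):
            SurrogateParams(shell_thickness=-1.0)


class TestMakeCase:
    def test_self_certifying_transform(self, surrogate):
        mesh, frame = surrogate
        case = make_case(mesh, frame, specimen_pose("specimen1"), seed=5)
        planned_g = case.T_local_to_global.apply(case.planned.vertices)
        achieved_g = case.T_local_to_global.apply(case.achieved.vertices)
        rebuilt = case.T_planned_to_achieved_global.apply(planned_g)
        assert np.abs(rebuilt - achieved_g).max() < 1e-9

    def test_pose_in_frame_round_trip(self, surrogate):
        mesh, frame = surrogate
        pose = specimen_pose("specimen2")
        T = transform_from_pose_in_frame(frame, pose)
        back = frame.pose_in_frame(T)
        from oipf import decompose_transform

        ang, t = decompose_transform(back)
        assert (ang.yaw, ang.pitch, ang.roll) == pytest.approx(
            (pose.yaw, pose.pitch, pose.roll), abs=1e-9
        )
        assert t == pytest.approx(pose.translation, abs=1e-9)

    def test_occlusion_removes_contiguous_faces(self, surrogate):
        mesh, frame = surrogate
        case = make_case(
            mesh,
            frame,
            specimen_pose("specimen3"),
            Perturbations(occlusion_fraction=0.3),
            seed=6,
        )
        assert case.achieved.n_faces == pytest.approx(0.7 * mesh.n_faces, rel=0.01)

    def test_bend_moves_only_extension(self, surrogate):
        mesh, frame = surrogate
        clean = make_case(mesh, frame, specimen_pose("specimen3"), seed=9)
        bent = make_case(
            mesh,
            frame,
            specimen_pose("specimen3"),
            Perturbations(bend_angle_deg=15.0),
            seed=9,
        )
        labels = clean.achieved.face_labels
        ext_verts = np.unique(clean.achieved.faces[labels == "lateral_extension"])
        body_verts = np.setdiff1d(
            np.unique(clean.achieved.faces[labels == "body"]), ext_verts
        )
        dv = np.linalg.norm(bent.achieved.vertices - clean.achieved.vertices, axis=1)
        assert dv[body_verts].max() < 1e-12
        assert dv[ext_verts].max() > 0.5

    def test_noise_magnitude(self, surrogate):
        mesh, frame = surrogate
        case = make_case(
            mesh,
            frame,
            specimen_pose("specimen3"),
            Perturbations(noise_sigma=0.1),
            seed=12,
        )
        clean = make_case(mesh, frame, specimen_pose("specimen3"), seed=12)
        dv = case.achieved.vertices - clean.achieved.vertices
        assert dv.std() == pytest.approx(0.1, rel=0.05)

    def test_noisy_identity_pose_recovered(self, surrogate, tight_icp):
        """0.1 mm vertex noise: the pipeline stays within 0.3 deg / 0.15 mm."""
        from oipf import PoseParameters, evaluate_placement

        mesh, frame = surrogate
        identity = PoseParameters(yaw=0.0, pitch=0.0, roll=0.0, t_x=0.0, t_y=0.0, t_z=0.0)
        case = make_case(
            mesh, frame, identity, Perturbations(noise_sigma=0.1), seed=71
        )
        rep = evaluate_placement(
            case.planned, case.achieved, case.reference, case.frame, icp=tight_icp
        )
        p = rep.pose
        assert np.abs([p.roll, p.pitch, p.yaw]).max() < 0.3
        assert np.abs(p.translation).max() < 0.15

    def test_invalid_perturbations_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Perturbations(occlusion_fraction=1.0)
        with pytest.raises(InvalidArgumentError):
            Perturbations(noise_sigma=-0.1)

    def test_case_reproducible(self, surrogate):
        mesh, frame = surrogate
        pert = Perturbations(noise_sigma=0.05, occlusion_fraction=0.1)
        a = make_case(mesh, frame, specimen_pose("specimen1"), pert, seed=3)
        b = make_case(mesh, frame, specimen_pose("specimen1"), pert, seed=3)
        assert np.array_equal(a.achieved.vertices, b.achieved.vertices)
        assert np.array_equal(a.planned.vertices, b.planned.vertices)


class TestReflectCase:
    def test_right_twin_well_formed(self, specimen2_case):
        twin = reflect_case(specimen2_case)
        assert twin.side == "right"
        assert twin.frame.side == "right"
        # frame stays right-handed before mirroring is applied
        assert np.allclose(
            np.cross(twin.frame.x_axis, twin.frame.y_axis), twin.frame.z_axis
        )
        assert np.allclose(twin.planned.vertices[:, 1], -specimen2_case.planned.vertices[:, 1])
        assert twin.true_pose.yaw == specimen2_case.true_pose.yaw

    def test_reflecting_right_case_rejected(self, specimen2_case):
        twin = reflect_case(specimen2_case)
        with pytest.raises(InvalidArgumentError):
            reflect_case(twin)


class TestVoxelizePhantom:
    def test_hu_strata_present(self, surrogate):
        mesh, frame = surrogate
        case = make_case(mesh, frame, specimen_pose("specimen3"), seed=41)
        with pytest.warns(UserWarning, match="spacing"):
            ph = voxelize_phantom(case, spacing=0.75, seed=41)
        vals = np.unique(ph.volume.voxels)
        for hu in (-1000.0, 40.0, 700.0, 3000.0):
            assert hu in vals
        assert ph.implant_mask.sum() > 500
        # bone must touch the implant (threshold separation is the hard case)
        from scipy import ndimage

        grown = ndimage.binary_dilation(ph.implant_mask)
        assert np.any(grown & (ph.volume.voxels == 700.0))

    def test_deterministic(self, surrogate):
        mesh, frame = surrogate
        case = make_case(mesh, frame, specimen_pose("specimen3"), seed=42)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = voxelize_phantom(case, spacing=0.75, seed=42)
            b = voxelize_phantom(case, spacing=0.75, seed=42)
        assert np.array_equal(a.volume.voxels, b.volume.voxels)

    def test_fine_spacing_no_dilation_warning(self, surrogate):
        mesh, frame = surrogate
        case = make_case(mesh, frame, specimen_pose("specimen3"), seed=43)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            voxelize_phantom(case, spacing=0.4, seed=43)

    def test_finer_spacing_recovers_better(self, surrogate, tight_icp):
        """Pose recovery degrades monotonically with voxel size (paired seeds)."""
        import warnings

        from oipf import (
            evaluate_placement,
            filter_components,
            mask_to_mesh,
            threshold_segment,
        )

        mesh, frame = surrogate
        icp = ICPParams(n_samples=2000, max_iterations=400, rms_rel_tolerance=1e-8)
        means = {}
        for spacing in (0.4, 0.75):
            errs = []
            for seed in (61, 62):
                case = make_case(mesh, frame, specimen_pose("specimen2"), seed=seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ph = voxelize_phantom(case, spacing=spacing, seed=seed)
                mask = filter_components(threshold_segment(ph.volume), keep="largest")
                achieved = mask_to_mesh(mask, ph.volume)
                rep = evaluate_placement(
                    case.planned, achieved, case.reference, case.frame, icp=icp
                )
                p, tp = rep.pose, case.true_pose
                da = max(abs(p.roll - tp.roll), abs(p.pitch - tp.pitch), abs(p.yaw - tp.yaw))
                dt = np.abs(p.translation - tp.translation).max()
                errs.append(float(np.hypot(da, dt)))
            means[spacing] = float(np.mean(errs))
        assert means[0.75] >= means[0.4]

    def test_invalid_spacing_rejected(self, surrogate):
        mesh, frame = surrogate
        case = make_case(mesh, frame, specimen_pose("specimen3"), seed=44)
        with pytest.raises(InvalidArgumentError):
            voxelize_phantom(case, spacing=0.0)
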