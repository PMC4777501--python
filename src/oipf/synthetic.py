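"""Synthetic fixtures: surrogate implant meshes, posed cases, CT phantoms.

The commercial preformed orbital plate is proprietary, so validation
runs on a parametric surrogate that preserves every property the method
relies on: a thin curved shell with a distinguishable long axis, a
tapering floor, a lateral extension flap, proximal screw-ring
appendages, labelled regions, and no rotational self-symmetry (so ICP
cannot converge to a flipped pose).  Ground-truth cases pose the
surrogate with a known roll/pitch/yaw + translation expressed in the
implant frame, optionally perturbed by vertex noise, contiguous
occlusion or a hinge bend of the lateral extension.  CT phantoms
voxelize the achieved implant into HU strata (air -1000 << soft tissue
40 << bone 700 < 1200 <= implant 3000) with a bony shelf touching the
implant underside, so threshold segmentation is exercised end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError
from .evaluation import PoseParameters, frame_from_landmarks
from .mesh_io import TriangleMesh, sample_surface
from .segmentation import CTVolume
from .transforms import (
    ImplantFrame,
    RigidTransform,
    mirror_for_right_side,
)

#: default HU per tissue class
DEFAULT_HU = {"air": -1000.0, "soft": 40.0, "bone": 700.0, "implant": 3000.0}

#: printed pose parameters of the three cadaver-head cases (deg / mm)
SPECIMEN_POSES: dict[str, dict] = {
    "specimen1": {"roll": -9.3, "pitch": -0.4, "yaw": 11.3, "t": (2.5, -2.7, -0.5)},
    "specimen2": {"roll": -11.2, "pitch": -5.3, "yaw": 0.1, "t": (4.1, -2.9, -0.1)},
    "specimen3": {"roll": -1.1, "pitch": 1.9, "yaw": -7.1, "t": (-0.3, 0.2, -0.4)},
}


def specimen_pose(name: str, side: str = "left") -> PoseParameters:
    """Ground-truth pose for a named specimen preset."""
    if name not in SPECIMEN_POSES:
        raise InvalidArgumentError(
            f"unknown specimen {name!r}; choose from {sorted(SPECIMEN_POSES)}"
        )
    p = SPECIMEN_POSES[name]
    return PoseParameters(
        yaw=p["yaw"],
        pitch=p["pitch"],
        roll=p["roll"],
        t_x=p["t"][0],
        t_y=p["t"][1],
        t_z=p["t"][2],
        side=side,
    )


@dataclass(frozen=True)
class SurrogateParams:
    """Dimensions of the parametric implant surrogate (all mm unless noted)."""

    floor_length: float = 35.0
    width: float = 24.0
    shell_thickness: float = 0.6
    saddle_curvature: float = 0.022  # 1/mm
    lateral_extension: float = 8.0
    n_appendages: int = 3
    appendage_size: float = 2.5
    resolution: float = 1.0  # grid step

    def __post_init__(self):
        for name in (
            "floor_length",
            "width",
            "shell_thickness",
            "lateral_extension",
            "appendage_size",
            "resolution",
        ):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.n_appendages < 0:
            raise InvalidArgumentError("n_appendages must be >= 0")


def _floor_height(x, y, p: SurrogateParams):
    """Saddle-shaped floor profile z(x, y).

    A posterior rise along the long axis plus a transverse saddle and an
    asymmetric S-ripple: the relief of an anatomically preformed plate,
    which is also what makes all six pose parameters observable from the
    surface alone.
    """
    L, W = p.floor_length, p.width
    k = p.saddle_curvature
    return (
        0.5 * k * (x - 0.4 * L) ** 2
        - 0.3 * k * y**2
        + 0.9 * np.sin(2.2 * np.pi * x / L + 0.7)
        + 0.6 * np.sin(1.6 * np.pi * y / W + 0.4) * np.cos(1.1 * np.pi * x / L)
    )


def _halfwidth(x, p: SurrogateParams):
    """Tapering half-width of the floor toward the dorsal tip."""
    return 0.5 * p.width * (1.0 - 0.45 * x / p.floor_length)


def _box_mesh(center, size):
    """Axis-aligned box as 12 triangles (vertices, faces)."""
    c = np.asarray(center, dtype=float)
    h = np.asarray(size, dtype=float) / 2.0
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )
    verts = c + corners * h
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # -x
            [4, 6, 7], [4, 7, 5],  # +x
            [0, 4, 5], [0, 5, 1],  # -y
            [2, 3, 7], [2, 7, 6],  # +y
            [0, 2, 6], [0, 6, 4],  # -z
            [1, 5, 7], [1, 7, 3],  # +z
        ],
        dtype=np.int64,
    )
    return verts, faces


def generate_surrogate(
    params: SurrogateParams | None = None, seed: int = 0
) -> tuple[TriangleMesh, ImplantFrame]:
    """Build the surrogate implant shell and its intrinsic frame.

    The mesh carries face labels ``body``, ``lateral_extension`` and
    ``appendage``.  The frame origin sits on the reinforced central part
    of the floor, x runs along the long axis to the dorsal tip, y toward
    the proximal appendage side, z upward.  ``seed`` is accepted for API
    symmetry; the construction is deterministic.
    """
    p = params or SurrogateParams()
    L, W, ext, res = p.floor_length, p.width, p.lateral_extension, p.resolution
    nx = max(int(round(L / res)) + 1, 4)
    ny = max(int(round((W + 2 * ext) / res)) + 1, 4)
    xs = np.linspace(0.0, L, nx)
    ys = np.linspace(-(W / 2 + ext), W / 2, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = _floor_height(X, Y, p)

    # a cell belongs to the plate when its centroid is inside the outline
    # (centroid inclusion makes the rasterized area converge ~O(h^2):
    # boundary over- and undershoot cancel)
    XC = 0.5 * (X[:-1, :-1] + X[1:, 1:])
    YC = 0.5 * (Y[:-1, :-1] + Y[1:, 1:])
    hw_c = _halfwidth(XC, p)
    cell_body = np.abs(YC) <= hw_c
    cell_flap = (
        (XC >= 0.30 * L) & (XC <= 0.60 * L) & (YC < -hw_c) & (YC >= -hw_c - ext)
    )
    cell_in = cell_body | cell_flap

    # nodes used by any included cell
    inside = np.zeros((nx, ny), dtype=bool)
    inside[:-1, :-1] |= cell_in
    inside[1:, :-1] |= cell_in
    inside[1:, 1:] |= cell_in
    inside[:-1, 1:] |= cell_in
    node_id = -np.ones((nx, ny), dtype=np.int64)
    node_id[inside] = np.arange(int(inside.sum()))
    top_verts = np.column_stack([X[inside], Y[inside], Z[inside]])
    faces = []
    labels = []
    for i, j in zip(*np.nonzero(cell_in)):
        a = node_id[i, j]
        b = node_id[i + 1, j]
        c = node_id[i + 1, j + 1]
        d = node_id[i, j + 1]
        lab = "lateral_extension" if cell_flap[i, j] else "body"
        faces.append((a, b, c))
        faces.append((a, c, d))
        labels.extend((lab, lab))
    faces = np.asarray(faces, dtype=np.int64)
    labels = np.asarray(labels, dtype=object)
    n_top = len(top_verts)

    # thicken: bottom sheet offset along -z, walls along the open boundary
    bot_verts = top_verts + np.array([0.0, 0.0, -p.shell_thickness])
    all_verts = [top_verts, bot_verts]
    all_faces = [faces, faces[:, ::-1] + n_top]
    all_labels = [labels, labels.copy()]
    edge_count: dict[tuple[int, int], int] = {}
    edge_owner: dict[tuple[int, int], int] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (min(u, v), max(u, v))
            edge_count[key] = edge_count.get(key, 0) + 1
            edge_owner[key] = fi
    wall_faces = []
    wall_labels = []
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (min(u, v), max(u, v))
            if edge_count[key] == 1:
                # winding chosen so wall normals face outward (interior
                # lies left of the directed boundary edge of a CCW face)
                wall_faces.append((v, u, u + n_top))
                wall_faces.append((v, u + n_top, v + n_top))
                wall_labels.extend((labels[fi], labels[fi]))
    if wall_faces:
        all_faces.append(np.asarray(wall_faces, dtype=np.int64))
        all_labels.append(np.asarray(wall_labels, dtype=object))
        all_verts = all_verts  # walls reuse existing vertices

    verts = np.vstack(all_verts)
    faces_out = np.vstack(all_faces)
    labels_out = np.concatenate(all_labels)

    # proximal screw-ring appendages along the +y rim
    if p.n_appendages > 0:
        xs_app = np.linspace(0.12 * L, 0.5 * L, p.n_appendages)
        for xa in xs_app:
            ya = _halfwidth(xa, p) + p.appendage_size / 2 - res * 0.25
            za = float(_floor_height(xa, _halfwidth(xa, p), p)) - p.shell_thickness / 2
            bv, bf = _box_mesh(
                (xa, ya, za),
                (p.appendage_size, p.appendage_size, 2.5 * p.shell_thickness),
            )
            faces_out = np.vstack([faces_out, bf + len(verts)])
            verts = np.vstack([verts, bv])
            labels_out = np.concatenate(
                [labels_out, np.full(len(bf), "appendage", dtype=object)]
            )

    mesh = TriangleMesh(verts, faces_out, face_labels=labels_out)

    x0 = 0.35 * L
    z0 = float(_floor_height(x0, 0.0, p))
    tip = np.array([L, 0.0, float(_floor_height(L, 0.0, p))])
    ledge_x = 0.12 * L
    ledge = np.array(
        [ledge_x, float(_halfwidth(ledge_x, p)), float(_floor_height(ledge_x, _halfwidth(ledge_x, p), p))]
    )
    frame = frame_from_landmarks(
        origin=(x0, 0.0, z0),
        x_point=(L, 0.0, z0),
        y_hint=(x0, 1.0, z0),
        side="left",
        key_points={"dorsal_tip": tip, "medial_ledge_top": ledge},
    )
    return mesh, frame


@dataclass(frozen=True)
class Perturbations:
    """Deviations of the achieved implant from a perfectly rigid displacement."""

    noise_sigma: float = 0.0  # mm, Gaussian vertex jitter
    occlusion_fraction: float = 0.0  # contiguous fraction of faces removed
    bend_angle_deg: float = 0.0  # hinge bend of the labelled region
    bend_region: str = "lateral_extension"

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise InvalidArgumentError("noise_sigma must be >= 0")
        if not (0.0 <= self.occlusion_fraction < 1.0):
            raise InvalidArgumentError("occlusion_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "noise_sigma_mm": self.noise_sigma,
            "occlusion_fraction": self.occlusion_fraction,
            "bend_angle_deg": self.bend_angle_deg,
            "bend_region": self.bend_region,
        }


@dataclass(frozen=True)
class GroundTruthCase:
    """A fully specified synthetic evaluation case.

    ``planned`` and ``achieved`` live in an arbitrary local (planning
    scan) coordinate system; ``reference`` and ``frame`` define the
    global frame.  Before perturbation, ``achieved`` equals
    ``T_planned_to_achieved_global`` applied to ``planned`` after both
    are mapped by ``T_local_to_global`` -- verified at construction.
    """

    reference: TriangleMesh
    frame: ImplantFrame
    planned: TriangleMesh
    achieved: TriangleMesh
    true_pose: PoseParameters
    T_local_to_global: RigidTransform
    T_planned_to_achieved_global: RigidTransform
    perturbations: Perturbations
    side: str
    seed: int
    shell_thickness: float

    def truth_dict(self) -> dict:
        return {
            "true_pose": self.true_pose.to_dict(),
            "T_local_to_global": self.T_local_to_global.to_dict(),
            "T_planned_to_achieved_global": self.T_planned_to_achieved_global.to_dict(),
            "perturbations": self.perturbations.to_dict(),
            "side": self.side,
            "seed": self.seed,
            "shell_thickness_mm": self.shell_thickness,
        }


def transform_from_pose_in_frame(
    frame: ImplantFrame, pose: PoseParameters
) -> RigidTransform:
    """World transform whose frame decomposition equals ``pose``: F T_f F^-1.

    For a right-side pose the mirrored frame is used, matching the
    reporting convention.
    """
    frame_eff = (
        mirror_for_right_side(replace(frame, side="right"))
        if pose.side == "right"
        else frame
    )
    A = frame_eff.axes
    Tf = pose.to_transform()
    R = A @ Tf.rotation @ A.T
    t = A @ Tf.translation - R @ frame_eff.origin + frame_eff.origin
    return RigidTransform.from_rotation_translation(R, t)


def _random_local_offset(rng: np.random.Generator) -> RigidTransform:
    """Modest local-coordinate offset: planning scans are near-aligned."""
    angles = rng.uniform(-5.0, 5.0, size=3)  # yaw, pitch, roll deg
    t = rng.uniform(-3.0, 3.0, size=3)
    return RigidTransform.from_euler_translation(tuple(angles), t)


def _bend_region(mesh: TriangleMesh, region: str, angle_deg: float) -> TriangleMesh:
    """Rotate the labelled region about its attachment hinge line."""
    if mesh.face_labels is None:
        raise InvalidArgumentError("mesh has no face labels; cannot bend a region")
    region_faces = mesh.face_labels == region
    if not region_faces.any():
        raise InvalidArgumentError(f"no faces labelled {region!r}")
    region_verts = np.unique(mesh.faces[region_faces])
    other_verts = np.unique(mesh.faces[~region_faces])
    hinge_verts = np.intersect1d(region_verts, other_verts)
    if len(hinge_verts) < 2:
        raise InvalidArgumentError(f"region {region!r} has no attachment hinge")
    hinge_pts = mesh.vertices[hinge_verts]
    centroid = hinge_pts.mean(axis=0)
    # hinge direction = principal axis of the attachment vertices
    _, _, Vt = np.linalg.svd(hinge_pts - centroid)
    axis = Vt[0]
    theta = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    verts = mesh.vertices.copy()
    move = np.setdiff1d(region_verts, hinge_verts)
    verts[move] = (verts[move] - centroid) @ R.T + centroid
    return TriangleMesh(verts, mesh.faces.copy(), mesh.face_labels.copy())


def _occlude(mesh: TriangleMesh, fraction: float, rng: np.random.Generator) -> TriangleMesh:
    """Remove a contiguous ``fraction`` of faces around a random seed face."""
    centroids = mesh.triangles().mean(axis=1)
    seed_face = int(rng.integers(mesh.n_faces))
    d = np.linalg.norm(centroids - centroids[seed_face], axis=1)
    n_drop = int(round(fraction * mesh.n_faces))
    drop = np.argsort(d)[:n_drop]
    keep = np.ones(mesh.n_faces, dtype=bool)
    keep[drop] = False
    return mesh.submesh(keep)


def make_case(
    reference: TriangleMesh,
    frame: ImplantFrame,
    true_pose: PoseParameters,
    perturbations: Perturbations | None = None,
    seed: int = 0,
    local_offset: bool = True,
    shell_thickness: float = SurrogateParams().shell_thickness,
) -> GroundTruthCase:
    """Pose the reference implant with a known ground truth and perturb it."""
    pert = perturbations or Perturbations()
    rng = np.random.default_rng(seed)
    T02 = transform_from_pose_in_frame(frame, true_pose)
    T_LG = _random_local_offset(rng) if local_offset else RigidTransform.identity()
    T_GL = T_LG.inverse()
    planned_g = reference
    achieved_g = reference.transformed(T02)
    planned = planned_g.transformed(T_GL)
    achieved = achieved_g.transformed(T_GL)
    # self-certification: the stored transform reproduces achieved from planned
    check = T_GL.apply(T02.apply(T_LG.apply(planned.vertices)))
    if not np.allclose(check, achieved.vertices, atol=1e-9):
        raise RuntimeError("ground-truth construction failed self-certification")
    if pert.bend_angle_deg != 0.0:
        achieved = _bend_region(achieved, pert.bend_region, pert.bend_angle_deg)
    if pert.occlusion_fraction > 0.0:
        achieved = _occlude(achieved, pert.occlusion_fraction, rng)
    if pert.noise_sigma > 0.0:
        achieved = TriangleMesh(
            achieved.vertices + rng.normal(0.0, pert.noise_sigma, achieved.vertices.shape),
            achieved.faces.copy(),
            None if achieved.face_labels is None else achieved.face_labels.copy(),
        )
    return GroundTruthCase(
        reference=reference,
        frame=frame,
        planned=planned,
        achieved=achieved,
        true_pose=true_pose,
        T_local_to_global=T_LG,
        T_planned_to_achieved_global=T02,
        perturbations=pert,
        side=true_pose.side,
        seed=seed,
        shell_thickness=shell_thickness,
    )


def _reflect_mesh(mesh: TriangleMesh) -> TriangleMesh:
    verts = mesh.vertices.copy()
    verts[:, 1] *= -1.0
    return TriangleMesh(
        verts,
        mesh.faces[:, ::-1].copy(),  # restore outward orientation
        None if mesh.face_labels is None else mesh.face_labels.copy(),
    )


def reflect_case(case: GroundTruthCase) -> GroundTruthCase:
    """xz-mirror a left-side case into its right-side twin.

    The twin's ground-truth pose keeps the same six parameters (with
    ``side='right'``): mirrored evaluation must reproduce them.
    """
    if case.side != "left":
        raise InvalidArgumentError("reflect_case expects a left-side case")
    M = np.diag([1.0, -1.0, 1.0])
    frame = case.frame
    r_frame = ImplantFrame(
        origin=M @ frame.origin,
        x_axis=M @ frame.x_axis,
        y_axis=-(M @ frame.y_axis),
        z_axis=M @ frame.z_axis,
        side="right",
        key_points={k: M @ v for k, v in frame.key_points.items()},
    )
    M4 = np.diag([1.0, -1.0, 1.0, 1.0])
    conj = lambda T: RigidTransform(M4 @ T.matrix @ M4)  # noqa: E731
    return GroundTruthCase(
        reference=_reflect_mesh(case.reference),
        frame=r_frame,
        planned=_reflect_mesh(case.planned),
        achieved=_reflect_mesh(case.achieved),
        true_pose=replace(case.true_pose, side="right"),
        T_local_to_global=conj(case.T_local_to_global),
        T_planned_to_achieved_global=conj(case.T_planned_to_achieved_global),
        perturbations=case.perturbations,
        side="right",
        seed=case.seed,
        shell_thickness=case.shell_thickness,
    )


@dataclass(frozen=True)
class Phantom:
    """Voxelized CT of the achieved implant plus ground-truth voxel labels."""

    volume: CTVolume
    implant_mask: np.ndarray
    screw_mask: np.ndarray
    hu_levels: Mapping[str, float]


def voxelize_phantom(
    case: GroundTruthCase,
    spacing: float | tuple[float, float, float] = 0.75,
    hu_levels: Mapping[str, float] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    include_screw: bool = False,
    margin: float = 6.0,
) -> Phantom:
    """Voxelize the achieved implant into an HU phantom with background anatomy.

    Voxels are classified against the shell *mid-surface* (surface
    samples offset inward by half the shell thickness along the outward
    normals), giving a slab of thickness max(shell, ~1 voxel) centred on
    the plate -- emulating the partial-volume blob a sub-voxel titanium
    plate produces in CT, rather than inflating the shell on both sides.
    A bony shelf (bone HU) touches the implant underside to exercise
    threshold separation, and an optional detached fixation-screw blob
    at implant HU exercises component filtering.  Gaussian HU noise is
    seeded.
    """
    hu = dict(DEFAULT_HU)
    if hu_levels:
        hu.update(hu_levels)
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(sp <= 0):
        raise InvalidArgumentError("spacing must be positive")
    if sp.max() > case.shell_thickness:
        warnings.warn(
            f"voxel spacing {sp.max():.2f} mm exceeds shell thickness "
            f"{case.shell_thickness:.2f} mm; shell dilated to one voxel",
            stacklevel=2,
        )
    mesh = case.achieved
    lo, hi = mesh.bounds()
    origin = lo - margin
    shape = np.ceil((hi - lo + 2 * margin) / sp).astype(int) + 1

    n_dense = max(20_000, int(mesh.area() * 10))
    sample = sample_surface(mesh, n_dense, seed=seed)
    dense = sample.points
    tri = mesh.triangles()[sample.face_index]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-300)
    mid = dense - normals * (case.shell_thickness / 2.0)
    tree = cKDTree(mid)

    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    centers = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * sp + origin
    radius = 0.5 * max(case.shell_thickness, 1.1 * float(sp.max()))
    dist, _ = tree.query(centers, workers=-1)
    implant = (dist <= radius).reshape(shape)

    vox = np.full(shape, hu["soft"], dtype=np.float32)
    # bony shelf just under the implant floor
    z_level = float(np.percentile(dense[:, 2], 20.0))
    zw = centers[:, 2].reshape(shape)
    bone = zw <= z_level
    vox[bone] = hu["bone"]
    vox[implant] = hu["implant"]

    screw = np.zeros(shape, dtype=bool)
    if include_screw:
        ymax_pt = dense[np.argmax(dense[:, 1])]
        center = ymax_pt + np.array([0.0, 3.5, 0.0])
        d = np.linalg.norm(centers - center, axis=1).reshape(shape)
        screw = (d <= 1.2) & ~implant
        vox[screw] = hu["implant"]

    # one-voxel air border so all strata are present
    vox[0, :, :] = vox[-1, :, :] = hu["air"]
    vox[:, 0, :] = vox[:, -1, :] = hu["air"]
    vox[:, :, 0] = vox[:, :, -1] = hu["air"]
    implant[0, :, :] = implant[-1, :, :] = False
    implant[:, 0, :] = implant[:, -1, :] = False
    implant[:, :, 0] = implant[:, :, -1] = False

    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed + 1)
        vox = vox + rng.normal(0.0, noise_sigma, vox.shape).astype(np.float32)

    volume = CTVolume(vox, spacing=sp, origin=origin)
    return Phantom(volume=volume, implant_mask=implant, screw_mask=screw, hu_levels=hu)
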