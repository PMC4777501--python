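"""The positioning-frame pipeline: chained registrations and pose reporting.

Given the planned implant model M0, the segmented achieved implant M2
(both in the planning-scan coordinates, already co-registered) and a
reference implant carrying the implant-intrinsic frame:

1. ICP-match the planned implant onto the reference to obtain the
   local-to-global transform T_L->G.
2. Map both M0 and M2 through T_L->G, preserving their relative pose
   while expressing it in reference coordinates.
3. ICP-match the mapped planned implant onto the mapped achieved implant
   to obtain T_0->2, the planned-to-achieved displacement.
4. Decompose T_0->2 in the implant frame (mirrored over the xz-plane for
   right-sided cases) into roll/pitch/yaw (degrees) and the displacement
   of the frame origin (mm, along the frame axes), plus the displacement
   of named key points.

Translations are reported as the frame-origin displacement expressed in
reference-frame coordinates; the raw matrix is always kept alongside the
decomposition so users are not bound to the Euler convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import __version__
from .errors import DegenerateGeometryError, ShapeMismatchWarning, StageError
from .mesh_io import TriangleMesh, sample_surface
from .registration import ICPParams, ICPResult, icp_register
from .transforms import (
    EulerAngles,
    ImplantFrame,
    RigidTransform,
    decompose_transform,
    mirror_for_right_side,
)

#: frame-alignment RMS (mm) above which a shape mismatch is suspected
SHAPE_MISMATCH_RMS = 0.5

CSV_COLUMNS = ("id", "roll", "pitch", "yaw", "t_x", "t_y", "t_z")


@dataclass(frozen=True)
class PoseParameters:
    """Implant dislocation parameters: the method's headline output.

    Angles in degrees (aircraft convention in the implant frame),
    translations in mm (frame-origin displacement along the frame axes),
    key-point displacements as world-magnitude vectors along the frame axes.
    """

    yaw: float
    pitch: float
    roll: float
    t_x: float
    t_y: float
    t_z: float
    key_point_displacements: Mapping[str, np.ndarray] = field(default_factory=dict)
    side: str = "left"
    gimbal_flag: bool = False

    def __post_init__(self):
        object.__setattr__(
            self,
            "key_point_displacements",
            {
                k: np.asarray(v, dtype=float)
                for k, v in dict(self.key_point_displacements).items()
            },
        )

    @property
    def angles(self) -> EulerAngles:
        return EulerAngles(self.yaw, self.pitch, self.roll, self.gimbal_flag)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.t_x, self.t_y, self.t_z])

    def to_transform(self) -> RigidTransform:
        """Rebuild the frame-coordinate transform from the six parameters."""
        return RigidTransform.from_euler_translation(self.angles, self.translation)

    def to_dict(self) -> dict:
        return {
            "roll_deg": self.roll,
            "pitch_deg": self.pitch,
            "yaw_deg": self.yaw,
            "t_x_mm": self.t_x,
            "t_y_mm": self.t_y,
            "t_z_mm": self.t_z,
            "side": self.side,
            "gimbal_flag": self.gimbal_flag,
            "key_point_displacements_mm": {
                k: v.tolist() for k, v in self.key_point_displacements.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PoseParameters":
        return cls(
            yaw=float(d["yaw_deg"]),
            pitch=float(d["pitch_deg"]),
            roll=float(d["roll_deg"]),
            t_x=float(d["t_x_mm"]),
            t_y=float(d["t_y_mm"]),
            t_z=float(d["t_z_mm"]),
            key_point_displacements={
                k: np.asarray(v) for k, v in d.get("key_point_displacements_mm", {}).items()
            },
            side=d.get("side", "left"),
            gimbal_flag=bool(d.get("gimbal_flag", False)),
        )


@dataclass(frozen=True)
class EvaluationReport:
    """Pose parameters plus everything needed to reproduce them."""

    pose: PoseParameters
    frame_alignment: ICPResult  # T_L->G, planned onto reference
    placement: ICPResult  # T_0->2, planned onto achieved (reference coords)
    shape_mismatch: bool
    provenance: dict = field(default_factory=dict)

    @property
    def transform_planned_to_achieved(self) -> RigidTransform:
        return self.placement.transform

    def to_dict(self) -> dict:
        return {
            "pose": self.pose.to_dict(),
            "transform_planned_to_achieved": self.placement.transform.to_dict(),
            "frame_alignment": self.frame_alignment.to_dict(),
            "placement": self.placement.to_dict(),
            "shape_mismatch": self.shape_mismatch,
            "provenance": self.provenance,
            "version": __version__,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def csv_row(self, case_id: str = "case") -> dict:
        return {
            "id": case_id,
            "roll": self.pose.roll,
            "pitch": self.pose.pitch,
            "yaw": self.pose.yaw,
            "t_x": self.pose.t_x,
            "t_y": self.pose.t_y,
            "t_z": self.pose.t_z,
        }


def frame_from_landmarks(
    origin,
    x_point,
    y_hint,
    side: str = "left",
    up_reference=(0.0, 0.0, 1.0),
    key_points: Mapping[str, np.ndarray] | None = None,
) -> ImplantFrame:
    """Construct an implant frame from three landmarks.

    x runs from ``origin`` toward ``x_point`` (long axis to the tip);
    z is perpendicular to the plane of the landmarks, oriented toward
    ``up_reference``; y = z x x completes the right-handed frame and
    points toward the ``y_hint`` side.
    """
    origin = np.asarray(origin, dtype=float)
    x_point = np.asarray(x_point, dtype=float)
    y_hint = np.asarray(y_hint, dtype=float)
    vx = x_point - origin
    nx = np.linalg.norm(vx)
    if nx < 1e-9:
        raise DegenerateGeometryError("x_point coincides with origin")
    x_axis = vx / nx
    vz = np.cross(x_axis, y_hint - origin)
    nz = np.linalg.norm(vz)
    if nz < 1e-9 * max(1.0, np.linalg.norm(y_hint - origin)):
        raise DegenerateGeometryError("landmarks are collinear; frame undefined")
    z_axis = vz / nz
    if float(np.dot(z_axis, np.asarray(up_reference, dtype=float))) < 0:
        z_axis = -z_axis
    y_axis = np.cross(z_axis, x_axis)
    return ImplantFrame(
        origin=origin,
        x_axis=x_axis,
        y_axis=y_axis,
        z_axis=z_axis,
        side=side,
        key_points=key_points or {},
    )


def align_to_reference(
    planned: TriangleMesh,
    reference: TriangleMesh,
    icp: ICPParams | None = None,
) -> ICPResult:
    """ICP-match the planned implant onto the reference implant (T_L->G).

    Emits a warning when the residual exceeds the same-shape heuristic
    (the two meshes should be the same product/size).
    """
    icp = icp or ICPParams()
    result = icp_register(planned, reference, icp)
    if result.rms_residual > SHAPE_MISMATCH_RMS:
        warnings.warn(
            f"frame-alignment RMS {result.rms_residual:.2f} mm exceeds "
            f"{SHAPE_MISMATCH_RMS} mm: planned and reference shapes may differ",
            ShapeMismatchWarning,
            stacklevel=2,
        )
    return result


def keypoint_displacement(
    T: RigidTransform, frame: ImplantFrame
) -> dict[str, np.ndarray]:
    """Displacement (R p + t) - p of each frame key point, along the frame axes."""
    out = {}
    for name, p in frame.key_points.items():
        d = T.apply(p) - p
        out[name] = frame.vector_in_frame(d)
    return out


def pose_from_transform(
    T: RigidTransform, frame: ImplantFrame, side: str = "left"
) -> PoseParameters:
    """Decompose a reference-coordinate transform in the (possibly mirrored) frame."""
    frame_eff = mirror_for_right_side(replace(frame, side=side)) if side == "right" else frame
    angles, t = decompose_transform(frame_eff.pose_in_frame(T))
    return PoseParameters(
        yaw=angles.yaw,
        pitch=angles.pitch,
        roll=angles.roll,
        t_x=float(t[0]),
        t_y=float(t[1]),
        t_z=float(t[2]),
        key_point_displacements=keypoint_displacement(T, frame_eff),
        side=side,
        gimbal_flag=angles.gimbal_lock,
    )


def evaluate_placement(
    planned: TriangleMesh,
    achieved: TriangleMesh,
    reference: TriangleMesh,
    frame: ImplantFrame,
    side: str = "left",
    icp: ICPParams | None = None,
    exclude_labels: tuple[str, ...] | None = None,
    provenance: Mapping | None = None,
) -> EvaluationReport:
    """Run the full pipeline and report the achieved-vs-planned pose.

    ``frame`` must be attached to the reference mesh's coordinates.
    ``exclude_labels`` keeps the named planned-mesh regions (e.g. an
    intraoperatively bent lateral extension) out of the placement
    registration.  Any stage failure is re-raised as a StageError naming
    the stage.
    """
    icp = icp or ICPParams()
    try:
        frame_alignment = align_to_reference(planned, reference, icp)
    except Exception as exc:  # noqa: BLE001
        raise StageError("frame_alignment", exc) from exc
    T_LG = frame_alignment.transform
    planned_g = planned.transformed(T_LG)
    achieved_g = achieved.transformed(T_LG)
    try:
        source = sample_surface(
            planned_g, icp.n_samples, seed=icp.seed, exclude_labels=exclude_labels
        )
        placement = icp_register(source, achieved_g, icp)
    except Exception as exc:  # noqa: BLE001
        raise StageError("placement_registration", exc) from exc
    try:
        pose = pose_from_transform(placement.transform, frame, side=side)
    except Exception as exc:  # noqa: BLE001
        raise StageError("decomposition", exc) from exc
    prov = {
        "icp_params": icp.to_dict(),
        "exclude_labels": list(exclude_labels) if exclude_labels else [],
        "side": side,
        "n_planned_faces": planned.n_faces,
        "n_achieved_faces": achieved.n_faces,
        "n_reference_faces": reference.n_faces,
    }
    if provenance:
        prov.update(dict(provenance))
    return EvaluationReport(
        pose=pose,
        frame_alignment=frame_alignment,
        placement=placement,
        shape_mismatch=frame_alignment.rms_residual > SHAPE_MISMATCH_RMS,
        provenance=prov,
    )
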