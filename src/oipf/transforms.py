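"""Rigid-transform algebra and the ZYX (yaw-pitch-roll) Euler convention.

Everything downstream trades in 4x4 homogeneous rigid transforms with
translations in millimetres.  Rotations are composed as

    R(alpha, beta, gamma) = Rz(alpha) @ Ry(beta) @ Rx(gamma)

i.e. roll (about x, ``gamma``) is applied first, then pitch (about y,
``beta``), then yaw (about z, ``alpha``) -- the aircraft-dynamics
convention used to report implant dislocation.  Angles are reported in
degrees with ``beta`` in [-90, 90] and ``alpha``, ``gamma`` in (-180, 180].

Right-sided implants are handled by conjugating with the xz-plane
reflection ``diag(1, -1, 1)`` rather than by geometrically mirroring
meshes; the two are equivalent and the conjugation keeps every matrix in
the pipeline a proper rotation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .errors import (
    GimbalLockWarning,
    InvalidArgumentError,
    InvalidTransformError,
)

#: per-element tolerance for exact rotation algebra
ORTHO_TOL = 1e-9
#: inputs orthonormal only to this tolerance are projected to the nearest rotation
PROJECT_TOL = 1e-6
#: |cos(pitch)| below this triggers the gimbal-lock convention
GIMBAL_COS_TOL = 1e-8

EULER_CONVENTION = "ZYX-intrinsic-rPy-composition Rz·Ry·Rx"

_MIRROR_XZ = np.diag([1.0, -1.0, 1.0])
_MIRROR_XZ4 = np.diag([1.0, -1.0, 1.0, 1.0])


@dataclass(frozen=True)
class EulerAngles:
    """Yaw/pitch/roll triple in degrees.

    ``gimbal_lock`` is set when the decomposition hit |pitch| ~ 90 deg and
    the roll := 0 convention was applied.
    """

    yaw: float
    pitch: float
    roll: float
    gimbal_lock: bool = False

    def __post_init__(self):
        for name in ("yaw", "pitch", "roll"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidArgumentError(f"{name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.yaw, self.pitch, self.roll], dtype=float)


def _check_rotation(R: np.ndarray, tol: float) -> float:
    """Return the max orthonormality defect of ``R`` (inf if not 3x3/finite)."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        return math.inf
    defect = float(np.abs(R @ R.T - np.eye(3)).max())
    defect = max(defect, abs(float(np.linalg.det(R)) - 1.0))
    return defect


def nearest_rotation(R: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix onto SO(3) (polar decomposition via SVD)."""
    U, _, Vt = np.linalg.svd(np.asarray(R, dtype=float))
    D = np.diag([1.0, 1.0, float(np.sign(np.linalg.det(U @ Vt)))])
    return U @ D @ Vt


def _validated_rotation(R: np.ndarray) -> np.ndarray:
    defect = _check_rotation(R, ORTHO_TOL)
    if defect > PROJECT_TOL:
        raise InvalidTransformError(
            f"matrix is not a rotation (orthonormality defect {defect:.3g} "
            f"> {PROJECT_TOL:g})"
        )
    if defect > ORTHO_TOL:
        return nearest_rotation(R)
    return np.asarray(R, dtype=float)


def compose_rotation(angles: EulerAngles | tuple[float, float, float]) -> np.ndarray:
    """Build ``Rz(yaw) @ Ry(pitch) @ Rx(roll)`` from angles in degrees."""
    if not isinstance(angles, EulerAngles):
        angles = EulerAngles(*angles)
    a, b, g = np.deg2rad(angles.as_array())
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cg, sg = math.cos(g), math.sin(g)
    return np.array(
        [
            [ca * cb, ca * sb * sg - sa * cg, ca * sb * cg + sa * sg],
            [sa * cb, sa * sb * sg + ca * cg, sa * sb * cg - ca * sg],
            [-sb, cb * sg, cb * cg],
        ]
    )


def decompose_rotation(R: np.ndarray) -> EulerAngles:
    """Recover (yaw, pitch, roll) degrees from a rotation matrix.

    pitch = asin(-R[2,0]); yaw = atan2(R[1,0], R[0,0]); roll = atan2(R[2,1], R[2,2]).
    At |pitch| ~ 90 deg yaw and roll are not separable; roll is set to 0, the
    remainder folded into yaw, and the result flagged (with a warning).
    """
    R = _validated_rotation(R)
    sb = float(np.clip(-R[2, 0], -1.0, 1.0))
    beta = math.asin(sb)
    if math.sqrt(max(0.0, 1.0 - sb * sb)) < GIMBAL_COS_TOL:
        warnings.warn(
            "pitch at +/-90 deg: yaw/roll not separable, applying roll := 0",
            GimbalLockWarning,
            stacklevel=2,
        )
        # with roll = 0:  R = Rz(yaw) @ Ry(+/-90)  =>  R[0,1] = -sin(yaw), R[1,1] = cos(yaw)
        alpha = math.atan2(-R[0, 1], R[1, 1])
        gamma = 0.0
        lock = True
    else:
        alpha = math.atan2(R[1, 0], R[0, 0])
        gamma = math.atan2(R[2, 1], R[2, 2])
        lock = False
    return EulerAngles(
        yaw=math.degrees(alpha),
        pitch=math.degrees(beta),
        roll=math.degrees(gamma),
        gimbal_lock=lock,
    )


class RigidTransform:
    """A 4x4 homogeneous rigid transform (rotation + translation in mm)."""

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray, *, validate: bool = True):
        M = np.array(matrix, dtype=float)
        if M.shape != (4, 4):
            raise InvalidTransformError(f"expected 4x4 matrix, got {M.shape}")
        if validate:
            if not np.all(np.isfinite(M)):
                raise InvalidTransformError("matrix contains non-finite entries")
            if not np.array_equal(M[3], [0.0, 0.0, 0.0, 1.0]):
                raise InvalidTransformError(
                    f"last row must be exactly [0,0,0,1], got {M[3]}"
                )
            M[:3, :3] = _validated_rotation(M[:3, :3])
        M.setflags(write=False)
        object.__setattr__(self, "matrix", M)

    # -- constructors ------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4), validate=False)

    @classmethod
    def from_rotation_translation(
        cls, R: np.ndarray, t: Iterable[float]
    ) -> "RigidTransform":
        M = np.eye(4)
        M[:3, :3] = np.asarray(R, dtype=float)
        M[:3, 3] = np.asarray(list(t), dtype=float)
        return cls(M)

    @classmethod
    def from_euler_translation(
        cls, angles: EulerAngles | tuple[float, float, float], t: Iterable[float] = (0, 0, 0)
    ) -> "RigidTransform":
        return cls.from_rotation_translation(compose_rotation(angles), t)

    # -- accessors ---------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- algebra -----------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self @ other`` (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix)

    __matmul__ = compose

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        M = np.eye(4)
        M[:3, :3] = R.T
        M[:3, 3] = -R.T @ self.translation
        return RigidTransform(M)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) through ``R @ p + t``."""
        pts = np.asarray(points, dtype=float)
        if pts.shape[-1] != 3:
            raise InvalidArgumentError(f"points must have last dim 3, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise InvalidArgumentError("points contain non-finite coordinates")
        return pts @ self.rotation.T + self.translation

    def __eq__(self, other) -> bool:
        return isinstance(other, RigidTransform) and np.array_equal(
            self.matrix, other.matrix
        )

    def __repr__(self) -> str:
        e = decompose_rotation(self.rotation)
        t = self.translation
        return (
            f"RigidTransform(yaw={e.yaw:.3f}deg, pitch={e.pitch:.3f}deg, "
            f"roll={e.roll:.3f}deg, t=({t[0]:.3f}, {t[1]:.3f}, {t[2]:.3f}) mm)"
        )

    # -- serialization -----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "matrix": [float(x) for x in self.matrix.ravel()],
            "units": "mm",
            "convention": EULER_CONVENTION,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RigidTransform":
        vals = np.asarray(d["matrix"], dtype=float)
        if vals.size != 16:
            raise InvalidTransformError(f"expected 16 matrix entries, got {vals.size}")
        return cls(vals.reshape(4, 4))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def decompose_transform(T: RigidTransform) -> tuple[EulerAngles, np.ndarray]:
    """Split a rigid transform into Euler angles (deg) and translation (mm)."""
    return decompose_rotation(T.rotation), np.array(T.translation)


def mirror_conjugate(T: RigidTransform) -> RigidTransform:
    """Conjugate by the xz-plane reflection: ``M @ T @ M`` with M = diag(1,-1,1).

    Negates yaw, roll and the y-translation while leaving pitch and the
    x/z translations unchanged -- the right-side reporting convention.
    """
    return RigidTransform(_MIRROR_XZ4 @ T.matrix @ _MIRROR_XZ4)


def reflect_points_xz(points: np.ndarray) -> np.ndarray:
    """Reflect points over the xz-plane (negate y)."""
    out = np.array(points, dtype=float)
    out[..., 1] *= -1.0
    return out


@dataclass(frozen=True)
class ImplantFrame:
    """Implant-intrinsic coordinate frame: origin plus orthonormal axes.

    The x-axis runs along the implant's long axis toward the dorsal tip,
    the y-axis toward the proximal extensions, the z-axis upward.
    ``key_points`` holds named landmarks (e.g. ``medial_ledge_top``,
    ``dorsal_tip``) in the same world coordinates as the origin.
    ``mirrored`` marks a right-side frame whose y-axis has been flipped
    for decomposition; a mirrored frame is left-handed by construction.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    side: str = "left"
    key_points: Mapping[str, np.ndarray] = field(default_factory=dict)
    mirrored: bool = False

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            v = np.array(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise InvalidArgumentError(f"{name} must be a finite 3-vector")
            v.setflags(write=False)
            object.__setattr__(self, name, v)
        if self.side not in ("left", "right"):
            raise InvalidArgumentError(f"side must be 'left' or 'right', got {self.side!r}")
        axes = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if np.abs(axes @ axes.T - np.eye(3)).max() > ORTHO_TOL * 10:
            raise InvalidArgumentError("frame axes must be orthonormal")
        handed = np.cross(self.x_axis, self.y_axis)
        expect = -self.z_axis if self.mirrored else self.z_axis
        if np.abs(handed - expect).max() > 1e-9:
            raise InvalidArgumentError(
                "axes violate the handedness convention "
                "(cross(x, y) must equal z, or -z for a mirrored frame)"
            )
        kp = {
            k: np.asarray(v, dtype=float) for k, v in dict(self.key_points).items()
        }
        object.__setattr__(self, "key_points", kp)

    @property
    def axes(self) -> np.ndarray:
        """3x3 matrix whose *columns* are the frame axes."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def pose_in_frame(self, T: RigidTransform) -> RigidTransform:
        """Express a world-coordinate transform in this frame: ``F^-1 T F``.

        ``F`` maps frame coordinates into the world; for a mirrored frame
        ``F`` is improper, but the conjugation is always a proper rigid
        transform.  The translation of the result is the displacement of
        the frame origin expressed along the frame axes.
        """
        A = self.axes
        R = A.T @ T.rotation @ A
        t = A.T @ (T.rotation @ self.origin + T.translation - self.origin)
        return RigidTransform.from_rotation_translation(nearest_rotation(R), t)

    def vector_in_frame(self, v: np.ndarray) -> np.ndarray:
        """Express a world-space displacement vector along the frame axes."""
        return self.axes.T @ np.asarray(v, dtype=float)

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "x_axis": self.x_axis.tolist(),
            "y_axis": self.y_axis.tolist(),
            "z_axis": self.z_axis.tolist(),
            "side": self.side,
            "mirrored": self.mirrored,
            "key_points": {k: v.tolist() for k, v in self.key_points.items()},
            "units": "mm",
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ImplantFrame":
        return cls(
            origin=np.asarray(d["origin"], dtype=float),
            x_axis=np.asarray(d["x_axis"], dtype=float),
            y_axis=np.asarray(d["y_axis"], dtype=float),
            z_axis=np.asarray(d["z_axis"], dtype=float),
            side=d.get("side", "left"),
            key_points={
                k: np.asarray(v, dtype=float)
                for k, v in d.get("key_points", {}).items()
            },
            mirrored=bool(d.get("mirrored", False)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ImplantFrame":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def mirror_for_right_side(frame: ImplantFrame) -> ImplantFrame:
    """Flip the y-axis of a right-side frame so left/right cases compare.

    With the flipped y-axis the reported yaw and roll are sign-opposed
    relative to the unmirrored frame; pitch and the x/z conventions are
    unchanged.  The operation is an involution.
    """
    if frame.side != "right":
        raise InvalidArgumentError(
            f"mirroring applies to right-side frames only, got side={frame.side!r}"
        )
    return replace(frame, y_axis=-frame.y_axis, mirrored=not frame.mirrored)
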