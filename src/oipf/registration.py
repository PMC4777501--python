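"""Rigid point-set registration: closed-form Kabsch fit and trimmed ICP.

The closed-form step solves the orthogonal Procrustes problem

    argmin_{R, t}  sum_i w_i || R s_i + t - d_i ||^2,  det(R) = +1

via SVD of the weighted cross-covariance, with the sign of the smallest
singular vector corrected so a reflection is never returned.  ICP is the
canonical point-to-point Besl-McKay loop: nearest-neighbour
correspondences through a k-d tree, optional rejection of the worst
``trim_fraction`` of pairs (partial overlap, bent sub-regions), then a
Kabsch fit of the *original* source points onto their matched targets so
the cumulative transform stays exactly rigid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    EmptyCorrespondenceError,
    InvalidArgumentError,
)
from .mesh_io import DEFAULT_SAMPLE_COUNT, SurfaceSample, TriangleMesh, sample_surface
from .transforms import RigidTransform


@dataclass(frozen=True)
class ICPParams:
    """ICP configuration.

    ``trim_fraction`` rejects the worst fraction of correspondences each
    iteration (0 = full overlap).  ``rms_rel_tolerance`` is the relative
    RMS change below which iteration stops.  ``n_samples`` controls the
    surface sampling density when meshes are passed directly.
    """

    max_iterations: int = 100
    rms_rel_tolerance: float = 1e-6
    trim_fraction: float = 0.0
    init: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0
    n_samples: int = DEFAULT_SAMPLE_COUNT
    accelerate: bool = True

    def __post_init__(self):
        if not (0.0 <= self.trim_fraction < 1.0):
            raise InvalidArgumentError(
                f"trim_fraction must be in [0, 1), got {self.trim_fraction}"
            )
        if self.max_iterations < 1:
            raise InvalidArgumentError("max_iterations must be >= 1")
        if self.rms_rel_tolerance < 0:
            raise InvalidArgumentError("rms_rel_tolerance must be >= 0")

    def to_dict(self) -> dict:
        return {
            "max_iterations": self.max_iterations,
            "rms_rel_tolerance": self.rms_rel_tolerance,
            "trim_fraction": self.trim_fraction,
            "seed": self.seed,
            "n_samples": self.n_samples,
            "accelerate": self.accelerate,
            "init": self.init.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ICPParams":
        d = dict(d)
        if "init" in d and not isinstance(d["init"], RigidTransform):
            d["init"] = RigidTransform.from_dict(d["init"])
        return cls(**d)


@dataclass(frozen=True)
class ICPResult:
    """Outcome of an ICP run: cumulative source-to-target transform."""

    transform: RigidTransform
    rms_residual: float
    iterations_run: int
    converged: bool
    residual_history: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "rms_residual_mm": self.rms_residual,
            "iterations_run": self.iterations_run,
            "converged": self.converged,
            "residual_history_mm": list(self.residual_history),
        }


def kabsch_fit(
    src_points: np.ndarray,
    dst_points: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Least-squares rigid fit of corresponding point pairs (Kabsch/Horn)."""
    src = np.asarray(src_points, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst_points, dtype=float).reshape(-1, 3)
    if src.shape != dst.shape:
        raise InvalidArgumentError(
            f"src/dst shape mismatch: {src.shape} vs {dst.shape}"
        )
    if len(src) < 3:
        raise DegenerateGeometryError("need at least 3 corresponding point pairs")
    if weights is None:
        w = np.full(len(src), 1.0 / len(src))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(src),) or np.any(w < 0) or w.sum() <= 0:
            raise InvalidArgumentError("weights must be non-negative with positive sum")
        w = w / w.sum()
    mu_s = w @ src
    mu_d = w @ dst
    S = src - mu_s
    D = dst - mu_d
    H = (S * w[:, None]).T @ D  # weighted cross-covariance
    U, sing, Vt = np.linalg.svd(H)
    scale = max(float(sing[0]), np.abs(S).max() ** 2, 1e-300)
    if sing[1] <= 1e-9 * scale:
        raise DegenerateGeometryError(
            "point configuration is collinear/degenerate (rank-deficient covariance)"
        )
    d = float(np.sign(np.linalg.det(Vt.T @ U.T)))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_d - R @ mu_s
    return RigidTransform.from_rotation_translation(R, t)


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact closest point on each triangle for each query point (paired).

    p: (M, 3), tri: (M, 3, 3).  Candidates are the in-plane projection
    (when its barycentrics are non-negative) and the clamped projections
    onto the three edges; the nearest candidate wins.
    """
    B, C1, C2 = tri[:, 0], tri[:, 1], tri[:, 2]
    cands = []
    for a, b in ((B, C1), (C1, C2), (C2, B)):
        e = b - a
        denom = np.maximum((e * e).sum(1), 1e-300)
        u = np.clip(((p - a) * e).sum(1) / denom, 0.0, 1.0)
        cands.append(a + u[:, None] * e)
    n = np.cross(C1 - B, C2 - B)
    nn = np.maximum((n * n).sum(1), 1e-300)
    proj = p - ((p - B) * n).sum(1)[:, None] * n / nn[:, None]
    # barycentric test for the interior projection
    v0, v1, v2 = C1 - B, C2 - B, proj - B
    d00 = (v0 * v0).sum(1)
    d01 = (v0 * v1).sum(1)
    d11 = (v1 * v1).sum(1)
    d20 = (v2 * v0).sum(1)
    d21 = (v2 * v1).sum(1)
    det = np.maximum(d00 * d11 - d01 * d01, 1e-300)
    bv = (d11 * d20 - d01 * d21) / det
    bw = (d00 * d21 - d01 * d20) / det
    inside = (bv >= 0) & (bw >= 0) & (bv + bw <= 1)
    best = cands[0]
    best_d = ((p - best) ** 2).sum(1)
    for c in cands[1:]:
        d = ((p - c) ** 2).sum(1)
        swap = d < best_d
        best = np.where(swap[:, None], c, best)
        best_d = np.where(swap, d, best_d)
    d_in = ((p - proj) ** 2).sum(1)
    use_in = inside & (d_in < best_d)
    return np.where(use_in[:, None], proj, best)


def _subdivide_to_uniform(tri: np.ndarray, max_rounds: int = 6) -> np.ndarray:
    """4-split triangles whose longest edge exceeds ~the median edge length.

    The subdivided set covers exactly the same surface; it only equalises
    candidate density for the centroid k-d tree, so no face is starved of
    nearby candidates next to much smaller neighbours.
    """
    edges = np.linalg.norm(tri - np.roll(tri, 1, axis=1), axis=2)
    target = 1.5 * float(np.median(edges))
    for _ in range(max_rounds):
        longest = np.linalg.norm(tri - np.roll(tri, 1, axis=1), axis=2).max(axis=1)
        big = longest > target
        if not big.any():
            break
        t = tri[big]
        m01 = 0.5 * (t[:, 0] + t[:, 1])
        m12 = 0.5 * (t[:, 1] + t[:, 2])
        m20 = 0.5 * (t[:, 2] + t[:, 0])
        quarters = np.concatenate(
            [
                np.stack([t[:, 0], m01, m20], axis=1),
                np.stack([m01, t[:, 1], m12], axis=1),
                np.stack([m20, m12, t[:, 2]], axis=1),
                np.stack([m01, m12, m20], axis=1),
            ]
        )
        tri = np.concatenate([tri[~big], quarters])
    return tri


class _SurfaceProjector:
    """Project query points onto the exact closest point of a mesh surface.

    A k-d tree over the triangle centroids proposes candidate faces; the
    exact point-triangle projection picks the winner.  Point-to-surface
    correspondences avoid the quantization bias of matching against a
    finite point sample.  ``k`` must be large enough that the containing
    face of a near-surface query is always among the candidates; for the
    near-uniform triangulations used here k = 16 is conservative.
    """

    def __init__(self, mesh: TriangleMesh, k: int = 16, seed: int = 0):
        self._triangles = _subdivide_to_uniform(mesh.triangles())
        self._tree = cKDTree(self._triangles.mean(axis=1))
        self._k = min(k, len(self._triangles))

    def project(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest surface points, distances) for ``pts``."""
        _, faces = self._tree.query(pts, k=self._k, workers=-1)
        faces = faces.reshape(len(pts), -1)  # (N, k)
        n, k = faces.shape
        flat = _closest_point_on_triangles(
            np.repeat(pts, k, axis=0), self._triangles[faces.ravel()]
        ).reshape(n, k, 3)
        d2 = ((flat - pts[:, None, :]) ** 2).sum(2)
        best = d2.argmin(1)
        rows = np.arange(n)
        return flat[rows, best], np.sqrt(d2[rows, best])


def _as_points(target, seed: int, n_samples: int) -> np.ndarray:
    if isinstance(target, SurfaceSample):
        return target.points
    if isinstance(target, TriangleMesh):
        return sample_surface(target, n_samples, seed=seed).points
    pts = np.asarray(target, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError("target must be points (K, 3), a SurfaceSample or a TriangleMesh")
    return pts


def icp_register(
    source: SurfaceSample | TriangleMesh | np.ndarray,
    target: SurfaceSample | TriangleMesh | np.ndarray,
    params: ICPParams | None = None,
) -> ICPResult:
    """Register ``source`` onto ``target`` with point-to-point trimmed ICP.

    Returns the cumulative rigid transform mapping source coordinates
    into the target frame.  Non-convergence within ``max_iterations`` is
    reported via ``converged=False``, not an exception.
    """
    params = params or ICPParams()
    src0 = _as_points(source, seed=params.seed, n_samples=params.n_samples)
    if len(src0) == 0:
        raise InvalidArgumentError("source must be non-empty")
    if isinstance(target, TriangleMesh):
        projector = _SurfaceProjector(target, seed=params.seed + 1)
        match = projector.project
    else:
        dst = _as_points(target, seed=params.seed + 1, n_samples=params.n_samples)
        if len(dst) == 0:
            raise InvalidArgumentError("target must be non-empty")
        tree = cKDTree(dst)

        def match(pts):
            dists, idx = tree.query(pts, workers=-1)
            return dst[idx], dists
    n_keep = int(np.ceil(len(src0) * (1.0 - params.trim_fraction)))
    if n_keep < 3:
        raise EmptyCorrespondenceError(
            f"trimming leaves {n_keep} correspondences; need >= 3"
        )
    def trimmed_rms(transform: RigidTransform) -> float:
        moved = transform.apply(src0)
        _, d = match(moved)
        if params.trim_fraction > 0.0:
            d = np.partition(d, n_keep - 1)[:n_keep]
        return float(np.sqrt(np.mean(d**2)))

    T = params.init
    history: list[float] = []
    prev_rms = np.inf
    prev_delta_vec: np.ndarray | None = None
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        prev_T = T
        moved = T.apply(src0)
        matched, dists = match(moved)
        if params.trim_fraction > 0.0:
            keep = np.argpartition(dists, n_keep - 1)[:n_keep]
        else:
            keep = slice(None)
        T = kabsch_fit(src0[keep], matched[keep])
        resid = np.linalg.norm(T.apply(src0[keep]) - matched[keep], axis=1)
        rms = float(np.sqrt(np.mean(resid**2)))
        if params.accelerate:
            # Extrapolate along the update direction when two consecutive
            # pose deltas align (the slow tangential-sliding regime of
            # point-to-point ICP); keep only improvements, so the recorded
            # residual history stays non-increasing.
            delta = T @ prev_T.inverse()
            dvec = np.concatenate(
                [Rotation.from_matrix(delta.rotation).as_rotvec(), delta.translation]
            )
            norm = float(np.linalg.norm(dvec))
            if prev_delta_vec is not None and norm > 1e-15:
                pnorm = float(np.linalg.norm(prev_delta_vec))
                if pnorm > 1e-15 and float(dvec @ prev_delta_vec) / (norm * pnorm) > 0.9:
                    scale = 3.0
                    ext = RigidTransform.from_rotation_translation(
                        Rotation.from_rotvec(scale * dvec[:3]).as_matrix(),
                        scale * dvec[3:],
                    )
                    T_ext = ext @ T
                    rms_ext = trimmed_rms(T_ext)
                    if rms_ext < rms:
                        T, rms = T_ext, rms_ext
                        dvec = dvec * (scale + 1.0)
            prev_delta_vec = dvec
        history.append(rms)
        if rms < 1e-12:  # exact overlap: nothing left to improve
            converged = True
            break
        if np.isfinite(prev_rms):
            denom = max(prev_rms, 1e-300)
            if abs(prev_rms - rms) / denom < params.rms_rel_tolerance:
                converged = True
                break
        prev_rms = rms
    return ICPResult(
        transform=T,
        rms_residual=history[-1],
        iterations_run=iterations,
        converged=converged,
        residual_history=tuple(history),
    )
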