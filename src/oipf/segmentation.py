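"""CT implant segmentation: HU thresholding, component filtering, surface extraction.

The achieved implant is extracted from the (already co-registered)
post-operative scan by thresholding at >= 1200 HU -- titanium (~3000 HU)
sits well above the threshold, cortical bone (~700 HU) below it.
Superfluous high-density structures (detached fixation-screw fragments,
dense bone bridges) are removed by connected-component filtering; the
proximal screw rings, which may have been bent intraoperatively, are
removed with geometric exclusion regions in world coordinates -- a
reproducible stand-in for interactive mask editing.  The final surface
is a marching-cubes isosurface of the *binary* mask at level 0.5, so the
exported geometry is consistent with every mask edit.

World-coordinate convention: ``world = origin + direction @ (index * spacing)``
with ``index`` in array (i, j, k) order.  NIfTI affines are honoured on
read and reproduced on write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import EmptyMaskError, EmptySegmentationWarning, InvalidArgumentError
from .mesh_io import TriangleMesh

#: HU threshold separating the titanium implant from bone
DEFAULT_THRESHOLD_HU = 1200.0

_HU_RANGE = (-1024.0, 30000.0)
_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with world-coordinate geometry."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None
    direction: np.ndarray = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise InvalidArgumentError("voxels must be a 3-D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise InvalidArgumentError(f"spacing must be positive, got {self.spacing}")
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float)
        )
        self.direction = (
            np.eye(3) if self.direction is None else np.asarray(self.direction, dtype=float)
        )
        if np.abs(self.direction @ self.direction.T - np.eye(3)).max() > 1e-6:
            raise InvalidArgumentError("direction cosines must be orthonormal")
        if not np.all(np.isfinite(self.voxels)):
            raise InvalidArgumentError("HU values must be finite")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < _HU_RANGE[0] - 1 or hi > _HU_RANGE[1]:
            raise InvalidArgumentError(
                f"HU range [{lo:.0f}, {hi:.0f}] outside plausible {_HU_RANGE}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = self.direction @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk * self.spacing @ self.direction.T + self.origin

    # -- I/O ---------------------------------------------------------
    @classmethod
    def from_nifti(cls, path) -> "CTVolume":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        A = img.affine
        M = A[:3, :3]
        spacing = np.linalg.norm(M, axis=0)
        direction = M / spacing
        return cls(data, spacing=spacing, origin=A[:3, 3], direction=direction)

    def to_nifti(self, path, data: np.ndarray | None = None) -> None:
        arr = self.voxels if data is None else np.asarray(data)
        nib.save(nib.Nifti1Image(arr.astype(np.float32), self.affine), str(path))

    @classmethod
    def from_dicom_series(cls, directory) -> "CTVolume":
        """Read a single-series DICOM directory; slices sorted by position,
        rescale slope/intercept applied to produce HU."""
        import pydicom

        from pathlib import Path

        files = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
        slices = []
        for f in files:
            if not f.is_file():
                continue
            try:
                ds = pydicom.dcmread(str(f))
            except Exception:  # noqa: BLE001 - skip non-DICOM files
                continue
            if hasattr(ds, "PixelData"):
                slices.append(ds)
        if not slices:
            raise InvalidArgumentError(f"no DICOM slices found in {directory}")
        first = slices[0]
        row = np.asarray(first.ImageOrientationPatient[:3], dtype=float)
        col = np.asarray(first.ImageOrientationPatient[3:], dtype=float)
        normal = np.cross(row, col)
        slices.sort(key=lambda ds: float(np.dot(ds.ImagePositionPatient, normal)))
        hu = []
        for ds in slices:
            arr = ds.pixel_array.astype(np.float32)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            inter = float(getattr(ds, "RescaleIntercept", 0.0))
            hu.append(arr * slope + inter)
        # stack as (i, j, k) = (column, row, slice) so index_to_world is direct
        vol = np.stack(hu, axis=-1).transpose(1, 0, 2)
        px = np.asarray(first.PixelSpacing, dtype=float)  # (row, col) mm
        positions = [np.asarray(ds.ImagePositionPatient, dtype=float) for ds in slices]
        dz = (
            float(np.linalg.norm(positions[1] - positions[0]))
            if len(positions) > 1
            else float(getattr(first, "SliceThickness", 1.0))
        )
        direction = np.column_stack([row, col, normal])
        return cls(
            vol,
            spacing=np.array([px[1], px[0], dz]),
            origin=positions[0],
            direction=direction,
        )


@dataclass
class BinaryMask:
    """Boolean voxel mask aligned to a CTVolume, with full provenance."""

    data: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise InvalidArgumentError("mask must be a 3-D boolean array")

    @property
    def count(self) -> int:
        return int(self.data.sum())


def threshold_segment(
    volume: CTVolume, threshold: float = DEFAULT_THRESHOLD_HU
) -> BinaryMask:
    """Segment voxels with HU >= ``threshold`` (inclusive semantics)."""
    mask = volume.voxels >= threshold
    count = int(mask.sum())
    if count == 0:
        warnings.warn(
            f"threshold {threshold} HU produced an empty segmentation",
            EmptySegmentationWarning,
            stacklevel=2,
        )
    return BinaryMask(
        mask,
        provenance={
            "threshold_hu": float(threshold),
            "voxel_count": count,
            "empty": count == 0,
        },
    )


def filter_components(
    mask: BinaryMask, min_voxels: int = 1, keep: str = "all-above"
) -> BinaryMask:
    """Connected-component filtering with 26-connectivity.

    ``keep='largest'`` retains only the largest component;
    ``keep='all-above'`` retains every component with >= ``min_voxels``.
    """
    if keep not in ("largest", "all-above"):
        raise InvalidArgumentError(f"keep must be 'largest' or 'all-above', got {keep!r}")
    if mask.count == 0:
        raise EmptyMaskError("cannot filter components of an empty mask")
    labels, n = ndimage.label(mask.data, structure=_CONNECTIVITY_26)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    if keep == "largest":
        keep_ids = np.array([int(sizes.argmax())])
    else:
        keep_ids = np.flatnonzero(sizes >= min_voxels)
    out = np.isin(labels, keep_ids)
    removed = int(n - len(keep_ids))
    prov = dict(mask.provenance)
    prov.update(
        {
            "components_found": int(n),
            "components_removed": removed,
            "min_voxels": int(min_voxels),
            "keep": keep,
            "voxel_count": int(out.sum()),
        }
    )
    return BinaryMask(out, provenance=prov)


def _region_contains(region: Mapping, pts: np.ndarray) -> np.ndarray:
    kind = region.get("type")
    if kind == "sphere":
        center = np.asarray(region["center"], dtype=float)
        radius = float(region["radius"])
        if radius <= 0:
            raise InvalidArgumentError(f"sphere radius must be > 0, got {radius}")
        return np.linalg.norm(pts - center, axis=1) <= radius
    if kind == "box":
        lo = np.asarray(region["min"], dtype=float)
        hi = np.asarray(region["max"], dtype=float)
        if np.any(hi <= lo):
            raise InvalidArgumentError("box max must exceed min on every axis")
        return np.all((pts >= lo) & (pts <= hi), axis=1)
    raise InvalidArgumentError(f"unknown exclusion region type {kind!r}")


def apply_exclusion(
    mask: BinaryMask, volume: CTVolume, regions: Sequence[Mapping]
) -> BinaryMask:
    """Clear mask voxels whose world coordinates fall inside any region.

    Regions are dicts: ``{"type": "sphere", "center": [x,y,z], "radius": r}``
    or ``{"type": "box", "min": [...], "max": [...]}``, in world mm.
    """
    out = mask.data.copy()
    if len(regions):
        idx = np.argwhere(out)
        world = volume.index_to_world(idx)
        drop = np.zeros(len(idx), dtype=bool)
        for region in regions:
            drop |= _region_contains(region, world)
        out[tuple(idx[drop].T)] = False
    prov = dict(mask.provenance)
    prov.update(
        {"exclusion_regions": [dict(r) for r in regions], "voxel_count": int(out.sum())}
    )
    return BinaryMask(out, provenance=prov)


def mask_to_mesh(
    mask: BinaryMask,
    volume: CTVolume,
    upsample: int = 3,
    smooth_iterations: int = 30,
) -> TriangleMesh:
    """Marching-cubes surface of the binary mask at level 0.5, in world mm.

    The mask is upsampled by an integer factor first, so the isosurface
    honours voxel-cell extents rather than treating voxels as point
    samples, and the staircase is then relaxed with Laplacian smoothing
    passes.  Masks of fewer than ~50 voxels are below the filter's
    resolved scale and are returned unsmoothed (set
    ``smooth_iterations=0`` to force the raw isosurface).
    """
    if mask.count == 0:
        raise EmptyMaskError("cannot extract a surface from an empty mask")
    if upsample < 1:
        raise InvalidArgumentError("upsample must be >= 1")
    field = mask.data.astype(np.float32)
    if upsample > 1:
        field = np.kron(field, np.ones((upsample,) * 3, dtype=np.float32))
    # pad so components touching the array border still close
    field = np.pad(field, 1)
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5)
    # fine-grid index -> coarse voxel index (cell centres at (k+0.5)/up - 0.5)
    verts = (verts - 1.0 + 0.5) / upsample - 0.5
    if smooth_iterations > 0 and mask.count >= 50:
        import trimesh as _trimesh

        tm = _trimesh.Trimesh(verts, faces, process=False)
        _trimesh.smoothing.filter_laplacian(
            tm, iterations=smooth_iterations, volume_constraint=False
        )
        verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    verts = verts * volume.spacing
    verts = verts @ volume.direction.T + volume.origin
    return TriangleMesh(verts, faces)
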