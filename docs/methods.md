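# Methods

## The measurement model

The quantity of interest is the rigid transform `T_0→2` between the
planned and the achieved implant position, expressed in an
implant-intrinsic coordinate frame (origin on the reinforced central
part of the implant floor; x along the long axis toward the dorsal tip;
y toward the proximal extensions; z up). Working in the implant frame —
rather than in scanner coordinates — makes the six parameters comparable
across patients, sides and scanners.

The transform is obtained by chaining two ICP registrations:
planned → reference (`T_L→G`, which carries both meshes into the frame's
coordinates) and planned → achieved in those coordinates (`T_0→2`).
Chaining through the reference, instead of registering planned to
achieved directly in scanner space, is what attaches the decomposition
to the implant's own axes.

Assumptions:

- the pre- and post-operative scans are already rigidly co-registered
  (image fusion is upstream of this tool);
- the achieved implant is the same rigid product as the planned model,
  up to the perturbations the method explicitly handles (bent
  sub-regions, partial segmentations);
- dislocations are in the clinical range (|angles| ≲ 15°, |t| ≲ 5 mm),
  far from the pitch = ±90° Euler singularity.

## Rotation convention

Rotations compose as `R = Rz(yaw) · Ry(pitch) · Rx(roll)` — roll applied
first, yaw last. Decomposition: `pitch = asin(−R₃₁)`,
`yaw = atan2(R₂₁, R₁₁)`, `roll = atan2(R₃₂, R₃₃)`, with
pitch ∈ [−90°, 90°] and yaw, roll ∈ (−180°, 180°]. At |pitch| → 90°
(never reached clinically) yaw and roll are not separable; the package
sets roll := 0, folds the remainder into yaw, flags the result and emits
a warning. Rotation blocks that are orthonormal only to 1e-6 (numerical
noise from registration chains) are projected to the nearest rotation by
polar decomposition; anything worse is rejected.

Right-sided implants: the frame's y-axis is negated before
decomposition. Algebraically this conjugates `T_0→2` with
diag(1, −1, 1), negating yaw, roll and the y-translation — implemented
as coordinate conjugation, never by mirroring meshes, so every matrix in
the pipeline stays a proper rotation. Evaluating an xz-reflected
right-side twin of a left case reproduces the left case's parameters
exactly; this reflection-conjugation identity is tested.

## Registration

Per-iteration closed-form fit: weighted Kabsch/SVD with the sign of the
smallest singular vector corrected, so a reflection is never returned;
rank-deficient (collinear) correspondence sets are rejected.

ICP is the canonical point-to-point Besl–McKay loop. Correspondence for
a mesh target is the *exact* closest point on the target surface: a k-d
tree over triangle centroids (triangles pre-subdivided to near-uniform
size) proposes k = 16 candidate faces and an exact point-triangle
projection picks the winner. Matching against the continuous surface
rather than a finite point sample removes the sampling-quantization
bias, which otherwise plateaus around 0.1°/0.07 mm. When the target is a
point set, plain nearest-neighbour matching is used.

Point-to-point ICP converges slowly along tangential directions. The
loop therefore extrapolates along the update direction whenever two
consecutive pose deltas align (cosine > 0.9), accepting the extrapolated
pose only if the trimmed RMS improves — so the recorded residual history
is non-increasing by construction. This cuts iteration counts roughly
threefold without changing the fixed point.

Parameters (defaults): `max_iterations` 100, `rms_rel_tolerance` 1e-6,
`trim_fraction` 0 (use 0.1–0.3 for partial overlap or suspected bending
without an explicit mask), `n_samples` 20 000 source points, identity
initialization (meshes arrive near the reference pose by construction of
the chain; a displaced cold start beyond ~20° falls outside the
correspondence basin, as for any ICP). The validation suite and the
acceptance script run with 3 000 source points, 500 iterations and a
1e-8 tolerance: on clean fixtures this recovers poses to ~0.005° /
0.003 mm in a few seconds per registration, so the larger default sample
buys robustness on real, noisy segmentations rather than accuracy on
clean ones.

## Segmentation

The implant is extracted from the co-registered post-op CT by
thresholding at ≥ 1200 HU (inclusive): titanium (~3000 HU) is far above,
cortical bone (~700 HU) below. Detached high-density fragments
(fixation-screw debris) are removed by 26-connectivity component
filtering — 26-connectivity because a thin metallic shell may connect
only diagonally across voxels. The proximal screw rings, which may have
been adjusted intraoperatively, are removed with geometric exclusion
regions (spheres/boxes in world mm) — a reproducible stand-in for
interactive mask editing.

The surface is extracted by marching cubes at level 0.5 on the *binary*
mask (not on HU at 1200), so the exported geometry is consistent with
every mask edit. The mask is first upsampled ×3 so the isosurface
honours voxel-cell extents (a literal level-0.5 isosurface around a
point-sampled single voxel is an octahedron of volume 1/6 mm³, not the
voxel cube), then relaxed with 30 unconstrained Laplacian passes to
remove the staircase — this reduces the surface-area error of a
voxelized 10 mm sphere from +35 % to +1 % and lets a thin implant slab
relax toward its mid-surface, which is also what the planned thin shell
registers against. Masks below ~50 voxels are under the filter's
resolved scale and are left unsmoothed. Volume-preserving variants
(Taubin, volume-constrained Laplacian) were rejected: the former barely
attenuates the staircase, the latter compensates thin-slab shrinkage by
global rescaling, displacing extremities by more than a voxel.

World convention: `world = origin + direction · (index ∘ spacing)`;
NIfTI affines are honoured on read and reproduced on write; DICOM series
are sorted along the slice normal with rescale slope/intercept applied.

## Synthetic data

The generator stands in for the proprietary implant geometry and for
cadaver scans; its defaults define the validation conditions.

**Surrogate implant** — a 35 × 24 mm tapering shell, 0.6 mm thick, with
saddle curvature 0.022 /mm plus an asymmetric S-ripple (z-relief ≈ 9 mm
— the pronounced relief of an anatomically preformed plate, and the
reason all six pose parameters are observable from the surface alone), a
lateral extension flap, and three 2.5 mm proximal appendages. Faces are
labelled `body` / `lateral_extension` / `appendage`. The shell is
watertight with outward normals, and has no rotational self-symmetry
(180° flips re-register at > 1 mm RMS). The grid rasterizes the outline
by cell-centroid inclusion, so the surface area converges ~O(h²) under
refinement (< 1 % change on halving the 1 mm default resolution).

**Ground-truth cases** — the achieved mesh is the reference posed by the
frame-coordinate transform built from the target six parameters; both
meshes are then moved into an arbitrary local system (random offset
≤ 5° / 3 mm, emulating planning-scan coordinates; the frame chain must
undo it). Construction is self-certifying: the stored transform must
reproduce achieved from planned to 1e-9 before any perturbation.
Perturbations model exactly the failure modes a surgeon introduces:
Gaussian vertex noise (σ in mm), contiguous occlusion (fraction of faces
around a random seed face), and a hinge bend of the lateral extension
about its attachment line.

**CT phantoms** — voxels are classified against the shell *mid-surface*
(surface samples offset inward by half the thickness along outward
normals): a voxel is implant when within max(shell, 1.1 voxel)/2 of the
mid-surface. This emulates the partial-volume blob a sub-voxel titanium
plate produces in CT — a roughly one-voxel slab centred on the plate —
rather than inflating the shell on both sides. The phantom embeds the
implant in soft tissue (40 HU) with a bony shelf (700 HU) touching the
implant underside (the hard case for threshold separation), an optional
detached screw blob at implant HU, an air border, and optional Gaussian
HU noise. Default spacing 0.75 mm isotropic, matching the scanner
protocol's reconstruction slice thickness; 0.4 mm matches its overlapping
increment.

What the phantoms do **not** model: metal artefacts and beam hardening,
anisotropic PSF, anatomical orbit geometry, and segmentation ambiguity
where implant and bone HU overlap. Passing tests therefore demonstrate
correctness of the measurement chain, not robustness to scanner physics.

## Numerical choices

- Rigid-transform invariants enforced at 1e-9 (orthonormality, det +1,
  exact last row); vertex welding at 1e-6 mm; degenerate faces dropped
  below 1e-12 mm².
- Surface sampling is area-weighted uniform (square-root barycentric
  trick), seeded, and the only stochastic element of the pipeline;
  identical inputs and seeds give bit-identical reports.
- Frame alignment RMS > 0.5 mm raises a shape-mismatch warning (planned
  and reference should be the same product).
- Reports always contain the raw 4×4 matrix next to the decomposed
  parameters, so downstream users are not bound to the Euler convention.

## Validation conditions and problem sizes

The test suite and acceptance script use 3 000 ICP source points,
500-iteration budget, 1e-8 relative tolerance; phantoms at 0.75 mm
spacing. Observed recovery under these conditions: ≲ 0.01° / 0.01 mm on
clean meshes, ≲ 0.5° / 0.4 mm end-to-end through voxelized phantoms,
within 1° / 0.5 mm with a 10° bent extension when the bent region is
excluded from matching.

## Known limitations

- Numeric agreement with commercial planning software cannot be checked
  directly — such systems do not publish their ICP variant, sampling
  density or convergence criteria; parameter recovery on synthetic
  ground truth is the validation surface instead.
- Landmark placement on real implants is user-supplied; the frame is
  only as reproducible as its landmarks.
- Scan-to-scan fusion is out of scope; a pre-computed volume-to-volume
  transform can be applied to extracted meshes instead.
- No global registration: initialization must be within the ICP basin
  (identity after the frame chain is sufficient for clinical-range
  dislocations).
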