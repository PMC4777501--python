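# oipf — Orbital Implant Positioning Frame

Quantifies how far a surgically placed orbital implant ended up from its
preoperatively planned position. Distance maps and slice-by-slice visual
checks hide rigid-body dislocations (a pure rotation can look like a good
fit on every slice); `oipf` instead reports the full rigid deviation —
roll, pitch and yaw in degrees plus three translations in millimetres —
expressed in an implant-intrinsic coordinate frame, so results are
comparable across patients and across left- and right-sided
reconstructions.

Intended users: researchers in computer-assisted craniomaxillofacial
surgery evaluating orbital reconstructions from co-registered pre- and
post-operative CT.

## Method

All meshes are STL in millimetres. Given the planned implant model `M0`,
the achieved implant `M2` (a pre-segmented STL, or segmented here from
the co-registered post-op CT by thresholding at ≥ 1200 HU), and a
reference implant carrying the positioning frame:

1. **Frame alignment** — ICP-match `M0` onto the reference implant:
   `M0,G = T_L→G · M0`.
2. **Joint mapping** — apply the same `T_L→G` to `M2`, preserving the
   planned-vs-achieved relationship while expressing it in reference
   coordinates: `M2,G = T_L→G · M2`.
3. **Placement registration** — ICP-match `M0,G` onto `M2,G`:
   `M2,G = T_0→2 · M0,G`.
4. **Decomposition** — express `T_0→2` in the implant frame and split its
   rotation as `R = Rz(α) · Ry(β) · Rx(γ)` (roll γ first, pitch β second,
   yaw α third): `β = asin(−R₃₁)`, `α = atan2(R₂₁, R₁₁)`,
   `γ = atan2(R₃₂, R₃₃)`. Translations are the frame-origin displacement
   along the frame axes; named key points (superiormost point of the
   medial ledge, dorsal tip) get their own displacement vectors.

For right-sided implants the frame's y-axis is flipped (mirroring over
the xz-plane), which sign-opposes yaw and roll so left and right cases
are directly comparable.

Registration is point-to-point ICP (nearest point on the target surface,
trimmed correspondences optional for partial overlap / bent regions) with
a closed-form Kabsch/SVD fit per iteration. Everything is deterministic
given a seed.

Because the commercial implant geometry is proprietary, the package ships
a parametric surrogate generator (`oipf.synthetic`) that reproduces the
features the method depends on — thin curved shell, long axis, lateral
extension, proximal screw-ring appendages, no rotational self-symmetry —
plus ground-truth posed cases and voxelized CT phantoms with HU strata
(air −1000, soft tissue 40, bone 700, implant 3000).

## Worked example

```python
from oipf import (ICPParams, evaluate_placement, generate_surrogate,
                  make_case, specimen_pose)

mesh, frame = generate_surrogate()                # reference implant + frame
truth = specimen_pose("specimen2")                # roll -11.2, pitch -5.3, yaw 0.1 deg
case = make_case(mesh, frame, truth, seed=11)     # planned + achieved meshes
icp = ICPParams(n_samples=3000, max_iterations=500, rms_rel_tolerance=1e-8)
report = evaluate_placement(case.planned, case.achieved,
                            case.reference, case.frame, icp=icp)
p = report.pose
print(f"roll {p.roll:+.1f} deg, pitch {p.pitch:+.1f} deg, yaw {p.yaw:+.1f} deg")
print(f"t = ({p.t_x:+.1f}, {p.t_y:+.1f}, {p.t_z:+.1f}) mm")
```

prints

```
roll -11.2 deg, pitch -5.3 deg, yaw +0.1 deg
t = (+4.1, -2.9, -0.1) mm
```

i.e. the pipeline recovers the dislocation the case was built with: the
implant is rolled 11.2° about its long axis, pitched 5.3°, and displaced
4.1 mm dorsally and 2.9 mm laterally relative to the plan — exactly the
kind of deviation that slice views miss.

The same pipeline is available from the shell:

```bash
oipf simulate --preset specimen2 --seed 11 --out case/
oipf evaluate --planned case/planned.stl --achieved case/achieved.stl \
              --reference case/reference.stl --frame case/frame.json \
              --side left --out report/
oipf segment  --ct case/phantom.nii.gz --threshold 1200 --out seg/
oipf decompose --matrix T.json
```

`evaluate` writes `report.json` (pose, raw 4×4 matrix, both ICP results,
full provenance) and `report.csv` with columns
`id, roll, pitch, yaw, t_x, t_y, t_z`.

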