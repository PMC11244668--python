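# Methods

This note documents the models, conventions and numerical choices behind
`dosecloud`, in the order the pipeline uses them.

## Coordinates and the dose grid

Dose lives on a regular lattice in patient millimetre coordinates with axes
x = left–right, y = anterior–posterior, z = superior–inferior, voxel-center
convention and 0-based indices. `DoseGrid.origin` is the center of voxel
(0,0,0). Default grid pitch is 2 mm isotropic, the resolution commonly used
for cranial dose calculation; geometry-sensitive checks (normalization
contract, sphere-volume fidelity) use 1 mm.

## Rigid setup errors: the static dose cloud

A setup error is a rigid map of the patient. We simulate its dosimetric
effect by the *static dose cloud* approximation: the delivered dose field is
frozen in room coordinates, so the dose seen by the (displaced) anatomy is
the original field pulled back through the patient map,

    out(x) = D(T_patient(x)),

with structures fixed on the lattice. This stands in for a full dose
recomputation with unchanged monitor units; for small rigid displacements of
a cranial target the differences (attenuation-path changes, surface-contour
changes) are second-order. A single flag (`patient_moves=False`) flips the
sign convention to "the dose cloud moves".

Conventions, declared rather than inferred because vendor software rarely
documents its own:

* Rotation order is fixed intrinsic **yaw (z) → pitch (x) → roll (y)**,
  right-handed, angles in degrees. At the ≤2° magnitudes studied the order
  effect is second-order, but fixing it makes results reproducible.
* A scenario's magnitude is applied **simultaneously on all three axes** by
  default (one worst-case scenario per magnitude); per-axis application is
  available via `applied_axes`.
* Resampling is trilinear only. It is exact for affine fields, which gives
  the test suite closed-form oracles; no spline option is offered so that
  the oracle equivalence stays exact.
* Samples falling outside the source lattice during resampling are set to
  0 Gy; if more than 0.1% of the voxels of interest (the brain mask in the
  pipeline) were extrapolated this way, a warning is logged.
* A zero-magnitude scenario returns a bit-for-bit copy: the identity is
  exact, not "within interpolation error". A scenario followed by its exact
  inverse recovers a smooth Gaussian test field to within 0.8% of its
  maximum at 2 mm spacing (regression bound frozen from a measured 0.66%).

## The synthetic cohort

The generator emulates the statistical structure of a multi-metastasis
treatment cohort, not any individual anatomy:

| parameter | default | rationale |
|---|---|---|
| brain | ellipsoid, semi-axes (70, 85, 60) mm | adult cranial dimensions |
| GTVs per patient | uniform on 1–6 | multi-metastasis caseload; 15 patients then carry ≈50 GTVs in total |
| GTV radius | uniform on 5–15 mm | 1–3 cm diameter metastases |
| GTV→PTV margin | 2 mm isotropic | standard setup margin; PTV = union of expanded GTVs |
| placement | rejection sampling, ≥5 mm surface separation, PTV ≥3 mm inside the brain surface | separable targets, no surface clipping |
| isocenter | mean of GTV centroids | single-isocenter technique |
| prescription | 40 Gy/5 fx if ≤3 GTVs else 42 Gy/7 fx | a declared deterministic stand-in for an unstated clinical rule; configurable |
| OARs | brainstem capsule, eye/lens spheres, optic-nerve capsules, chiasm sphere | fixed anatomically plausible positions relative to the brain ellipsoid |

Generation is bitwise reproducible from `(seed, config)`; infeasible
configurations fail with the violated constraint named after a bounded
number of rejection attempts.

### The dose kernel

Per target, radially from the GTV center with GTV radius `R_g`, PTV radius
`R = R_g + margin` and penumbra width `w`:

* `Rx · (1 + hotspot)` inside the GTV (default hotspot 0.15 — stereotactic
  plans run hot at the lesion center),
* a linear ramp down to exactly `Rx` at the PTV surface, so that the 5% of
  the PTV left uncovered by the 95% normalization lives in the margin rim,
  not inside a GTV (baseline GTV V100% ≈ 100%, as in clinical plans),
* a Gaussian-tail penumbra `Rx · exp(−ln2 ((r−R)/w)²)` beyond the surface:
  monotone, sigmoid-shaped, with its 50% point exactly `w` mm beyond the
  PTV surface.

Targets combine by **voxelwise maximum** (summation would create unphysical
>2×Rx hotspots for nearby targets). A brain-wide Gaussian bath
(`bath_level · Rx` at the isocenter, 60 mm decay length) models scatter and
low-dose spill so brain V4/V12 are nonzero.

The two techniques differ only in these knobs: coplanar-like
`w = 6 mm, bath 0.12`; non-coplanar-like `w = 4.5 mm, bath 0.10`. Steeper
penumbra ⇒ lower gradient index and lower brain V12, reproducing the
qualitative contrast between couch-rotated and coplanar arc geometries.
What the kernel deliberately does **not** model: arc-dependent dose
anisotropy, MLC aperture shapes, tissue heterogeneity, and realistic CI
differences between techniques — conclusions about those do not transfer
from passing tests.

## DVH metrics and normalization

* Volumes are voxel counts × voxel volume; no partial-volume or surface
  estimation. At 2 mm this limits accuracy for the smallest targets (the
  1 mm grid restores ≤2% sphere-volume error).
* `Vx` counts dose ≥ threshold, inclusive. `Dmax` is the voxel-point
  maximum (conservative; not D0.03cc). `D95` is the 5th percentile of voxel
  doses with linear interpolation between sorted values.
* **Normalization.** The scale factor is `Rx / d(m)` where `d(m)` is the
  m-th highest PTV voxel dose, `m = round(0.95 n)`, nudged by one part in
  10¹² so the defining voxel stays on the covered side after the
  floating-point multiply. This guarantees V100%(PTV) = 95% within half a
  voxel-count step *by construction*; the interpolated D95 would miss that
  contract by up to ~1 voxel at unlucky mask sizes. The operation is
  idempotent to 1e-12 and scale-invariant.
* Empty structures raise an explicit "undefined metric" error rather than
  returning 0 — a silent zero for a missing OAR would read as a perfect
  sparing.
* Paddick indices: `CI = TV_PIV²/(TV·PIV) ∈ [0,1]`, `GI = PV50/PIV ≥ 1`
  (isodose volumes nest; the constructor enforces it).

## 3D gamma analysis

For each reference voxel `r` above the low-dose threshold,

    γ(r) = min over e of sqrt( ((D_e(e) − D_r(r)) / (Δ·D_norm))² + (‖r−e‖/δ)² )

with Δ = 3% dose criterion, δ = 2 mm distance-to-agreement. Decisions:

* **Roles:** the perturbed plan is the *evaluated* distribution, the
  original plan the *reference*; γ is not symmetric and the suite pins the
  wiring.
* **Normalization:** global (reference Dmax) by default — the low-dose
  threshold is already defined against the original plan's maximum, and
  patient-specific QA guidance recommends global; local mode is available.
* **Threshold:** reference voxels below 10% of reference Dmax are excluded.
* **Search:** candidate points on a lattice of pitch `interp_step`
  (default δ/10) within a sphere of radius 2δ; γ is capped at 2; any voxel
  whose constrained minimum exceeds 1 would be re-searched with a doubled
  radius before being reported as failing (with the default radius already
  at cap·δ this is a no-op).
* **Pass:** γ ≤ 1 inclusive, with 1e-9 absolute slack so an exactly
  critical voxel (uniform 3% offset ⇒ γ ≡ 1) is not failed by round-off.
* **Implementations:** the production path is a compiled kernel that visits
  offsets in order of increasing distance and stops per voxel once no
  farther candidate can lower its minimum — an exact pruning. The
  verification oracle (`brute_force_gamma`) is an independent
  SciPy-interpolation dense search at 4× finer pitch with no pruning,
  guarded to ≤32³ grids; the two agree to |Δγ| ≤ 0.02 for γ ≤ 1.2 on the
  test fixtures, the residual being candidate-lattice quantization.

## Cohort experiment and statistics

Per patient and technique, four scenarios (+1/+2 mm, +1/+2°) are evaluated
against fixed masks; variations are modified − original. Gamma is computed
only for the largest translation and rotation by default (flag to enable
all). PTV-level quantities contribute one observation per patient (n = 15);
per-GTV coverage pools every GTV as one observation (n = total GTVs,
deliberate pseudo-replication mirroring common practice). The paired t-test
uses the n−1 sample SD of differences with a two-sided Student-t p-value;
all-zero differences return t = 0, p = 1 by convention. Outliers use Tukey
fences at 1.5·IQR with linearly interpolated quartiles. No multiple-testing
correction is applied; p-values are raw at the 0.05 convention.

Problem sizes: the default experiment is 15 patients × 2 techniques ×
4 scenarios at the 2 mm grid (≈0.4 M voxels per plan), which runs in a few
minutes on one core; the oracle-vs-fast gamma comparison uses 16³ grids and
a raised (55%) threshold to keep the quartic-cost oracle tractable.

## Persistence

The native bundle is a directory with a JSON manifest (geometry,
prescription, technique, grid spec, seed, SHA-256 of the payload) plus a
compressed `.npz`; round-trips are bitwise and tampering is detected.
DICOM RT Dose import/export maps stored integers × `DoseGridScaling` and
the `ImagePositionPatient`/`PixelSpacing`/`GridFrameOffsetVector` geometry;
non-uniform frame offsets are rejected. Writing quantizes to 32-bit, so a
round trip is exact to one scaling quantum.

## Known limitations

* The static dose cloud ignores attenuation-path changes; it is a
  first-order model of a TPS recomputation with fixed monitor units.
* Spherical targets and geometric OARs make conformity/gradient indices
  analytically checkable but flatter the CI distribution than clinical
  contours would.
* Voxel counting at 2 mm biases volumes of the smallest structures (lenses,
  chiasm); their Dmax is still meaningful, their volumes are not reported.
* Technique contrast is carried entirely by penumbra width and bath level;
  observed between-technique differences in any other metric are artifacts
  of geometry, not of arc physics.
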