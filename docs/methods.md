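# Methods

`petgtv` re-creates, on synthetic digital phantoms, a clinical comparison
of four ways to contour the gross tumor volume (GTV) of an esophageal
tumor — a gradient-based PET edge detector, two SUV-threshold rules and a
CT-criteria reading — and the downstream effect of the chosen contour on
a radiotherapy plan. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic setting can and
cannot show.

## The phantom model

Each case is a straight, z-aligned solid cylinder ("tumor") of length
*L* and radius *r* at SUV 6.0 inside a uniform background at SUV 1.0.
The PET-like image is this two-level indicator convolved with an
isotropic Gaussian point-spread function (default σ = 4 mm, a typical
clinical PET resolution), optionally plus additive Gaussian noise in SUV
units, clipped at zero. The CT-like image is the tumor support dilated
by a *wall-thickening margin* (default 5 mm) and binarised — a stand-in
for the fact that a CT reader contours the entire thickened esophageal
wall, not the tumor proper.

Grid: 64 × 64 × 48 voxels at (2, 2, 4.25) mm. The 4.25 mm slice
thickness matches the axial sampling of the PET acquisition being
emulated; the in-plane 2 mm is a desk-scale choice (the scanner's
in-plane sampling is not constrained by the emulated protocol). Cohorts
draw *L* uniformly from 3.44–11.00 cm — the range of pathological tumor
lengths the study design targets — and *r* from 8–12 mm.

Known simplifications: the esophagus is straight (no curved centerline),
uptake is homogeneous inside the tumor, and noise is additive Gaussian
rather than a reconstructed Poisson process. Consequently the default
study (noiseless) measures *method geometry* — partial-volume bias,
threshold placement, margin arithmetic — not robustness to clinical
image quality. Passing tests say nothing about heterogeneous uptake,
motion, or FLT-avid inflammation.

## Gradient-based segmentation

The detector finds, along rays from a user seed near the lesion centre,
the radius of the strongest negative radial derivative of the
(interpolated, lightly smoothed) SUV profile:

1. **Six-axis initialisation.** Along ±x, ±y, ±z the edge radius is
   detected; the six half-axes define an ellipsoid.
2. **Dense ray casting.** 320 near-uniform directions (face centroids of
   a twice-subdivided icosahedron) are searched out to
   `bounding_scale ×` the ellipsoid radius for that direction. Profiles
   are sampled by trilinear interpolation at 0.5 × min(spacing) steps,
   smoothed with a 1-sample Gaussian, differentiated by central
   differences.
3. **Edge continuity.** Rays whose edge strength is below 30 % of the
   strongest ray are rejected; every ray's radius is replaced by the
   median over its 9 nearest directions (rejected rays inherit that
   median), enforcing a continuous edge surface.
4. **Rasterisation.** The star-convex region is voxelised
   (nearest-direction lookup) and the connected component containing the
   seed is returned.

Because only derivative *locations* matter and the rejection threshold is
relative, the mask is invariant under multiplication of the image by any
positive constant — the property that distinguishes it from a fixed SUV
threshold.

`bounding_scale` defaults to 2.0: the six-axis ellipsoid is *inscribed*
in the lesion, so for elongated lesions (tube aspect ratios up to ~7:1
occur in this cohort) it under-bounds directions ~10° off the long axis;
a factor of 2 keeps the true cap inside the search window while still
excluding distant structure. The method cannot represent shapes that are
not star-convex about the seed; that is a documented limitation, not a
failure mode of these phantoms.

Validation anchor: for a Gaussian-blurred sphere the radius of maximum
|radial derivative| can be computed independently by dense 1-D quadrature
of the radial convolution integral. On the R = 15 mm, σ = 4 mm
calibration phantom the mask's equivalent-sphere radius agrees with that
oracle to ~0.2 mm (tolerance 1 mm). Note the oracle radius itself is
≈ 14.0 mm, not 15: blur on a curved boundary moves the steepest gradient
inward — the same partial-volume geometry that makes PET contours run
small.

## Threshold methods and CT criteria

Both threshold rules operate inside a user sphere over the tumor
(membership by voxel centre, thresholds inclusive): a fixed 1.4 SUV, and
30 % of the maximum SUV found inside the sphere. The result is the
26-connected component nearest the sphere centre (ties toward the larger
component). An empty result is returned with a warning, not an error.

The CT emulation applies, per axial slice, the reader's size criteria to
the thickened-wall image: keep a region when its wall thickness is
≥ 5 mm **or** its diameter ≥ 10 mm. Wall thickness is measured as twice
the region's maximum Euclidean distance to background (the annulus width
for a hollow cross-section, the diameter for a solid one); diameter as
the maximum pixel-centre distance plus one pixel (pixels count at full
size, as slices do along z).

## Geometry measures

Longitudinal length is slab extent: N occupied slices → N × dz (first
and last slices count at full thickness), measured along z. The overlap
index is OI = |GTV_PET ∩ GTV_CT| / |GTV_CT| — the inclusion of the PET
contour in the CT contour, not a symmetric Dice score. Volumes are voxel
count × voxel volume.

## Margins, planning grid, synthetic dose

CTV = GTV ⊕ ellipsoid(10, 10, 30) mm; PTV = CTV ⊕ 5 mm, implemented as
a scaled Euclidean distance transform (≤ 1 + 1e-9, so exact-integer
margins land on-grid). Planning runs on a 2.5 mm isotropic grid onto
which GTV masks are resampled (nearest-neighbour at voxel centres), as a
treatment planning system would use its own dose grid. 2.5 mm divides
all three protocol margins, so the realised expansions are exact: the
CTV craniocaudal extent exceeds the GTV extent by exactly 6.0 cm — on
the 4.25 mm PET grid the 30 mm margin could only be realised as 7.06
slices.

The dose model is a conformal bath, not a beam arrangement: the PTV
expanded by two penumbra sigmas, convolved with a Gaussian penumbra
(default σ = 5 mm), scaled by a global factor found by 1-D bisection
(80 iterations, then a 1e-9 relative nudge so the coverage test survives
the rescaling to Gy) as the smallest factor with ≥ 95 % of the PTV at
the 60 Gy prescription. If that factor would put the maximum dose at or
above 110 % of prescription the constraint set is reported unsatisfiable
together with the achievable coverage. Dose falls monotonically with
distance outside the PTV, which is the property that converts "smaller
PTV" into "less lung and heart dose" case by case.

DVHs are cumulative with 0.1 Gy bins; V_x uses inclusive ≥. D_q (minimum
dose to the hottest q %) is computed from the exact sorted voxel doses
(sort-descending, take the ⌈qn/100⌉-th); the binned curve is used only
for plotting and curve reads. HI = (D2 − D98)/prescription × 100 %;
CI = (Vt,ref/Vt)·(Vt,ref/Vref) with the prescription isodose as the
reference level (the coverage criterion is stated at the prescription
line, and no other reference level is part of the emulated protocol).

Organs at risk are fixed geometry on the planning grid: two lateral lung
ellipsoids, an anterior heart ellipsoid, a posterior 5 mm-radius cord
cylinder spanning the full craniocaudal extent — scaled-down analogs
whose absolute dose numbers are not comparable to thorax anatomy, but
whose *between-plan differences* are meaningful because both plans see
identical organs.

## Statistics

Pearson correlations (length of each method vs true length) and
two-tailed paired t-tests (gradient-based vs CT-based plan metrics) use
exact t-distributions — n is 10, so normal approximations are avoided.
Identical pairs return t = 0, p = 1; constant non-zero differences are
flagged degenerate with no p-value. No multiple-testing correction is
applied; each comparison is reported at α = 0.05. Because the synthetic
dose model has almost no case-to-case noise, even trivial CI/HI
differences can reach significance; the magnitude columns in the summary
are the guard against over-reading those.

## Reproducibility and problem sizes

Every stage is a pure function of (config, seed); per-case noise seeds
are spawned from the study seed. The default study is 10 cases on the
64 × 64 × 48 phantom grid and a 52 × 52 × 82 planning grid — sizes chosen
so a full study, including both plans per case, completes in seconds on
one CPU while keeping voxelisation error well below the one-slice length
tolerance the analyses rely on.

## Known limitations

* Star-convex masks only; no curved esophagus, no heterogeneous uptake.
* The CT emulation sees a clean binary wall image; real CT reading
  contends with gas, contrast and inter-observer variability.
* The dose model has no beams, heterogeneity corrections or optimiser
  trade-offs; conformity indices are higher and more uniform than a real
  five-beam plan would produce.
* Absolute organ-at-risk doses depend on the fixed phantom anatomy and
  transfer only as directions of effect, not magnitudes.
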