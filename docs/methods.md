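# Methods

This note documents the models behind `phantomcal`, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Calibration model

Each scan is modelled as affine in density: `I = g·ρ + b + ε`,
`ε ~ N(0, σ_noise)`.  The calibration line is fitted by unweighted ordinary
least squares of certified density on mean insert intensity — density on
intensity, because that is the direction in which the line is applied — and
solved from the normal equations in closed form.  Two design choices:

* **Unweighted OLS.**  The inserts have similar volumes, so their mean
  intensities have similar standard errors; variance weighting would change
  nothing detectable and would require noise estimates we do not otherwise
  need.
* **Clamping.**  Mapped densities are floored at 0 g/cc.  Air voxels with
  noise can otherwise map slightly negative, which is unphysical and breaks
  mass bookkeeping downstream.

Mapped voxels whose prediction falls outside the certified insert range
[min ρᵢ, max ρᵢ] rely on extrapolation of the line; `count_extrapolated`
reports them.  Because the top insert (PTFE, ≈2.15 g/cc) exceeds cortical
bone density, cortical readings are interpolations — one of the practical
advantages of a polymer phantom over low-density commercial insert sets.

Insert certification: `ρ = m/V·1000` (g, mm³ → g/cc), with the mean of the
laser-scan and CT-scan densities taken **before** rounding; all rounding is
report-time only.

## Agreement statistics

Two density maps of the same object are compared voxel-paired over a mask:
bias (mean difference), precision (SD of differences, n−1 denominator),
limits of agreement (±1.96·SD), Pearson R, and the OLS slope of measurement
2 on measurement 1.  For two scans with independent noise of SD `s` (density
units), the expected precision is `s·√2`; the test suite and acceptance
script verify this ratio.  Note the regression slope between two *noisy*
measurements is attenuated below 1 by errors-in-variables; it is reported as
a descriptive statistic, not corrected.

## Sensitivity analysis

The factorial design crosses voltage × exposure × filtration (2×2×3 by
default, voltage slowest, filter fastest).  The sensitivity σ is the
**sample** standard deviation (n−1) of the per-protocol bone-masked mean
densities; 6σ is reported alongside.  Because the line is refitted for every
scan, protocol-dependent gain and offset cancel, and the pipeline σ on
synthetic data reflects only noise and segmentation variability — orders of
magnitude below the published-study σ, which includes physical effects
(beam hardening, spectrum shifts) the affine scanner model deliberately
omits.

The one-way ANOVA uses the classical between/within F statistic
(`scipy.stats.f_oneway`); a definitional sum-of-squares oracle guards it in
the tests.  The observational units for a voxel-population ANOVA are a
genuine modelling choice — whole-scan voxel populations are so large that
any difference is "significant" — so the package exposes fixed-size seeded
subsampling through its group inputs, and the calibration utility
(`anova_null_rejection_rate`) checks the test rejects at ≈α under the null.

## Synthetic scenes

**Phantom.**  Five cylinders (defaults: r = 3 mm, h = 8 mm on a 9 mm ring,
0.4 mm voxels) in a base polymer block of 1.05 g/cc, insert densities taken
from the certified mass/volume means (≈1.15, 1.31, 1.42, 1.62, 2.15 g/cc).
Surface voxels get volume-weighted mixed densities via 3× per-axis
supersampling — 27 sub-samples per voxel keeps the insert-mass error below
0.5 % at these grids while staying cheap.

**Femur.**  An idealised tapered tube, not an anatomical mesh: periosteal
radius 7→6 mm along the shaft, 1.8 mm cortical shell at 1.95 g/cc, medullary
canal with marrow at 1.0 g/cc and a trabecular network at 1.85 g/cc tissue
density.  The network is a Gaussian random field smoothed to a 0.5 mm
correlation length and thresholded at the canal-restricted quantile that
realises the target BV/TV (default 0.30); the realised fraction is recorded
and required within ±0.02.  Cortical voxels are pure (no partial-volume
mixing), which makes shell-masked means exact oracles.  Densities follow the
g/cc range reported for femoral bone (≈1.1–2.0 g/cc).

**Scanner.**  `gain = g₀·(kV/100)^0.65·(ms/100)^0.35·f(filter)` with
`g₀ = 1000` intensity units per g/cc, `offset = 40·f(filter)`, filter
factors 1.0 / 0.92 / 0.85 / 0.72 for none / 0.25 mm Cu / 0.25 mm Sn /
0.75 mm Sn, additive Gaussian noise with σ = 5 intensity units by default.
The exponents and factors are invented (no noise magnitudes or gain curves
are published for either scanner); only monotone affinity in density
matters for the calibration claims, and the constants live in
`INTENSITY_MODEL` so sensitivity to them can be probed.  Default noise was
chosen so insert-mean standard errors stay below 0.1 % of the mean — the
calibration error is then dominated by the model, not by sampling.

**Surgical stages.**  The broach cavity is a tapered square prism (defaults
5→3 mm width, 16 mm long) entering from the proximal end.  Trabecular bone
inside the cavity is removed; a fraction `debris_retention` ∈ [0,1] of the
removed mass is re-deposited into the Euclidean distance-transform band of
1 mm around the cavity by converting marrow voxels to bone, nearest to the
cavity surface first (seeded random tie-break) — debris concentrates at the
interface, which is the osseodensification picture.  The final voxel takes a
fractional density so the mass budget closes exactly; if the shell saturates
(occupancy 1 everywhere), the surplus is reported as unplaced mass rather
than silently dropped.  `retention_for_shell_bvtv_delta` inverts the
bookkeeping: given a target shell BV/TV increase in percentage points it
returns the retention that supplies exactly that many converted voxels.
Implantation fills the cavity with implant material (4.43 g/cc, a titanium
alloy) and touches no bone voxel.

**Clinical-CT analogue.**  Block-averaging to `round(0.5 mm / spacing)`
voxels per axis followed by independent re-noising.  Block averaging is the
partial-volume effect in its purest form: each coarse voxel is the exact
mean of its source block, so region means are preserved while sub-voxel
structure is blended.  Trailing partial blocks average over the voxels
actually present.

## Registration and ROIs

* ICP uses k-d-tree nearest-neighbour correspondences with an SVD (Kabsch)
  update and no outlier trimming — stages are the same specimen, so
  trimming is unnecessary.  Degenerate (collinear) point sets are rejected
  at the SVD rank check.
* Label transfer is explicit nearest-neighbour through world coordinates
  (positions within half a pitch of the outermost voxel centers still
  belong to the grid); density transfer uses trilinear interpolation.
  Content mapping outside the source grid becomes 0 — round-trip tests
  therefore restrict claims to in-grid content.
* Gruen zones are a deterministic 3-D operationalisation of the
  radiographic convention: implant axis from PCA of the implant mask
  (oriented proximally along the femur frame), thirds along the implant
  length, lateral/medial split by the sagittal plane, zones 1–3 lateral
  proximal→distal, 4 distal to the tip, 5–7 medial distal→proximal.  The
  femur frame is always right-handed; the side flag flips which
  medial–lateral sign counts as lateral.
* The interface shell is `0 < d ≤ t` of the anisotropic-spacing distance
  transform around the cavity/implant, intersected with the bone domain.
  On a discrete grid the effective shell thickness is biased low by
  ≈0.3 voxel pitches (distances are measured to voxel centers); analytic
  volume comparisons in the tests use grids fine enough for this to be
  inside tolerance.
* Zone summaries report both bone-masked means (real-density reading) and
  whole-ROI means (apparent-density reading), since published zone
  comparisons are ambiguous between the two.  A 1-voxel rind around the
  implant can be excluded from the bone mask to guard against bright-metal
  bleed-in.

## Problem sizes

Default validation scenes are desk-scale: the phantom grid is ≈26×65×66
voxels at 0.4 mm, the femur 150×100×100 at 0.16 mm (≈1.5 M voxels), with a
48×52×52 specimen for the 12-protocol DOE.  These sizes put every
statistical claim (≥10⁵ paired voxels for agreement, per-insert standard
errors ≪ tolerance) in reach while keeping the whole suite and the
acceptance script in the tens of seconds.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the pipeline recovers known ground truth
under its own forward model: affine intensity, Gaussian noise, ideal
geometry, no beam hardening, scatter, rings or metal streaks, monochromatic
contrast, and an idealised femur.  They do **not** demonstrate accuracy on
real scanner data; in particular the published accuracy (±0.097 g/cc) and
precision (±0.052 g/cc) of the physical phantom derive from cadaveric and
ovine scans that have no public deposit and are replaced here by
parameter-recovery properties with known answers.  The published definition
of "accuracy" is also not given as a formula; this package operationalises
it as bias ± 1.96·SD limits of agreement.

Known limitations: no DICOM ingestion; no polychromatic or artifact
physics; the femur is a tube, so Gruen zones are geometrically clean in a
way anatomical femurs are not; broaching debris is modelled as whole-voxel
occupancy conversion rather than a continuum compaction field; the ANOVA
treats voxel subsamples as independent observations, ignoring spatial
correlation.
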