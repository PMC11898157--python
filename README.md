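# phantomcal

Quantitative CT densitometry for periprosthetic bone: calibrate CT intensity
to physical density with a multi-insert phantom, and quantify how broaching
and uncemented implantation change bone density and bone volume fraction
around a femoral stem.

The package is aimed at researchers in bone biomechanics and orthopaedic
imaging who need the whole measurement chain in one place — and need it
testable without scanner access.  Every stage therefore runs end-to-end on a
synthetic CT generator with exact ground truth (known voxel-wise density,
tissue labels and total bone mass).

## The measurement model

A density calibration phantom (DCP) with polymer inserts of certified density
ρ₁…ρₙ is scanned alongside the specimen.  Each scan is assumed to map density
affinely to intensity, so after segmenting the inserts and computing their
mean intensities Ī₁…Īₙ, ordinary least squares gives the per-scan line

    ρ(I) = a·I + b        (density on intensity, g/cc)

which is applied voxel-wise to map the whole scan to density.  Insert
densities are certified from first principles: ρ = m/V with the mass from an
analytical balance and the volume from two independent scans (laser and CT),
averaged unrounded.

On top of the calibrated density maps the package computes:

* **Agreement statistics** (Bland–Altman style): bias, SD of voxel-paired
  differences, 1.96·SD limits of agreement, Pearson R and regression slope —
  the accuracy/precision vocabulary for comparing two density measurements.
* **Scan-parameter sensitivity**: a full-factorial design over scanner
  voltage, exposure and filtration; σ is the sample SD of the per-protocol
  mean densities, reported with its 6σ span, plus a one-way ANOVA.
* **Registration and ROIs**: rigid ICP (SVD/Kabsch) to align surgical
  stages, an ISB-style femur coordinate system, 3-D Gruen zones 1–7 around
  the implant axis, and a distance-transform interface shell (default 1 mm)
  at the bone–implant boundary.
* **Morphometry**: BV/TV (bone volume over total volume) per ROI, per-zone
  mean densities, and stage-change reports (pre-surgery → post-broaching →
  post-implantation).
* **Partial-volume analysis**: block-averaging micro-CT volumes to ~0.5 mm
  voxels reproduces the clinical-CT reading, where trabecular apparent
  density drops (bone blends with marrow inside each coarse voxel) while
  cortical readings survive.

The synthetic generator mirrors the physical workflow: a five-insert polymer
phantom (certified densities ≈ 1.15–2.15 g/cc), an idealised femur (cortical
tube + thresholded-Gaussian-field trabecular network at a target BV/TV),
mass-conserving broaching that compacts removed trabecular bone into the
interface shell (osseodensification), implant insertion, and an affine
scanner model with protocol-dependent gain/offset plus Gaussian noise.

## Worked example

`examples/02_calibrate_and_map.py` renders the synthetic phantom, fits the
line and maps the scan:

```
slope     1.086897e-03 g/cc per intensity unit (true 1/gain = 1.086957e-03)
intercept -0.0398 g/cc,  R^2 = 1.000000

mapped insert means vs certified densities:
  Nylon    mapped 1.1523  certified 1.1524 g/cc
  PEEK     mapped 1.3135  certified 1.3134 g/cc
  Acetal   mapped 1.4234  certified 1.4232 g/cc
  PPS      mapped 1.6230  certified 1.6231 g/cc
  PTFE     mapped 2.1473  certified 2.1474 g/cc
```

The fitted slope matches the inverse scanner gain to 5 decimal places and
every insert maps back to its certified density within the noise standard
error — the calibration is recovering ground truth, not echoing it.  The
other examples cover insert certification (`01`), the sensitivity DOE
(`03`), the micro-CT vs clinical-CT partial-volume comparison (`04`), the
surgical-stage BV/TV analysis (`05`) and ICP registration (`06`); each
prints a few numbers and says what they mean.

## Layout

```
src/phantomcal/
  volume_io.py            volumes + spacing metadata, MetaImage/NIfTI/TIFF, block averaging
  synthetic_ct.py         phantom/femur/stage generators, scanner model
  segmentation.py         insert segmentation, histograms, watershed bone mask
  density_calibration.py  insert certification, OLS line, density mapping, agreement
  registration_roi.py     ICP, femur frame, Gruen zones, interface shell, BV/TV
  sensitivity_stats.py    DOE runner, sensitivity summary, ANOVA, stage reports
  reference_data.py       published insert measurements and factorial means
  config.py               YAML loaders for the generator specifications
examples/                 one narrative script per capability
tests/                    unit, property and end-to-end suites
scripts/acceptance.py     headline-quantity reproduction
docs/methods.md           models, assumptions, parameter choices, limitations
```
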