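# Methods

`ftirlcm` implements the computational chain behind infrared-guided tissue
microdissection: per-pixel spectral quality control, scattering correction,
hierarchical tissue classification, geometric transfer of classified regions
into a microdissection stage frame, absorbance-balanced sample pooling, and
the downstream differential-proteomics ranking statistics. This note
documents the models, the defaults and why they were chosen, what the
synthetic phantoms do and do not emulate, and the numerical choices made
where the design was open.

## Spectral model and quality control

A measurement is an absorbance cube A(r, c, ν) over a uniform wavenumber
grid; the acquisition grid is 2700 → 952 cm⁻¹ at 4 cm⁻¹ (438 bands, stored
descending). All operations index by wavenumber, never by raw band
position, so sub-ranges and re-gridded cubes behave identically.

Quality control rejects pixels whose spectra cannot support classification:

- **SNR** = (peak absorbance in the amide I window 1700–1600 cm⁻¹ above the
  endpoint baseline) / (SD of the linearly detrended absorbance in the
  spectroscopically quiet 2000–1800 cm⁻¹ window). Default threshold 10.
  A constant spectrum has zero noise and passes (SNR = ∞); an identically
  zero spectrum fails (SNR = 0).
- **Amide I integral** (trapezoid above the endpoint baseline) must lie in
  [0.5, 60] absorbance·cm⁻¹. The lower bound rejects blank substrate and
  cracks, the upper bound saturated folds. The endpoint baseline makes the
  criterion insensitive to the smooth Mie baselines that QC necessarily
  precedes correction of. These bounds are configuration, not science: they
  are chosen to bracket tissue at nominal section thickness.

`integrate_band` itself defaults to no baseline (it is then exactly linear
in the spectrum); by the Lambert–Beer law the amide I integral at fixed
path length is proportional to local protein concentration, which is what
makes it usable both for QC and for pooling (below).

## EMSC scattering correction

Cellular spheres imprint broad extinction baselines on transmission
spectra. The correction decomposes each spectrum z(ν) over the fit range
2300–950 cm⁻¹ as

    z(ν) = c·m(ν) + Σⱼ bⱼ νʲ + Σᵢ gᵢ pᵢ(ν) + e(ν)

with m a reference chemical spectrum, a quadratic baseline, and pᵢ the
top-7 principal components of van de Hulst extinction curves
Q(ρ) = 2 − (4/ρ)sin ρ + (4/ρ²)(1 − cos ρ), ρ = 4πrν(n−1), simulated on a
10×10 grid of sphere radius r ∈ [2, 8] μm and refractive index
n ∈ [1.1, 1.5]. The corrected spectrum is (z − baseline − Mie)/c. The fit
is one shared least-squares solve for all pixels (the design matrix is
pixel-independent), so a 64×64×438 cube corrects in well under a second.

Choices: the non-resonant van de Hulst basis (the complex-index resonant
refinement is out of scope; the basis argument is the hook for it);
baseline order 2; k = 7 components, which reconstruct the centred curve
family to < 1% RMS. Iterating replaces the reference with the mean
corrected spectrum; on undistorted input the iteration is stationary after
the first pass (< 1e-10 change at 20 iterations), so the default is a
single iteration. Pixels whose fitted scale c falls below 1e-3 are flagged
degenerate, returned uncorrected, and removed from the QC mask rather than
divided by a near-zero scale.

Savitzky–Golay smoothing/second derivatives (9-point, quartic, derivatives
scaled by the actual grid step) are provided for unsupervised exploration
only; the classifier consumes unsmoothed EMSC-corrected absorbance. The
quartic default and polynomial-interpolation edge handling keep the filter
exact for cubics over the whole support and track the analytic second
derivative of a Gaussian band with correlation > 0.999; a cubic with
reflection padding does neither.

## Classifier cascade

Tissue annotation is a cascade of random forests on the fingerprint region
1800–950 cm⁻¹ (213 bands of the acquisition grid): level 1 separates
pathologic from other tissue, level 2 resolves the tumour class, level 3
the subtype (for pleural mesothelioma: epithelioid vs sarcomatoid). The
hierarchy is configuration (`CascadeSpec`), not code, so other taxonomies
are expressible. A level only re-labels pixels whose previous-level label
is one of its declared parents, which makes the restriction invariant (no
leaf without its ancestor) structural rather than statistical.

Defaults: 200 trees, √B features per split, unlimited depth, out-of-bag
scoring, per-class balanced subsampling to the smallest class (tissue-class
prevalences cannot be equalized in practice), at least 100 training pixels
per class. Training and prediction are deterministic for a fixed seed.
QC-failed and EMSC-degenerate pixels carry label 0 and never enter
training. Prediction refuses a cube whose wavenumber grid differs from the
training grid — resampling is never implicit.

Sample-level diagnosis uses pixel majorities: a sample is called biphasic
when both subtype fractions reach 0.20 of the subtype pixels, otherwise
the majority subtype. Binary diagnostic performance is reported as
accuracy/sensitivity/specificity in percent, rounded only for display.

## ROI geometry and coordinate transfer

Regions of one class are 8-connected components; the cutting polygon
vertices are the centres of the *marginal* pixels (those with ≥1 4-neighbor
outside the region), ordered by Moore boundary tracing starting at the
top-most then left-most marginal pixel. The stage position of pixel (r, c)
is (origin_x + (c+0.5)·w, origin_y + (r+0.5)·h), y increasing downward.
Only the outer boundary is traced; ROIs with interior holes are a
documented limitation.

Oversized regions are split to respect the instrument's shape-size limit
(default 250,000 μm², configurable): the interior Euclidean distance map is
watershed-segmented from its regional maxima, any catchment still above the
limit is bisected along its longer axis, and adjacent pieces are re-merged
smallest-first while staying within the limit. The result is asserted to be
an exact partition on every call, so areas and amide integrals are additive
by construction.

Frame transfer is a strictly 4-parameter planar Helmert similarity
x' = t + s·R(θ)·x, estimated linearly in (tx, ty, a, b) from ≥3
non-collinear fiducial pairs; collinearity raises a conditioning error.
With isotropic noise σ on n pairs the RMS residual follows the
least-squares law σ·√(2(n−2)/n), which the tests verify over 200 seeds.
Optical aberration between the visible and infrared paths is calibrated
separately from a resolution-target grid as anisotropic scale + rotation
(+ offset), recovered by affine least squares and decomposition; applying
calibration before the Helmert keeps anisotropy out of the similarity map.

Pooling: instead of collecting equal areas, fragments are selected per
sample so the summed amide I integral — a relative protein amount by
Lambert–Beer — hits a common target within a tolerance (default 2% of
target). Exact subset-sum is NP-hard; the implementation is greedy
largest-first with best single add/remove/swap refinement, which meets a
±2.5% tolerance on 20-fragment pools in every tested seed. Infeasible
targets raise an error naming the sample and its maximum.

## Differential-abundance statistics

The pipeline order is fixed: arcsinh-transform the normalized abundances
(ln(x + √(x²+1)), variance-stabilizing and defined at zero), average the
three technical replicates of each biological sample on the transformed
scale, pooled-variance two-sided t-test (df = n₁+n₂−2) on the transformed
sample means, fold changes as group-mean ratios on the *untransformed*
normalized scale (a back-transformed alternative sits behind
`fold_change_scale`), the significance filter (≥2 unique peptides,
unsigned FC ≥ 2, p ≤ 0.05, all inclusive), and ranking by the Euclidean
distance from the volcano-plane origin

    d_eucl = √((log₁₀ p)² + (log₁₀ FC)²),

with FC the unsigned ratio ≥ 1. d_eucl is monotone in both coordinates and
dominates each of them. Volcano tiers use the contour radii 1, 1.5, 2 with
closed boundaries. Zero pooled variance yields p = 1 when the means agree
and a flagged degenerate p → 0 when they differ; zero group means flag the
record out of ranking. No multiple-testing correction enters the filter; a
Benjamini–Hochberg column is emitted for information only. Ties in the
ranking break by smaller p, then accession.

## Synthetic phantoms: what they emulate, what they do not

Phantoms stamp random disks of tissue classes over an optional stroma
background. Each class is a sum of Gaussian bands; all classes share an
identical amide I band (amplitude 0.60, σ 25 cm⁻¹ at 1654 cm⁻¹) so the band
integral is a class-independent concentration proxy, and differ in amide
II, lipid-ester (1740), amide III/collagen (1236) and carbohydrate
(1030–1080) bands. Per-pixel spectra are concentration × signature
(concentration ~ U(0.8, 1.2)) + 0.1 × a per-pixel Mie curve drawn from the
same (r, n) ranges as the correction basis + white noise (σ = 0.005
absorbance, i.e. amide SNR ≈ 120). Ten blank and five saturated defect
pixels are planted by default. Protein tables are log-normal (ln-σ 1.0
around 10⁴) for 6 vs 4 biological samples with 3 technical replicates,
replicate noise at a stated CV and biological spread at half that,
planted multiplicative effects on chosen proteins, and unique-peptide
counts ≥ 1 with a configurable fraction ≥ 2 (default 0.8).

The phantoms emulate the *structure* of tissue imaging data — band shapes,
Beer–Lambert scaling, scattering baselines, defects — not tissue biology.
Classes are far better separated than real histology, so a passing
classifier suite demonstrates the correctness of the pipeline (feature
extraction, cascade restriction, determinism, graceful degradation with
noise), not clinical accuracy. The published tissue-level accuracies are
not reproducible here because no spectra are deposited; the printed
worked examples (marker-panel distances, the 17-sample confusion matrix)
are reproduced exactly from their printed inputs instead.

The Beer–Lambert contract (amide integral vs planted concentration,
R² > 0.999) is evaluated on a scatter-free phantom: Mie scattering breaks
absorbance–concentration proportionality by construction — that is the
motivation for EMSC — and scattering removal is validated separately
(≥10× RMSE reduction on distorted spectra).

## Problem sizes and runtime

Test and acceptance suites run at desk scale: 32–64 px square phantoms with
the full 438-band axis, 10-seed classifier repetitions, 200-seed residual
law and 500-seed fold-change simulations, 2000-replicate null calibration.
The full suite completes in well under a minute per heavy suite; full
preprocessing of a 64×64×438 phantom takes ~1 s.

## Known limitations

- Non-resonant Mie basis only; no Kramers–Kronig complex-index refinement,
  no atmospheric-vapour correction.
- Outer-boundary polygons only (no holes in dissection shapes).
- Axis-bisection fallback in the watershed can, for pathological shapes,
  produce thin fragments; partition invariants still hold.
- Neutral XML/CSV shape dialects, not vendor-exact instrument formats.
- The protein-table reader consumes a generic delimited export; vendor
  column layouts must be mapped to (accession, gene, unique_peptides,
  runs) + a design file first.
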