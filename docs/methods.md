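# Methods

This note documents the models, estimators and design choices behind
`qusrad`: what each stage computes, which parameters matter, what the
synthetic data do and do not emulate, and where the design was genuinely
open.

## RF phantom model

A frame is a 2-D array of RF echo samples (axial sample × scan line).
Scatterer positions are drawn from a homogeneous spatial Poisson process
per region — an elliptical tumour "core" inside background tissue, or a
uniform reference medium.  Each scatterer is a spherical Gaussian
reflector of effective radius a = d/2: its echo amplitude spectrum carries
a Rayleigh k² factor and the square root of the Gaussian form factor
exp(−0.827 k²a²).  With n scatterers per unit area and per-scatterer
amplitude γ = sqrt(10^(AAC/10)/n), the ensemble backscatter power of a
region follows

    BSC(f) = 10^(AAC/10) · k⁴ · exp(−0.827 k² a²),   k = 2πf/c,

which makes the downstream ASD/AAC estimator's forward model exact on
synthetic data.  AAC is therefore a power-like decibel quantity:
AAC = 10·log10(nγ²), so a +20 dB core/background AAC difference produces a
+20 dB mean-squared RF amplitude contrast (verified in the tests to within
Monte-Carlo error).

The transmit/receive pulse is a Gaussian-enveloped sinusoid whose −6 dB
one-way amplitude points fall on the configured band edges (default
3.0–8.5 MHz around 6.5 MHz).  Frequency-linear attenuation (dB/cm/MHz) is
applied per scatterer as a round-trip amplitude filter; scatterers are
binned into 64 depth strata and share a precomputed time-domain kernel per
stratum.  A Gaussian lateral point-spread (σ = 0.35 mm default) blurs
across lines, and white Gaussian noise is added at a configurable SNR
(default 30 dB, relative to the frame RMS, so an empty phantom stays
silent).

Defaults the acquisition hardware does not pin down were fixed once:
40 MHz sampling and 1540 m/s (typical for clinical linear-array research
systems), 80 lines over 20 mm.  The simulation is strictly 2-D; a
volumetric scan is represented as independent frames.  There is no wave
propagation (no diffraction, multiple scattering, elevational beam or
speckle correlation with depth), so tests passing on phantoms demonstrate
estimator correctness under the stated scattering model, not robustness to
everything real tissue does.

## Spectral estimation

Per-window power spectra are Hann-tapered periodograms averaged across the
window's scan lines in linear power, then converted to dB.  Windows must
span at least 8 wavelengths axially at the centre frequency (≈1.9 mm at
6.5 MHz); this floor is configurable and was chosen so the default 2 mm
analysis window is admissible.  Normalization is a pointwise dB
subtraction of a reference-phantom spectrum measured with the same system
model, which cancels the pulse spectrum, the k² scattering prefactor's
system-independent part, lateral-blur gain and taper effects.

MBF/SS/SI come from ordinary least squares on the normalized spectrum
restricted to the analysis band (≥ 8 in-band points required): SI is the
fitted value at 0 MHz, SS the slope, and MBF the fitted value at the band
midpoint (5.75 MHz for 3.0–8.5 MHz) — MBF ≡ SI + SS·f_mid is asserted on
every fit.  The "0 MHz intercept" and "spectral intercept" are treated as
the same quantity.

The backscatter coefficient uses the reference-phantom method: measured
linear power ratio times the reference's analytic BSC (computed from its
known ASD/AAC).  Optional point attenuation compensation
(2·Δα·f·z dB) is off by default because phantom sample/reference pairs are
generated with matched attenuation.  ASD/AAC inversion fits log10-BSC to
the Gaussian-form-factor model: for each candidate diameter on a
20–400 µm grid (2 µm steps) the amplitude term is a closed-form mean
offset, so the residual is evaluated vectorially; the best grid point is
refined by bounded golden-section search, and AAC follows from the offset.
A fit at the grid boundary is flagged in the estimate's metadata.

Attenuation is estimated by the spectral-difference method: normalized dB
spectra of windows at ≥ 2 depths, a per-frequency linear fit of dB versus
depth, and a through-origin fit of the resulting one-way dB/cm rate
against frequency.

## Parametric maps

Maps tile the frame with square windows (default 2 mm; 80% overlap for
detail maps, 50% in the batch pipelines for speed) and keep a window iff
at least 70% of its RF pixels fall inside the region mask — the inclusion
rule stabilizes estimates on thin margin rings.  Map pixels live on the
window-centre lattice with coordinates in mm.  The margin mask is the band
within 5 mm outside the core boundary (Euclidean distance transform with
anisotropic pixel spacing), clipped at image edges and disjoint from the
core by construction.

## Texture and texture derivatives

GLCMs use the Haralick-standard configuration by default: 16 grey levels,
distance 1, angles {0°, 45°, 90°, 135°} averaged, symmetric counting.
Quantization is linear over a per-parameter range (data-driven min/max for
synthetic maps); the top bin is right-closed; a degenerate range maps all
pixels to bin 0.  Invalid pixels are recoded to a sentinel level whose
GLCM row/column is struck before normalization, so they never contribute
pairs.  Feature dialects are pinned because libraries disagree:
homogeneity is the inverse difference moment with |i−j|,
Σ P/(1+|i−j|); energy is the angular second moment Σ P² (not its square
root); correlation is defined as 0 for zero-variance matrices.

First-pass texture features are whole-region GLCM features of each
quantized parametric map.  Texture *maps* are sliding-window evaluations
(5×5 map pixels, step 1, ≥ 70% valid pixels per window) of the same four
features; the texture derivative is a second GLCM pass over each texture
map, quantized data-driven (first-pass ranges do not apply), giving 16
derivative features per parametric map named
`<region>-<param>-<first>-<second>`.

## Feature registry

The default registry totals exactly 201 features: attenuation (1), mean
QUS (5 parameters × core/margin = 10), core-to-margin (ratio +
contrast ratio per parameter = 10), first-pass texture from the core only
(20), and texture derivatives from core and margin (160).  The family
decomposition that reaches this total is not uniquely determined by the
headline count alone; this registry is the documented-group decomposition
that reproduces it and is explicitly an assumption — a both-region
registry (221 features) is provided as the natural alternative.  The
core-to-margin contrast ratio is Michelson-style, |c−m|/(|c|+|m|).
Attenuation is a single whole-tumour value.  Molecular subtype (ERBB2+ =
ER−/PR−/HER2+; triple negative = ER−/PR−/HER2−; Luminal-A = ER+ and/or
PR+, HER2−; Luminal-B = ER+ and/or PR+, HER2+) rides alongside the
registry and is one-hot encoded by the classifier.  Features that cannot
be computed are flagged missing (NaN) and mean-imputed at training time,
keeping small cohorts usable without changing vector length.

## Response model

Feature selection is greedy sequential forward selection maximizing 5-fold
stratified cross-validated balanced accuracy of an RBF SVM, stopping at 10
features; ties break to the earlier column, and fold assignment is fixed
by the config seed, so selection is deterministic.  The final model
z-scores the selected features (training statistics stored in the
pipeline) and grid-searches C ∈ {0.1, 1, 10, 100} and
γ ∈ 10^{−3…1} (9 log-spaced values) with balanced class weights.  A
cross-validated sigmoid (Platt) calibration of the winning pipeline
supplies probabilities.  Predictions report the label from the decision
function's sign (an exact 0 ties conservatively to NR, flagging the case
for review), the signed decision value as hyperplane distance, and a class
score 2·P(R)−1 whose sign is forced to agree with the label (calibration
can disagree with the margin in a thin boundary band) and whose magnitude
is the calibrated confidence.

## Synthetic cohorts

A synthetic patient is one phantom frame plus a matched reference put
through the entire feature pipeline.  Responders and non-responders differ
only in core-versus-background AAC contrast (+15 dB vs +2 dB, SD 2 dB);
background AAC (55 ± 3 dB) and both regions' scatterer diameters
(140 ± 12 µm) vary per patient; classes are balanced.  Frames are
20 × 20 mm with a 3.5 mm-radius core and 5 mm margin; cohort pipelines use
50% window overlap.  These choices keep one 100-patient cohort near half a
minute of compute while leaving the injected effect realistically noisy.
Because the only class difference is the injected contrast, the
permutation null (labels shuffled, feature list held fixed) sits at 0.5 by
construction; the non-null cross-validated estimate selects features on
the full cohort first and is therefore mildly optimistic — acceptable
here, where the claim under test is effect recoverability, not an unbiased
effect size.

## Clinical validation arithmetic

The packaged 56-patient table transcribes the validation cohort's
covariates, pre/post-NAC sizes, receptor status, treatment, actual and
predicted response, and the three patients whose chemotherapy was changed
after the prediction was disclosed.  Metrics treat the responder as the
positive class and are reported as integer percentages rounded half away
from zero — the rule that reproduces every printed value (e.g.
95.9 → 96, 94.9 → 95, 57.1 → 57, 96.9 → 97).  Actual-response labels are
taken from the table as ground truth; the RECIST size-change classifier
(≥ 30% diameter decrease) is advisory only, since the recorded labels
combine clinical and pathological assessment and cannot be derived from
sizes alone (one patient's tumour grew from 2.4 to 7.2 cm yet was an
actual responder by pathology).  Two documented discrepancies are reported
but not asserted: the direct even-n median of the pre-treatment sizes is
3.65 cm (3.7 printed), and subtype percentages computed from the receptor
columns do not match the printed ones under the stated definitions.

## Numerical and testing notes

- Determinism: every stochastic routine takes an explicit seed;
  (config, truth, seed) reproduce frames bit-for-bit.
- GLCM correctness is established against an independent brute-force
  pair-enumeration oracle on random small images (property-based tests).
- Problem sizes in the suite — 14 mm test frames, 20-seed recovery
  averages, two 100-patient cohorts, a 10-permutation null — are the
  package's own balance of statistical resolution against run time.
- Known limitations: no diffraction or depth-dependent beam effects; no
  elevational dimension; sparse-scatterer speckle is not fully developed
  at the default density; the clinical model's original training weights
  are not public, so the classifier here is always trained on synthetic
  cohorts and the clinical table is used only for validation arithmetic.
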