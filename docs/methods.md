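# Methods

## Impactor reduction

The reduction is nonparametric: no log-normal is fitted. Stage
activities a_k on cut diameters d_0 < … < d_n give the empirical
cumulative activity distribution F(d_k) = Σ_{j≤k} a_j / Σ a_j, and all
metrics are read off this curve. Quantiles interpolate linearly in
(ln d, Φ⁻¹F), i.e. on the log-probability plot, where any log-normal is
a straight line — so for log-normally generated stages the interpolation
is exact regardless of grid resolution (the AMAD of a noiseless
log-normal run is recovered exactly even on the default 12-stage grid).
Segments whose endpoint fraction is 0 or 1, where the probit is
undefined, fall back to linear interpolation in the fraction itself;
`fraction_below` uses the same per-segment rule, making the two
directions exact inverses of each other.

Two definitional points:

* d16/d84 are the literal 16 % and 84 % quantiles. For a log-normal
  these sit at z = ∓0.9945, not ∓1, so √(d84/d16) equals GSD^0.9945 —
  a 0.2–0.7 % downward offset for GSD 1.6–3.2 that is inherent to the
  16/84 convention, not an interpolation error.
* `hatch_choate_range` (AMAD/GSD, AMAD·GSD) is a diagnostic
  cross-check; empirical distributions need not obey it, and reported
  ranges are always the empirical quantiles.

Activity outside the instrument range (30 nm – 10 μm by default) is
carried in explicit catch bins: it enters the normalization, so the
cumulative curve tops out below 1 when mass sits above the last
boundary, and a quantile falling in a catch bin raises an extrapolation
error naming the nearest attainable quantile rather than inventing a
diameter. A broad micron aerosol (GSD 3.2) leaves ≈1.7 % above 10 μm;
its d84 remains attainable. Stage cut-offs are calibration data, so the
stage table is fully overridable from CSV. A run with exactly one loaded
stage is treated as monodisperse: AMAD = geometric mean of the stage
edges, GSD = 1. Metrics are never rounded in computation, only at
presentation.

## Planar quantification

The correction chain per region and view is: gross ROI counts → net
counts = gross − b̄·n, with b̄ the mean per-pixel rate of the three
external background ROIs and n the target ROI pixel count (the
per-pixel convention makes unequal ROI areas valid) → count rate →
conjugate-view combination → decay correction.

The anterior/posterior combination is the geometric mean
√(R_A·R_P)/√f. With the source plane between the detectors and total
transmission f along the combined path, the geometric mean cancels the
source-depth dependence; with equal views and f = 1 it degrades to the
single-view estimate. Transmission factors are per-region configuration
(default 1.0): factors for a plastinated head or ex vivo lung are not
tabulated anywhere, so they must come from the experiment (e.g. a
transmission scan); the synthetic generator writes the factors it used
into the scene's correction config so analysis is self-consistent.

Decay correction multiplies by 2^(Δt/T½), Δt the acquisition start
minus the reference time (the start of the pre-inhalation full-nebulizer
acquisition); T½ = 6.0113 h for ⁹⁹ᵐTc is an implementation constant.
Negative net counts clamp to zero with a warning — expected behaviour
for low-count ROIs such as the expiratory filter in large-particle
runs — rather than erroring. The posterior raster is assumed mirrored
left-right by the camera and is flipped before masks (defined on the
anterior grid) are applied; the convention is configurable. Masks are
co-registered rasters; no registration step is provided or needed for
single-camera acquisitions of a fixed setup.

Corrected "activities" are in count-rate units; all reported quantities
are ratios, so the scalar camera sensitivity cancels everywhere except
in absolute-activity displays, where dividing by it restores MBq.

## Deposition reporting

ET and TH are percentages of the *deposited* total and sum to 100
exactly; the exhaled fraction is a percentage of the *emitted* activity
(emitted = full − empty nebulizer, decay-corrected). Reports carry both
denominators explicitly because the two conventions are easy to
conflate. The mass balance 100·(emitted − ET − TH − filter)/emitted is a
QC quantity; |value| > 5 % (configurable) is flagged, motivated by the
filter being only an approximation of the exhaled route. Group
comparison is Welch's unequal-variance t from summary statistics (mean,
SD, n) with Welch–Satterthwaite degrees of freedom — the standard choice
when only summaries are available; the test identity is recorded in
output metadata.

## SPECT partition

Central (trachea + principal bronchi) and peripheral percentages are
normalized to the in-lung total, so they sum to exactly 100; activity
outside both labels is excluded and its share reported. Labels are
trusted as given — no partial-volume or spill-over correction. The <5 %
criterion on the central share uses a strict inequality.

## Synthetic generators

The generators emulate the statistical structure the analysis assumes,
with defaults set to the study conditions: 740 MBq loaded, 10-min
nebulization, acquisition schedule 60 s (full nebulizer) / 180 s (other
elements), 256×256 matrix, 2.4 mm pixels, 8.3 mm FWHM Gaussian PSF,
emitted fractions 44.5/9.3/4.2 %, TH/ET splits 89–11/78–22/35–65,
exhaled 68/34/27 % of emitted, 4 % central lung share. Expected pixel
counts are activity × sensitivity × duration painted uniformly into
elliptical footprints, blurred, attenuated, plus uniform background
(0.05 counts/px/s default); Poisson noise is applied after blurring
(counting noise arises at detection). Attenuation is applied as √f per
view by default, making the conjugate-view estimator exactly unbiased;
an asymmetric mode (f^0.75/f^0.25) probes estimator behaviour when the
source is off-center. Decay is evaluated at each acquisition's start
time, which the analysis inverts exactly; within-acquisition decay
(≈0.4 % over 180 s of ⁹⁹ᵐTc) is not integrated and cancels in the
ratios between equal-duration acquisitions. The default camera
sensitivity is 1 count/(MBq·s); recovery experiments use 10 so that a
full scene carries ≥5×10⁵ counts.

What the generators do **not** emulate: scatter, dead time, septal
penetration, camera non-uniformity, source self-attenuation gradients,
anatomical shapes beyond ellipses/ellipsoids, impactor wall losses or
charger effects, and any deposition physics (the configured partition
*is* the truth). Passing recovery tests therefore demonstrate that the
correction chain is unbiased under counting statistics, blur, uniform
background and known attenuation — not that it would remove biases the
generator never injects (unknown attenuation factors, scatter,
mis-registered ROIs).

## Problem sizes and numerical choices

Recovery experiments use 50 seeded replicates per condition, 10⁵ counts
per impactor run on a 50-stage grid, and full five-element scenes per
planar replicate; medians are reported, being robust to the occasional
low-count outlier. Random number streams are `numpy` PCG64 generators
passed explicitly; identical spec + seed gives bit-identical outputs.
Probit interpolation uses `scipy.stats.norm`; exact quantile hits
(|F − q| ≤ 1e-15) return the boundary diameter directly, and plateaus
from empty stages are skipped so quantiles stay well-defined.

## Known limitations

* Attenuation factors and the anterior/posterior combination used in any
  specific historical experiment are not recoverable from published
  summaries; both are configuration, and the defaults (geometric mean,
  f = 1) are the field's standard.
* Printed d84 values or sub-micron fractions from empirical, not-quite
  log-normal distributions cannot be reproduced from (AMAD, GSD) alone;
  the package computes empirical quantiles and offers Hatch–Choate only
  as a diagnostic.
* p-values from historical in vivo comparisons depend on unpublished
  replicate data; `compare_groups` reproduces the method (Welch), not
  those numbers.
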