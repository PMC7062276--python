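# Methods

## Sectioning stereology

The core geometric model treats a microcompartment as a sphere of true
diameter *D*. An ultra-thin section at distance *r* from the centre shows a
circle of diameter *d(r) = 2·√((D/2)² − r²)*. Two averaging schemes are
implemented:

- **`volume_weighted`** — section positions weighted by the spherical volume
  element, density ∝ *r²* on [0, D/2]. This gives E[d] = (3π/16)·D, i.e. a
  41.1 % mean underestimation, and is the package default.
- **`uniform_plane`** — offsets uniform on [0, D/2], the classical
  uniform-random-plane stereology, giving E[d] = (π/4)·D (21.5 %
  underestimation).

The two weightings answer subtly different sampling questions (volume
element vs plane position); both are exposed so the consequences of the
choice are visible, and no intent is guessed where the distinction is not
stated. All expectations are linear in *D*, so the percent shortfall is
scale-invariant; the Monte-Carlo simulators are validated against the
closed forms to within 3 standard errors at 10⁶ draws.

Zero slice thickness is assumed throughout (sections are planes). A finite
`slice_thickness` field exists on `SectioningModel` as an extension point
but the analytic results and all shipped analyses use 0; real ultramicrotome
sections (~50–70 nm) are not negligible against a 140 nm particle, which is
a recognised limitation of the plane model.

### Irregular particles

Microcompartments are angular, roughly icosahedral shells, not spheres.
`make_irregular_particle` perturbs a regular icosahedron's vertices radially
by a uniform factor in [1 − a, 1 + a] (a ≤ 0.3), re-hulls to restore
convexity, re-centres at the hull's volume centroid, and rescales so the
maximum Feret diameter is exact. Sections are convex polygons computed from
hull-edge/plane intersections, and their "diameter" is the maximum pairwise
vertex distance of the cut polygon — the same longest-diameter convention a
manual tracer applies to an ellipse fit.

A caution on normalisation: for a polyhedron the max Feret diameter is a
vertex-to-vertex distance, which exceeds the mean caliper width, so the
mean-section-to-max-Feret ratio of even an unperturbed icosahedron
(≈ 0.507 under volume weighting) sits *below* the spherical 3π/16 ≈ 0.589.
The simulator itself reproduces 0.589 on a fine (1000-vertex) sphere
tessellation, which is how its correctness is tested; the icosahedron gap is
a real shape effect, not discretisation error.

### Detection limit

Observed UTS means undershoot the true size by less than the model predicts
(≈ 28 % observed vs 41 % predicted). The package models this as left
truncation: sections smaller than a threshold *L* are never recorded,
because small faint cross-sections are hard to recognise during image
analysis. The truncated expectation is computed by numerical integration
(sections with d(r) ≥ L correspond to r ≤ √((D/2)² − (L/2)²)); it increases
monotonically from (3π/16)·D at L = 0 towards D as L → D, so
`fit_detection_limit` can invert it by Brent root bracketing (absolute
tolerance 10⁻⁶·D).

Two variants are provided. The single-sphere fit (`size_sd = 0`) inverts the
truncated mean of one diameter. The population fit (`size_sd > 0`) averages
the truncated moments over a Gaussian true-size distribution using 41-node
Gauss–Hermite quadrature. The distinction matters: detection removes a
larger fraction of sections from small particles, so a threshold fitted on
the mean sphere alone (65.3 nm for 99/138 at D = 138) over-predicts the
population mean by ~1.7 nm, while the population fit (61.7 nm at
SD = 21 nm) is self-consistent — re-simulating 10⁴ sectioned particles
reproduces the 99 nm target within Monte-Carlo error. The pipeline uses the
population fit wherever a size spread is specified.

## Synthetic data calibration

The generator's defaults *are* the study conditions:

| technique | mean ± SD (nm) | N |
|---|---|---|
| TEM (negative stain) | 102 ± 17 | 3 × 100 |
| TEM + HMDS | 124 ± 17 | 3 × 100 |
| SEM | 126 ± 17 | 3 × 100 |
| cryo-TEM | 138 ± 21 | 3 × 100 |
| UTS TEM | 99 ± 32 | 3 × 100 |

Within-replicate noise is Gaussian (box-whisker plots of such data are
roughly symmetric and no distributional form is otherwise constrained);
between-replicate mean offsets are Gaussian with SD 5 nm, a free knob since
pooled group statistics say nothing about replicate-level spread. Negative
draws are redrawn rather than truncated so moments stay interpretable; at
these calibrations redraws are vanishingly rare. With `exact_moments` (the
default) the pooled sample is affinely standardised so mean and n−1 SD hit
the calibration to machine precision — group-level statistics computed
downstream are then exactly reproducible, while rank-based quantities remain
stochastic.

The sectioned-UTS generator draws true diameters from the cryo-TEM
calibration (the least-perturbed modality), applies one random section per
particle and the detection-limit filter, and keeps sectioning until the
requested number of recorded measurements accumulates.

DLS correlograms use β = 0.8 (coherence intercept), 173° backscatter
detection, 633 nm He-Ne illumination, water at 4 °C (viscosity 1.567 mPa·s,
refractive index 1.333) — all configurable via `InstrumentParams`. The
default lag grid is 400 linear points spanning eight mean decay times.
Noise, when requested, is i.i.d. Gaussian on g₂; tests and acceptance runs
use noiseless curves.

The NTA sample is a lognormal mixture: a main population with mode
130.7 nm and log-sigma 0.13 plus a 3 % aggregate component calibrated to an
arithmetic mean of 650 nm (SD 160 nm), chosen so the mixture's sample mean
(~149.5 nm) sits well above its mode (~131 nm) the way particle-by-particle
tracking of an aggregate-contaminated sample does, while the mode barely
moves. Ensemble DLS of the same material centrifuges aggregates out and
does not see this shift.

What the generator does *not* emulate: micrograph pixel data and tracing
error, stain-dependent contrast, finite NTA track lengths, Mie scattering
(see below), or replicate-level structure beyond a shared mean offset.
Passing tests therefore demonstrate the internal consistency of the models
and statistics, not the behaviour of any real instrument.

## Cumulant analysis

`CumulantModel` fits ½·ln[(g₂ − 1)/β] with a quadratic in τ (intercept,
−Γ̄τ, μ₂τ²/2) by least squares weighted by the squared normalised amplitude,
over the window where (g₂ − 1)/β ≥ 0.1 (both the weighting and the window
are standard guards against log-amplified tail noise; the window threshold
is a parameter). The intercept absorbs any miscalibration of β, making the
results invariant to its rescaling. Z-average = kT/(3πη·(Γ̄/q²));
PDI = μ₂/Γ̄², clamped at zero with a diagnostic flag when the quadratic
coefficient fits slightly negative (which noiseless monodisperse inputs can
produce).

For lognormal intensity weights with log-variance σ², the Z-average equals
exp(μ − σ²/2) and the PDI equals exp(σ²) − 1; `lognormal_psd` inverts these
to build calibrated inputs. Masses are assigned on a log-uniform grid
(where the lognormal is a plain Gaussian in log-diameter — assigning
density values on such a grid without the Jacobian would silently shift the
distribution by a factor of exp(σ²)). Recovery on noiseless inputs is ~0.05 %
in Z-average and −0.003 in PDI at PDI 0.045; the residual PDI bias is the
truncation error of the second-order expansion against a lognormal's higher
cumulants.

PSD reweighting uses Rayleigh-regime algebra (I ∝ N·d⁶). At 122 nm
particles under 633 nm light this is an approximation — full Mie theory
would damp the d⁶ growth — and is recorded as a known bias. Only the
qualitative ordering (number mode < volume mode < intensity mode, the
left shift) is asserted, not absolute number/volume peak positions, which
are distribution-dependent.

## Statistics

Sample SDs use the n−1 denominator. Quartiles are medians of the
median-exclusive halves (the convention matters: it shifts outlier counts
at small n, so it is fixed and documented). Outliers follow the Tukey
1.5·IQR rule; whiskers reach the most extreme observations inside the
fences. The t-test defaults to Welch, since the group SDs (17–32 nm) are
plainly unequal; the pooled variant is available for parity with
spreadsheet defaults, and the two agree exactly for balanced equal-variance
groups (tested). `ttest_from_summary` reproduces the raw-data test from
(n, mean, SD) alone under normality — useful when only published moments
exist, though it cannot reproduce p-values computed from unpublished raw
data whose shape deviates from normal. No multiple-testing correction is
applied by default, mirroring the raw-p reporting convention the comparison
emulates; percent changes round to integers only in the report layer.

## Determinism

Every stochastic routine takes an explicit seed. The pipeline expands one
global seed into per-stage child seeds via `SeedSequence` keyed by CRC-32
of a stage tag (Python's salted `hash` would not survive process
boundaries), so each stage is independently reproducible and all CSV
outputs are byte-identical across same-seed reruns. Problem sizes in the
shipped analyses — 10⁶ sphere sections for the closed-form cross-check,
10⁴ sectioned particles, 2×10⁴ NTA particles, 400 correlogram lags — keep
Monte-Carlo error well inside the tolerances they are compared at while
running in seconds.

## Known limitations

- Plane sections (zero thickness); real ~50–70 nm sections bias apparent
  diameters upward relative to the model.
- Rayleigh rather than Mie weighting for intensity PSDs.
- Gaussian technique populations by assumption, not inference; published
  raw-data p-values that depend on higher moments are out of reach.
- The detection-limit model is a sharp threshold; real recognisability
  presumably degrades smoothly.
- The icosahedral particle model captures angularity, not the collapse or
  deflation mechanics of dehydrated particles.
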