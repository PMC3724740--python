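# Methods

## Whisker phantoms

A phantom is a generalized elliptical cylinder voxelized slice by slice
along the volume's z axis, emulating a whisker taped flat onto a slide and
scanned at 30 µm isotropic resolution.

**Taper.** Cross-sectional area follows
A(u) = A₀ · (1 − (1 − r_tip)·u)^p with u = s/L, base area A₀ (default
0.6 mm²), tip area ratio r_tip (default 0.15) and taper exponent p (default
1.5). Eccentricity ramps linearly from base (default 0.72 undulated / 0.70
smooth) to tip (default 0.85), reproducing the observed flattening toward
the tip.

**Undulation.** For the undulated (true-seal) archetype the maximum
semi-axis is modulated as a(s) = a₀(s)·(1 + α·sin(2πs/λ)) and the minimum
semi-axis is b(s) = A(s)/(π·a(s)), so the caliper width swings crest to
trough while the area follows only the taper — the structural signature of
undulated vibrissae. The undulation wavelength and amplitude are not
reported quantities; the defaults λ = 2.0 mm, α = 0.15 were chosen once as
visually consistent with published shaft profiles and are plain parameters.
Specs whose trough sections would invert the major/minor axes
((1 − α)² < √(1 − e²)) are rejected, as are specs thinner than 3 voxels
anywhere.

**Slide convention and θ.** The shaft's major curvature lies in the x–z
("slide") plane as a gentle circular bow (default radius 400 mm), and θ is
measured from the in-slice x direction. Undulated archetypes keep θ ≡ 0
(flattening in the curvature plane); the smooth archetype offsets θ by
~15° with a slow ±12° variation, reflecting the off-axis rotation reported
for sea-lion whiskers. Because the bow's slopes are shallow (≤ L/2R ≈ 0.03
at the defaults), axial slices and centerline-perpendicular sections
coincide to well under a voxel; the designed cross-section is drawn
directly in each axial slice and the returned ground truth is therefore
exact on that grid. Strongly curved shafts, oblique re-slicing of real
scans, greyscale calibration, and follicle anatomy are out of scope.

## Morphometry

Segmentation thresholds each slice (Otsu by default, fixed value
optionally), keeps the largest connected component, and fills holes; a
second component ≥ 50% of the largest raises an ambiguity error rather than
guessing.

Caliper (Feret) widths sweep projection directions in 0.5° steps over
[0°, 180°); the extent is computed on the convex hull of foreground *pixel
centers* plus one pixel spacing, which is unbiased for digitized discs. The
0.5° step bounds the sweep error at ~4·10⁻⁵ of the width, far below the
voxel quantization of sections under ~100 px across. Minimum caliper is the
minimum projection extent (minimum Feret), the common morphometric
definition.

θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂) from second central moments, mapped to
(−90°, 90°]. When the moment anisotropy falls below 1% of μ₂₀ + μ₀₂ the
orientation is undefined (circular section) and θ is reported as 0 with a
flag. Eccentricity is computed from the caliper widths,
e = √(1 − (min/max)²).

Shaft profiles order slices base→tip with the base defined as the
largest-area end. Crests and troughs are local extrema of the max-caliper
series with prominence ≥ 5% of the series median, forced to alternate by
keeping the more extreme of any same-kind run. The area-consistency
statistic evaluates detrended coefficients of variation of area and max
caliper at the crest∪trough slices; the detrend is a *local* linear fit
(±2 neighboring extrema) so the taper — including its curvature — is
removed but the undulation is not.

Accuracy at the 30 µm default (checked against phantom ground truth):
caliper widths within 2 voxels everywhere, θ within ~2° on whisker-like
sections (eccentricity ≥ ~0.5; the orientation of near-circular sections is
intrinsically ill-conditioned), area within ~3% except at few-voxel-wide
tip sections where edge quantization dominates (worst ~10–15%). The worst
caliper error shrinks roughly linearly with voxel size.

## Spectral analysis

Recordings are split into consecutive non-overlapping nfft-sample segments
(default 240 at 1200 Hz → 5 Hz bins, 30 segments for a 6 s record; the
trailing remainder is discarded). Each segment gets a rectangular-window
single-sided amplitude spectrum scaled so an on-bin sinusoid of amplitude A
reads A; amplitudes (not powers) are averaged across segments, since the
study's spectra are in velocity units. A Hann window is available as an
option but is not the default: the minimal reading of "FFT averaging with a
240 point FFT" is unwindowed, non-overlapping segments. Off-bin tones lose
up to the rectangular scalloping factor (≈ 0.64 at half a bin).

Peak picking takes the arg-max over bins, always excluding DC, optionally
excluding a configurable band (ties break toward lower frequency). The
0–50 Hz exclusion used by the pipeline mirrors the empirical separation
between the sting-mount artifact (everything below 50 Hz) and whisker tones
(55 Hz and above at the study's flow speed).

Segment quality: segments whose RMS falls below a threshold fraction
(default 0.2) of the median segment RMS are flagged as dropouts and
excluded from the average; a recording with no usable segments raises an
"unusable recording" error. The RMS rule is this package's own — the
original dropout criterion is not documented anywhere.

## Sting-mount artifact model

The rig artifact is modeled as Gaussian noise shaped in the frequency
domain by a Gaussian envelope centered at 15 Hz (σ = 6 Hz), zeroed at DC
and hard-zeroed above the 50 Hz band limit, then rescaled so the realized
240-point averaged-spectrum peak equals the configured amplitude (default
0.005 m/s). Only the artifact's spectral mode (15 Hz), band limit (50 Hz)
and amplitude bound are reported facts; the envelope shape is a modeling
choice, made narrow enough that the 15 Hz bin is robustly the modal peak
across seeds.

## Vortex-shedding model

Re = U·d/ν and f = St·U/d with the classical circular-cylinder empirical
fits St = 0.212 − 4.5/Re on [50, 150] and St = 0.212 − 2.7/Re on
[300, 2000]. The transition range (150, 300) is irregular in the cited
wake literature; the two fits are blended linearly in Re, keeping the map
total and continuous (to < 1e-12 at both edges) and labeled
`transition_blend`. Outside [50, 2000] the model refuses rather than
extrapolates. Fit constants are configurable (`StrouhalFit`).

Defaults are the study conditions: U = 0.5 m/s, ν = 1.0e-6 m²/s (fresh
water ≈ 20 °C; the water temperature is otherwise unstated). The
stream-wise diameter at 0° is the centroid-slice minimum caliper, at 90°
the maximum; "centroid" defaults to half arc length, with a
volumetric-centroid option. For undulated whiskers the max/min local widths
within half a wavelength of the centroid give a (f_low, f_high) interval;
the group-comparable scalar is their midpoint, a choice made because no
combination rule is documented. The 45° orientation gets no prediction (an
angled plane makes the stream-wise width ill-defined), and the model
predicts frequency only, never velocity. Percent difference is
100·|measured − theoretical|/measured — asymmetric by convention, with the
measured value in the denominator.

## Group statistics

The mixed-design (split-plot) ANOVA decomposes: between-subject SS into
species (group-size-weighted subject means) and subjects-within-species;
within-subject SS into angle, species×angle, and the angle×subject residual.
Species is tested against subjects-within-species; angle and interaction
against the residual; the subjects term is also reported against the
residual. The decomposition is exactly additive, reproduces the
(2, 2, 4, N−g, (N−g)(k−1)) DF layout for unequal group sizes, and with a
single species reduces to the one-way repeated-measures ANOVA. No
sphericity correction is applied (none was reported in the design this
mirrors); that is a known limitation for strongly non-spherical data.

Tukey HSD runs within each species over angle pairs using the pooled
within-subject residual MS and the studentized range distribution with
k = number of angles; the mean difference is first-minus-second angle of
each ordered pair. Using the pooled error for all species matches a shared
error-term convention; under the null the familywise error is ~5%
(verified by seeded simulation).

Complete-case enforcement removes any subject missing an angle level
(repeated-measures requirement) and errors if fewer than 2 subjects per
species remain. Length regressions are OLS of the outcome on sample length
in cm, by default on one point per subject (the subject's mean across
angles) so n equals the number of individuals. Summaries report per-cell
mean, SE = SD/√n, and range; single-value cells get SE 0 with a flag.

## Study-table generator

Cell means and SEs default to the study's pooled species×angle values for
peak frequency and velocity, with complete-case counts 8/8/6 and species
length distributions (7.7/8.19/7.35 cm means). Each value is
cell_mean + subject_effect + residual: the subject effect
(SD 14 Hz / 0.0139 m/s, derived from the reported ANOVA variance
components) is shared across a subject's angles, giving true
repeated-measures correlation; the residual SD is SE·√n_ref with n_ref the
reference count the SE was computed at, so cell spread is invariant to
scaling subject counts up. The Gaussian model can produce negative
velocities in the smallest-mean cells; means (which the analyses use) are
unaffected, but the generator should not be read as a physical amplitude
model.

## Closed-loop pipeline

`run_study` generates one phantom per species (default 24 mm at 30 µm —
shorter than a real ~65 mm whisker but preserving ~10 undulation
wavelengths), measures it, predicts f(0°)/f(90°) from the measured centroid
widths, synthesizes one recording per subject×angle with the tone at the
predicted frequency (45° uses the 0°/90° midpoint; per-subject jitter
SD 8 Hz shared across angles plus 5 Hz per recording) and amplitude at the
design's velocity cell mean with lognormal (σ = 0.3) scatter, then runs the
spectral stage and the full statistics on the recovered peaks. Because
tones equal predictions, the measured-vs-theoretical percent difference is
a self-consistency oracle (≈ 0–5%, from 5 Hz bin quantization plus the
jitter); a `mismatch_hz` knob injects deliberate discrepancy. All
randomness derives from the single config seed via a seed sequence; two
runs at the same seed produce byte-identical CSVs.

What the synthetic study does *not* emulate: fluid–structure interaction,
amplitude physics (velocities are injected, not predicted), harmonics and
broadband turbulence structure, CT greyscale/beam artifacts, and real
between-species geometry differences beyond the smooth/undulated archetype
parameters. Passing tests therefore demonstrate the correctness and
self-consistency of the measurement chain, not biological conclusions about
real whiskers.
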