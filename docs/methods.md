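# Methods

`ctiq` implements the task-based image-quality chain used to characterize
CT reconstructions — noise power spectrum (NPS), circular-edge task
transfer function (TTF), iodine contrast, and the non-prewhitening model
observer with eye filter (NPWE) — together with a synthetic phantom
generator that provides exact ground truth for every stage.  This note
records the models, the numerical choices, and the limits of what the
synthetic validation demonstrates.

## Image model and conventions

Stacks are 3D arrays of Hounsfield units indexed `(slice, row, col)`,
row = y, col = x, with the physical position of a pixel center at
`(index + 0.5) * spacing` mm.  Analysis is always in floating-point HU;
the native on-disk format stores int16 with a slope/intercept (unit slope
whenever the HU range fits, so round-trip error is at most 0.5 HU).
Circular ROIs include a pixel when its *center* lies within the radius —
the convention of common clinical ROI tools; no area weighting.

## Noise power spectrum

The 2D NPS is the ensemble average over ROI-slice instances of the
detrended periodogram,

    NPS(fx, fy) = (Δx Δy) / (Nx Ny) · ⟨ |DFT₂{ROI − FIT}|² ⟩,

with `FIT` a per-ROI least-squares second-order polynomial surface
(coefficients solved on centered, normalized coordinates for
conditioning).  The default geometry is four 128×128 quadrant ROIs over
40 slices (160 instances).  No window or taper is applied beyond
detrending.

Detrending notches the lowest spatial frequencies: projecting out the
6-dimensional quadratic surface removes, for white noise, ~43% of the
power in the first radial frequency bin and all of the DC bin.  Because
the removed fraction per DFT bin is computable exactly from an
orthonormal basis of the fit space (`1 − Σⱼ |DFT(qⱼ)|²/N`), the spectrum
is divided by this survival fraction (bins attenuated below 20% — in
practice only DC — are left as measured).  Without this correction the
average spatial frequency of a flat spectrum is biased high by ~3%; with
it the bias is ≲0.1%.

The radial NPS is the mean of 2D samples per radial bin (default bin
width: one 2D frequency step).  Samples beyond the *axis* Nyquist (grid
corners) are excluded; the last, cap-truncated bin is coordinated at the
cap.  Noise magnitude is `sqrt(∬ NPS)` — the standard deviation of the
detrended noise by Parseval; the term is not otherwise standardized, so
the definition is recorded in result metadata.  `f_av = ∫f·NPS(f)df /
∫NPS(f)df` is evaluated by trapezoid over the binned profile, extended
to f = 0 with the edge value and skipping a leading bin that contains
only the (detrend-invalidated) zero-frequency sample.

## Circular-edge TTF

Every pixel of an annular ROI around a cylindrical insert contributes a
(radius, HU) sample; samples are pooled across slices and binned by
radius (default bin width 0.1 × pixel spacing; empty interior bins are
filled by linear interpolation so the profile is uniformly sampled).
The edge spread function is differentiated (optional 3-bin moving
average first; central differences) into the line spread function, whose
zero-padded Fourier modulus, normalized at DC, is the TTF.

Conditioning at realistic noise levels required three measures, all
disabled-by-construction irrelevant for clean data:

* **Edge localization on a smoothed copy.** The taper placement uses a
  moving-average-smoothed |LSF| so single noise spikes cannot hijack the
  peak or width estimate.
* **Outer-tail baseline and taper.**  The LSF baseline is the median of
  the bins beyond twice the taper half-width *outside* the insert — the
  innermost radial bins hold only one or two pixels per ring and are far
  too noisy to enter a baseline.  A Tukey window confines the transform
  to ±2 FWHM around the edge, suppressing the broadband noise floor that
  otherwise biases the TTF modulus upward.
* **Kernel transfer correction.**  The radial bin average (boxcar), the
  optional 3-bin smoother, and the central-difference derivative each
  attenuate high frequencies deterministically; their combined |transfer|
  is divided out where it exceeds 0.3, making the TTF insensitive to the
  bin width chosen (wider bins are used at high noise: bin width scales
  with the noise-to-contrast ratio, clamped to [0.1, 0.5] pixels).

TTF₅₀ is the first downward crossing of 0.5, linearly interpolated.
Against a known Gaussian blur the noiseless recovery is accurate to
<0.5%; at contrast 120 HU, noise magnitude 20 HU and 20 slices, single
measurements land within ±10% and three-replicate averages within ~±5%.
At the most extreme emulated condition (noise 100 HU, CNR ≈ 1.2) single
measurements can err by ±15%, which is why the study emulation uses the
replicate-averaged TTF curve for detectability.

Insert contrast is measured as the count-weighted mean ESF deep inside
the edge (r < 0.6 R) minus far outside (r > 1.4 R).

## NPWE detectability

For a disk task of radius R and contrast C the task function is
`W(ρ) = C·πR²·|2J₁(2πRρ)/(2πRρ)|`, and

    d′² = [∬ W² TTF² E² du dv]² / ∬ W² TTF² NPSᵏ E⁴ du dv

evaluated as Riemann sums on a 256² Cartesian grid spanning ± the
reconstruction Nyquist (doubling the resolution changes d′ by <10⁻⁴).
Radial TTF and NPS profiles are interpolated linearly in radius; beyond
the last measured frequency the TTF holds its last value and the NPS is
zero.  The exponent k defaults to 1 — the standard NPWE denominator,
linear in noise power; `nps_exponent=2` is available as a configuration
switch for formulations that square the NPS, and both modes are tested.

The eye filter is `E(ρ) = ρ^1.5·exp(−cρ²)` in cycles/degree, normalized
to peak 1 with the peak at 4 cyc/deg (c = 0.75/16); exponent and peak
are configurable, since no single form is universal among model-observer
implementations.  Image frequencies convert to angular frequencies
through a display model — zoom 1.5, viewing distance 500 mm, 300 mm
field of view on a 512 matrix, 0.05 mm monitor pixel pitch — giving
magnification M = zoom·(monitor pitch)/(image pixel) and angular
frequency `f/M · D · π/180`.  Under these defaults the eye filter peaks
at 0.059 mm⁻¹ in the image plane, inside the 10-mm-disk task band.

## Synthetic phantom generator

Noise is shaped by frequency-domain filtering of white Gaussian fields
with `sqrt(S(f))`, normalized on the discrete grid so the expected pixel
variance equals `sigma_hu²` exactly.  Shapes: `white` (flat) and
`ramp_gauss`, radial NPS ∝ `f·exp(−f/f0)` — a CT-like spectrum that
rises to a peak at f0 and decays; its untruncated NPS-weighted mean
frequency is 2·f0, and f0 is solved numerically from a target f_av
(truncated at the measurement Nyquist) so generator targets are stated
in the same units the analysis reports.

Inserts are ideal disks convolved with an isotropic Gaussian PSF; the
convolution is evaluated *exactly* at each pixel center via the
noncentral-χ² CDF (the Gaussian mass inside a disk), so the ground-truth
TTF is exactly `exp(−2π²σ_b²f²)` with no rasterization error.  Slices
are independent noise realizations: the analysis treats slices as
ensemble members, and this is the cleanest null structure.  Real CT
stacks have inter-slice correlation, anisotropy, aliasing from the
reconstruction kernel, and non-stationary noise — none of which the
generator emulates, so passing tests demonstrate estimator correctness
under the stated model, not robustness to all properties of scanner
data.

Geometry defaults mirror an abdominal protocol: 512×512 pixels at
0.488 mm (250-mm FOV) for the QA-phantom scenes, 0.82 mm (420-mm FOV)
for the multi-energy scenes, acrylic insert 25 mm at +120 HU, iodine
inserts 28 mm, 2-cm measurement ROIs.  Every stochastic operation takes
an explicit seed; replicate r of a condition uses a fixed arithmetic
offset of the base seed, so any subset of the study regenerates
bit-identically.

## Emulated study and calibration defaults

The emulated comparison of two reconstruction-algorithm versions (V1,
V2) at three strengths (mild/standard/strong) and four VMI energies
(40–70 keV) uses three parameter tables:

* **Noise magnitude and iodine contrast** per condition are transcribed
  measurement tables shipped with the package (`ctiq/data/*.csv`).
* **Texture (f_av) and TTF₅₀ defaults** (`ctiq.tables`) are the
  package's calibration: the source study reports these only as figures
  and percent differences, so values were chosen once to land in the
  reported qualitative regime — f_av strictly decreasing from mild to
  strong at every energy, V2 above V1 in both f_av and TTF₅₀, V2's
  texture coarsening from 40 to 60 keV with the decline spread evenly
  across that range, magnitudes 0.15–0.31 mm⁻¹ (f_av) and
  0.21–0.51 mm⁻¹ (TTF₅₀) — and frozen.  Where a reported between-energy
  change was explicitly not statistically significant, the defaults may
  flatten or slightly reverse it when the detectability orderings
  require it (the V2/strong 60→70 keV cells); these choices are visible
  in `ctiq.tables` and are deliberately conservative nowhere else.

The study runner generates per condition and replicate: a uniform stack
(NPS → noise magnitude, f_av), an acrylic-insert stack (TTF₅₀), and a
multi-energy stack (contrast per iodine concentration).  d′ combines the
per-replicate NPS with the replicate-averaged TTF curve and
replicate-averaged measured contrast for a 10-mm disk task.  The run
uses reduced stack sizes — 256×256 uniform/insert slices with 64×64
quadrant ROIs, 16 NPS slices, 20 TTF slices, 192×192 multi-energy stacks
with 8 slices — which keep every per-condition noise, texture, blur and
contrast target of the full protocol while making a complete 72-stack
study reproducible in about half a minute.  With these defaults the
emulation reproduces the study's qualitative results across seeds:
d′(V2) > d′(V1) at 40–60 keV for every level and concentration, d′(V1)
maximal at 70 keV, d′(V2) maximal at 60 keV.

## Statistics

Percent differences are `100·(b − a)/a` with the first-named condition
as reference.  Replicate aggregation is mean ± sample SD (n−1; a single
value has SD 0 by documented convention).  The paired Wilcoxon
signed-rank test is two-sided, with zero differences handled by the
Pratt method (ranked with the rest, then dropped); for n ≤ 15 retained
pairs the p-value is exact by enumeration of all 2ⁿ sign patterns
(which remains exact under tied ranks), otherwise a normal approximation
with Σrᵢ²/4 variance (absorbing ties) is used.  No multiple-testing
correction is applied.  The derived-percentage reproduction compares
recomputed values with printed ones at ±0.1 absolute, absorbing printed
rounding; quantities whose printed derivation used unrounded
replicate-level source data (not public) cannot be reproduced to that
precision from table means and are reported without a pass/fail
assertion.

## Known limitations

* The generator is image-domain only: no projection physics, beam
  hardening, or the anti-correlated noise of spectral material
  decomposition.
* TTF estimates below CNR ≈ 1.5 remain noisy (±10–15% per measurement)
  even with the stabilized pipeline; replicate averaging is the
  recommended mitigation and is what the study runner does.
* The eye-filter functional form and the display-magnification reading
  are documented defaults, not universal standards; absolute d′ values
  shift under other conventions although orderings are stable.
* `wilcoxon_paired` assumes exchangeability of paired differences; with
  n as small as 3 the smallest attainable two-sided p is 0.25.
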