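# Methods

## Signal model

The package models an interleaved Look-Locker partial-saturation-recovery
(LL partial-SR) acquisition. Each repetition begins with a train of
slice-selective saturation pulses (one slot of `t_sat` per slice, the whole
train filling one inter-pulse interval `TR_alpha`), followed by `n_points`
readout pulses of flip angle `alpha` spaced by `TR_alpha`; slice `s` is read
while the others relax. All angles are accepted in degrees, all times in
milliseconds, matching how such protocols are quoted.

The discrete recursion underlying the model is: saturation scales `Mz` by
`cos(sat_angle)`; between pulses `Mz` relaxes toward `M0` with time constant
`T1`; each readout pulse samples `sin(alpha)·Mz` and scales `Mz` by
`cos(alpha)`. At steady state with a perfect 90° saturation this recursion
has the exact closed form

    Mz(t_k) = A · (1 − exp(−t_k/T1*)),   t_k = (k+1)·TR_alpha,
    A = M0 (1 − E) / (1 − E cos alpha),  E = exp(−TR_alpha/T1),
    1/T1* = 1/T1 − ln(cos alpha)/TR_alpha.

Two amplitude conventions coexist in the literature: the exact discrete
steady state `A` above, and the continuous-readout pair
`M0* = M0·T1*/T1`, `M0** = M0*(1 − e^(−TR/T1*))`, which equals `A` only to
first order in `TR_alpha/T1`. The simulator and all internal oracles use the
exact `A` (`train_amplitude`); `steady_state_amplitudes` exposes the
continuous approximation and warns when `TR_alpha` is not small against T1*.
The distinction never affects T1 estimation — the fit's amplitude is a free
parameter — but matters when asserting exact model equivalence.

Because perfect saturation nulls `Mz` regardless of history, a truncated
readout train produces *exactly* the first samples of the full train; this
is the property that makes variable averaging consistent. With an imperfect
saturation pulse (`sat_angle ≠ 90°`) residual magnetization carries across
repetitions; the simulator then iterates the cycle recursion to steady state
(convergence to 1e-9 relative between consecutive cycles, independent of the
initial magnetization). Each schedule block is treated as repeated to its
own steady state; transients at block boundaries are neglected, which is
accurate because every block is repeated several times.

Deliberately out of scope: RF pulse shapes and slice profiles, off-resonance,
magnetization transfer, T2*/TE decay (TE is carried for timing only — the
sampled signal is `sin(alpha)·Mz` with ideal spoiling).

## Variable averaging

A schedule is an ordered list of blocks `(n_points, n_repeats)`; the
per-time-point average count `NA(k)` is the sum of repeats of all blocks
that still sample point `k`, which is non-increasing by construction.
`build_schedule` reproduces a printed set of constraints — head points at a
fixed high NA, tail points at a fixed low NA, an exact total budget — and
fills the interior with a deterministic non-increasing staircase that
spreads the remaining budget as evenly as integer counts allow. For the
default constraints (79 points, NA 42×5 head, 3×20 tail, budget 948) the
interior sits at 13/12, and the block decomposition is
`(79,3),(59,9),(35,1),(5,29)`. Only the constraints are authoritative; the
interior interpolation is a package choice, and every derived headline
quantity (budget, head/tail NA, durations) depends only on the constraints.

Scan time is `n_lines · Σ_blocks n_repeats · (n_slices·t_sat +
n_points·TR_alpha)`. At equal budget the readout time of the variable and
constant schemes is identical and only the per-repeat saturation overhead
differs (594 s vs 576 s at 24 lines — both "10 minutes"); truncation is
cheaper than repeating the full train the same number of times, which is
where the extra early averages come from.

Predicted SNR per time point is `sin(alpha)·Mz(t_k)·sqrt(NA(k))/noise_sd`,
using the exact train amplitude.

## Synthetic data generator

The generator emulates a 0.1 T phantom experiment on a 64 × 35 matrix at
3 mm in-plane resolution:

- **Phantom**: a circular water bath (radius 13.5 px ≈ 8.1 cm jar, default
  T1 3000 ms for water at low field) containing up to five vial discs
  (radius 4.1 px ≈ 2.5 cm) on a ring. Vial T1 is either given directly or
  evaluated from linear temperature laws `T1_i = k_i·T + c_i` at a requested
  temperature (warning outside the calibrated 20–65 °C range). The disc
  sizes follow the physical phantom; smaller vials leave too little interior
  clear of the Hamming partial-volume band against the long-T1 bath.
- **Flip-angle field**: Gaussian-filtered white noise (correlation length
  8 px), standardized and rescaled so the sample mean and s.d. match the
  requested 4.8 ± 0.6° exactly; seeded.
- **Undersampling**: exactly `n_keep` of `n_lines` phase-encode lines drawn
  without replacement with Gaussian weights centered on the DC line
  (default width `n_lines/4`, a package choice); the DC line is always
  retained since the fit's dynamic range requires it.
- **Noise**: independent complex Gaussian noise of s.d. `noise_sd` per
  component is added per k-space sample, per repeat, on sampled lines only;
  magnitude images therefore carry Rician noise. No Rician bias correction
  is applied anywhere. The default `noise_sd = 2.0` (for `M0 = 1` on the
  64 × 35 grid, i.e. image-domain σ ≈ 0.042 against a peak signal of
  ≈ 0.087, single-average peak SNR ≈ 2) was chosen so that the reconstructed
  per-vial T1 dispersion lands in the regime reported for this protocol
  (≈ 7% for T1 of 50–235 ms; ≈ 9% and accuracies in the 75–90% range for
  T1 of 470–1005 ms).

What the generator does **not** emulate: coil sensitivity profiles, B0
off-resonance, gradient nonlinearity, physiological drift, scanner
instabilities, and the hardware-specific sources of the underestimation seen
on real systems. Passing tests therefore demonstrate correctness of the
estimation chain and its noise response, not field performance.

## Reconstruction

Per repeat: optional peak-normalized separable 2-D Hamming apodization,
optional symmetric zero-fill (64 × 35 → 128 × 69, intensity rescaled by the
matrix-size ratio), inverse 2-D FFT, magnitude. Magnitude is taken per
repeat and averaged in postprocessing — the acquisition stores every repeat —
with division by `NA(k)`. Background subtraction (mean over a user ROI,
applied per repeat, negatives clipped to zero by default) restores the
dynamic range assumption that the signal approaches zero at the first
sample; both the clipping and the fit weighting (`weight_by_na`) are
switches with documented defaults (clip on, weights off). In the synthetic
setting, background subtraction trades a Rician-floor underestimation for a
high-signal over-subtraction bias; NA-weighting was evaluated and rejected
as a default because down-weighting the late points substantially amplifies
the early-point noise-floor bias for long T1.

Vial segmentation is intensity-based region growing: 4-connected flood fill
per seed admitting pixels within `tolerance · seed_intensity` (scikit-image
`flood`); seeds below an intensity threshold are rejected, and two seeds
reaching one region merge by default.

**T1\* fitting.** The amplitude enters the model linearly, so the fit
profiles it out and minimizes over T1* alone: a deterministic coarse
logarithmic grid over `(TR_alpha/10, T1*max]` vectorized across pixels,
followed by bounded scalar refinement between the neighboring grid nodes
(relative tolerance 1e-7). This replaces a per-pixel heuristic
initialization: the grid search cannot be trapped by a bad starting point on
low-SNR magnitude data and is deterministic with an explicit tie-break
(first minimum). T1* is bounded above by `T1*max = −TR_alpha/ln(cos
alpha_nominal)`; pixels pinned at either end are flagged invalid (an upper
pin means no recovery within the window, a lower pin a recovery saturated
before the first sample — a constant positive trace fits the *lower*
degenerate end exactly), as are pixels with non-positive amplitude.
All-zero pixels are invalid, never an error. 95% confidence half-widths are
available from the Gauss–Newton covariance at the optimum.

T1 conversion inverts the apparent-relaxation relation per pixel with the
local flip angle; pixels whose T1* reaches the local pole are invalidated.

## Thermometry

Spectroscopic saturation-recovery calibration fits `M0(1 − e^(−t/T1))`
(log-spaced sampling supported); per-sample temperature laws are ordinary
least squares with r² as squared Pearson correlation. The global
sensitivity K is fit through the origin (the law `k = K·T1a` has no
intercept), unweighted by default with an inverse-variance-weighted variant;
on the bundled 15-sample table the unweighted fit gives K ≈ 0.0283 ± 0.0003
°C⁻¹, while the study's printed value 0.0265 ± 0.0007 °C⁻¹ presumably
reflects a different regression convention that is not recoverable from the
printed table alone — where a worked conversion prescribes K = 0.0265, that
constant is used as an input. Temperature maps come from
`Tb = Ta + (T1b/T1a − 1)/K` (sample-independent) or
`Tb = Ta + (T1b − T1a)/k_i` (sample-specific); the two agree identically
when `k_i = K·T1a` pixel-wise. Maps must share the reference temperature;
validity masks propagate.

## Validation statistics

Accuracy is the mean over samples of (estimate/reference)·100; precision the
mean of (s.d./estimate)·100. Bland–Altman reports bias, s.d. and 95% limits
`bias ± 1.96·s.d.` with a one-sample t-test for zero bias. The Grubbs test
is the two-sided single-outlier form, applied at most once. Levene's test
defaults to mean-centering (Brown–Forsythe selectable). The
homogeneity-of-regression check for merging heating and cooling runs is a
nested F-test of one pooled line against separate lines (2 numerator
degrees of freedom); merging is conventional only at p ≥ 0.05.

## Numerical and design choices

- Frozen reference values in the tests were computed with 50-digit
  arbitrary-precision arithmetic (mpmath) or brute-force enumeration,
  independently of the implementation.
- FFT convention: DC-centered k-space (fftshift); line index `n_lines//2`
  is the central line.
- Problem sizes: the test suite simulates single-slice 64 × 35 acquisitions;
  the stochastic schedule comparison uses 20 fixed seeds and three long-T1
  vials; the examples run the full 79-point protocol. These sizes make every
  property testable on a laptop while preserving the protocol's timing,
  matrix and budget exactly.
- Determinism: every random operation takes an explicit seed
  (`numpy.random.default_rng`); identical configuration and seed reproduce
  bit-identical k-space and an identical pipeline manifest hash.

## Known limitations

- The magnitude-domain noise biases (Rician floor, background
  over-subtraction) are reproduced but not corrected; bias-correction
  schemes exist and could be slotted in before the fit.
- The interleave is modeled on a shared nominal time grid; per-slice offsets
  (< TR_alpha) are below the model's resolution and ignored.
- The matched-budget advantage of variable averaging measured on real
  hardware is much larger than what pure noise statistics produce in this
  clean simulator (fractions of a percent); reproducing the printed
  accuracy tables from synthetic scans is out of reach by design, and the
  package substitutes parameter-recovery checks.
- Temperature laws are linear; protein-denaturation nonlinearity above the
  mild-hyperthermia range is not modeled.
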