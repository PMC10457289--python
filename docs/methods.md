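# Methods

This note documents the models behind `pulsecount`, the parameters that
matter, the numerical choices, and what the synthetic studies do and do
not demonstrate about real detectors.

## Pulse-response model

Measured single-electron responses of scintillator ADF detectors show a
sharp (~100 ns) rise and an approximately exponential fall; solid-state
detectors are roughly an order of magnitude faster. No closed form is
canonical, so the package adopts the phenomenological double exponential

    s(t) = (1 − exp(−t/τ_r)) · exp(−t/τ_f),

sampled on the ADC grid, normalized to unit peak and truncated once the
tail falls below 10⁻³ of the peak (configurable; bounds the cost of trace
synthesis). Defaults:

| kernel       | τ_r    | τ_f      | sampling |
|--------------|--------|----------|----------|
| scintillator | 100 ns | 0.413 µs | 8 ns     |
| solid_state  | 20 ns  | 50 ns    | 8 ns     |

The 8 ns period corresponds to a 125 MHz ADC clock. Scintillators can
additionally show a much slower afterglow (charge trapping and delayed
release); `make_afterglow_kernel` mixes a slow exponential tail (default
τ = 4.5 µs) into the fast kernel at an amplitude fraction of 0.05. The
fraction is a declared default — the afterglow is visibly weaker than the
primary pulse but no amplitude ratio is established — and is configurable.
Measured pulse shapes can be loaded from the two-column kernel CSV and
used everywhere a generated kernel can.

### Decay fitting

`fit_exponential_decay` fits `A·exp(−t/b) + c` by damped least squares
(scipy's Levenberg–Marquardt, falling back to a trust-region fit with
`b > 0` enforced if LM wanders to a non-physical decay time). The initial
guess comes from a log-linear regression on the baseline-subtracted tail.
Standard errors are the square roots of the Jacobian-based covariance
diagonal, i.e. the local curvature of the objective at the optimum.

The fit window matters when two decay components coexist: fitting a
single exponential to an afterglow tail too close to the peak biases `b`
far below the slow constant (starting the window at 3 fall times still
yields `b ≈ 1.4 µs` against a true 4.5 µs, because the fast component
still rivals the 5% afterglow there). The window is therefore an explicit
parameter; the slow constant is recovered to ~1% once the window starts
at ≈ 7 fast fall times (t ≳ 3 µs for the default scintillator).

## Event streams and trace synthesis

Electron arrivals are a homogeneous Poisson process (count
Poisson(rate·duration), times uniform). Pulse heights are zero-truncated
Gaussian with mean 1 and cv = 0.15 by default — the height distribution
of a real detector chain is not standardized, so the cv is a declared,
configurable study condition. Impact positions are uniform in azimuth
with radius drawn from a piecewise-linear radial density; the default is
a Rutherford-like `r⁻³` fall-off across the detector span, mimicking
high-angle scattering. Sampling from the piecewise-linear density is
exact (per-interval quadratic CDF inversion), not binned.

Traces are `baseline + Σ h_i · kernel(t − t_i) + N(0, σ)` with each pulse
placed at the first sample instant at or after its continuous arrival
time: a clocked ADC sees exactly this, and sub-sample phase is below the
8 ns resolution. Superposition is exact, making the linearity and
dose-conservation properties testable to machine precision. ADC
quantization clips to `[0, range]`, scales to `2^bits − 1` levels and
rounds half-to-even.

For segmented detectors each segment is an independent electronic
channel: its trace contains only its own events and its own noise draw.

## Discriminator

A deterministic two-state machine per channel, mirroring threshold logic
implementable in FPGA fabric:

* working signal: the trace (amplitude mode) or the lagged difference
  `s[i] − s[i−lag]` (gradient mode; default lag 4 samples = 32 ns,
  spanning the ~100 ns rise);
* ARMED → HOLD: after `min_consecutive_above` (default 2) consecutive
  working samples above threshold; the event is stamped at the run start
  (a `record_at="end"` flag exists, since hardware could latch either);
* HOLD → ARMED: after `min_consecutive_below` (default 2) consecutive
  samples at or below threshold − hysteresis AND `dead_time` (default 2)
  samples since the event.

Hysteresis defaults to 0; real discriminators need a few noise standard
deviations of it to avoid double-triggering when the signal recrosses the
threshold slowly (the efficiency study sets 4σ). With minimal settings
(runs of 1, dead time 0) an alternating above/below input yields one
event per two samples — 62.5 MHz at the 8 ns clock, the hard ceiling of
the approach.

Detection efficiency is the *count ratio* detected/true (it may exceed 1
if noise triggers; it is reported as-is). A time-matched scorer (greedy
one-to-one matching within a tolerance) exists for diagnostics and for
threshold calibration, where over- and under-counting must not cancel.

## Efficiency study

The study crosses discriminator mode × segmentation × kernel on
*identical* event streams per repetition (paired design), so condition
orderings are not washed out by event-sampling noise. Study conditions:
1000 µs per repetition, 100 repetitions per rate, noise σ = 0.02 of the
unit pulse height (a realistic post-conditioning noise floor; declared,
configurable), heights cv = 0.15. The segmented geometry is four inner
quadrants (25–60 mrad) plus two rings (60–110, 110–180 mrad) — the inner
annulus is subdivided because the `r⁻³` dose concentrates there (~84% of
electrons), which is exactly why quadrant-splitting the inner region buys
the most efficiency.

Thresholds are optimized per condition on a held-out calibration stream
(~1000 events; stretched in duration at low rates): candidates span the
working signal linearly from its median to its maximum, the score is
time-matched efficiency minus the spurious-detection fraction, and ties
across the resulting plateau resolve to the plateau midpoint (maximum
margin against both the noise floor and the pulse-height spread). This
mirrors per-stream threshold tuning on hardware while preventing the
degenerate solution where noise triggers compensate merged pulses.

Expected behaviour, all reproduced by the acceptance suite: efficiency
→ 1 at low rate for every condition; at 10 e⁻/µs the ordering
segmented-gradient ≥ segmented-amplitude, monolithic-gradient ≥
monolithic-amplitude, segmented ≥ monolithic within each mode, and
solid-state ≥ scintillator for matched conditions. Monolithic amplitude
is the weakest and also the condition closest to the low-rate 99% limit:
its merge window is the full pulse decay back to threshold (~0.5 µs), an
irreducible ~0.5% coincidence loss at 0.01 e⁻/µs.

## Scan imaging

A raster scan is simulated row by row: per-pixel Poisson rates
`base_rate × specimen`, one continuous trace per row so pulses straddle
pixel boundaries. The analog pixel value is the *mean* of the trace
samples in the dwell window (integrating-ADC behaviour); the counted
value bins discriminated events by time; truth bins generated events.
Pixel windows are floor-boundary sample slices, so the dwell need not be
an integer multiple of the ADC period (50 ns dwell = 6.25 samples is
fine). Rows are independent by default; a flyback-carryover flag builds
the frame as a single timeline with configurable flyback idle so
afterglow persists across rows. Frames are averaged plainly; registration
is out of scope.

`directional_spectrum_ratio` compares mean top-quartile periodogram power
along the fast axis against the slow axis (1 = isotropic). The analog
image of a step edge at 50 ns dwell shows a ≥3-pixel decay tail and a
ratio ≪ 1; the counted image's tail is ≤1 pixel and its ratio ≈ 1. The
demonstration dose is 0.5 e⁻/µs: well below pile-up, which is the regime
counting targets. At several e⁻/µs the counted image itself becomes
sub-Poisson (dead-time anticorrelation along the scan direction) and its
spectrum ratio rises above 1 — a real pile-up signature, not an artifact
of the simulation.

## Detector-map QC

The active region is `map > (min+max)/2` (a robust 1st/99th-percentile
midpoint option guards hot pixels); the map is normalized so background
→ 0 and the active mean → 1, making every score scale-invariant. The
inner opening (background enclosed by the active region) is fitted by
second moments — for a filled ellipse the principal diameter is
4·√eigenvalue — giving ellipticity = major/minor ≥ 1 and the profile
center (geometric centroid of the hole; hole intensities are flat, so
intensity weighting would change nothing).

Profiles use 1-pixel radial bins and 360 azimuthal bins. Flatness is the
azimuthal mean over *active* pixels per radial bin, evaluated where the
mask's azimuthal coverage is ≥ 90% — restricting to active pixels keeps
azimuthal defects (gaps, dead wedges) from contaminating the radial
profile. Roundness is the radial mean per azimuthal bin over *all* pixels
of that valid annulus, so azimuthal defects register fully. Scalar scores
are RMS fractional deviations from 1 (flatness, roundness over their
profiles; smoothness over active pixels, optionally after median-filter
detrending). RMS is this package's declared convention: the metrics'
scalar form is not standardized, so absolute comparability with other
implementations' bar charts is not claimed — orderings and calibrated
recoveries (e.g. an injected 1 + 0.1·sin φ sensitivity yields roundness
0.1/√2) are.

## Randomness and reproducibility

A single integer seed is expanded into per-purpose substreams by hashing
string labels into `SeedSequence` keys; adding a consumer never perturbs
existing streams. Every CLI run writes its resolved configuration and
seed next to its outputs; re-running from that file reproduces outputs
bit-identically.

## Problem sizes

The shipped studies use 100 repetitions of 1000 µs traces (125k samples
at 8 ns) for efficiency points, 128×128 scans for imaging demonstrations,
100×100 scans (10⁴ pixels) for Poisson fidelity, and 256×256 maps for QC
— sizes at which the Monte-Carlo error is comfortably below every
asserted tolerance. The discriminator inner loop is numba-compiled; a
full acceptance run is a few minutes on one CPU.

## What the synthetic studies do not show

The generator emulates Poisson arrival statistics, pulse shape, height
spread and white Gaussian noise. It does not emulate detector-specific
noise spectra, gain drift, light-guide nonuniformity (beyond what QC maps
inject deliberately), backscattering, or scan distortion. Passing tests
therefore validate the counting *logic* and its statistical behaviour
under the stated conditions, not the absolute efficiency of any physical
detector; efficiency curves for a specific instrument require its
measured pulse profile (loadable via the kernel CSV) and noise trace
(injectable via the CSV trace reader).
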