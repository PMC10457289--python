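# pulsecount

Electron pulse counting for STEM detectors, in software.

Scanning transmission electron microscopes (STEM) traditionally integrate
the analog output of a scintillator–photomultiplier (or solid-state)
detector at every scan pixel. Counting the individual electron pulses
instead gives images with a true zero vacuum level, intensities calibrated
in electrons, no Gaussian readout noise, and no temporal streaking from
the detector's decay time. The price is *pile-up*: pulses arriving closer
together than the discriminator can separate are merged, and detection
efficiency falls with beam current.

`pulsecount` is a software replica of an FPGA-based pulse-counting chain:
it models single-electron detector pulses, synthesizes digitized Poisson
event traces, discriminates events in the amplitude or gradient domain
with consecutive-sample noise suppression and dead time, forms
simultaneous counted and analog raster images, quantifies detection
efficiency under pile-up for segmented and monolithic detectors, and
scores detector-map uniformity. Everything runs on synthetic signals, so
every claim about counting — uniformity, quantification, temporal
response, efficiency — can be exercised and tested without a microscope.

Intended users: electron-microscopy method developers and detector
engineers who want to prototype discriminator settings, predict counting
efficiency for a detector geometry, or QC detector maps.

## Models

**Pulse response.** A single electron produces a unit-peak pulse
`s(t) = (1 − exp(−t/τ_r)) · exp(−t/τ_f)`, with defaults τ_r = 100 ns,
τ_f = 0.413 µs (scintillator) and τ_r = 20 ns, τ_f = 50 ns (solid-state).
A slow afterglow component (τ = 4.5 µs, 5% amplitude) can be mixed in.
Measured pulse shapes load from CSV. Decays are fitted with
`A·exp(−t/b) + c` by damped least squares, with standard errors from the
local curvature.

**Trace synthesis.** Arrivals are Poisson in time with rate proportional
to beam current; pulse heights follow a zero-truncated Gaussian
(cv = 0.15); impact positions are uniform in azimuth with a Rutherford-like
`r⁻³` radial fall-off over the detector, assigning each event to a
segment. The trace is `baseline + Σ h·s(t − t_i) + N(0, σ)` sampled at
the 8 ns ADC clock, optionally quantized to 14 bits.

**Discrimination.** A two-state machine over the working signal (the
trace, or its lagged finite difference `s[i] − s[i−lag]`): trigger after
`min_consecutive_above` samples above threshold, re-arm after
`min_consecutive_below` samples at/below threshold (minus hysteresis) and
an elapsed dead time. Detection efficiency is detected/true electrons.

## Worked example

```python
import numpy as np
from pulsecount.detector_response import make_kernel
from pulsecount.event_simulator import (EventStream, sample_poisson_events,
                                        sample_heights, synthesize_trace)
from pulsecount.counting_engine import (DiscriminatorConfig, discriminate,
                                        detection_efficiency)

kernel = make_kernel(kind="scintillator")        # 8 ns sampling
times = sample_poisson_events(rate=2.0, duration=500.0, rng_seed=7)
events = EventStream.monolithic(times, sample_heights(len(times), rng_seed=7))
trace = synthesize_trace(events, kernel, noise_sigma=0.02,
                         duration=500.0, rng_seed=7)

for mode, thr in [("amplitude", 0.5), ("gradient", 0.15)]:
    res = discriminate(trace, DiscriminatorConfig(mode=mode, threshold=thr))
    print(f"{mode:9s}: {res.n_detected:4d} detected of {len(events)} "
          f"(efficiency {detection_efficiency(res, events):.3f})")
```

Output:

```
amplitude:  232 detected of 992 (efficiency 0.234)
gradient :  821 detected of 992 (efficiency 0.828)
```

At 2 e⁻/µs the scintillator pulses (~0.5 µs wide) pile up into a raised,
fluctuating baseline: the absolute signal rarely falls back below an
amplitude threshold, so amplitude-domain counting merges most electrons
(23% counted). Gradient thresholding only needs each pulse's sharp rising
edge and recovers 83% of them — the core argument for counting in the
gradient domain.

The same machinery is exposed on the command line:

```bash
pulsecount simulate --rate 2 --duration 500 --seed 7 --out run/
pulsecount count --trace run/trace.csv --config disc.yaml --out run/events.csv
pulsecount scan --config scan.yaml --out images/     # analog/counted/truth TIFFs
pulsecount qc --map detmap.tiff --out report.json
pulsecount efficiency --config eff.yaml --out curve.csv
pulsecount fit-decay --trace run/trace.csv --t-min 1.8
```

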