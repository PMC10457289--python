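"""Raster-scan simulation: simultaneous analog and counted images.

A STEM probe dwells on each pixel in turn along the fast scan axis; the
detector signal is one continuous time series per scan row, so a slow
detector response smears ("streaks") bright features along the fast axis
of the analog image. Counting the discriminated events instead assigns
each electron to the pixel where its rising edge fired the discriminator,
removing the streak. This module simulates both images from the *same*
synthesized trace per row, plus a directional power-spectrum diagnostic
that quantifies the fast-axis suppression of high frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .counting_engine import DiscriminatorConfig, bin_events, discriminate
from .detector_response import PulseKernel
from .errors import InvalidParameterError, UndefinedRatioError
from .event_simulator import EventStream, sample_heights, synthesize_trace

__all__ = [
    "ScanConfig",
    "SpecimenMap",
    "ScanResult",
    "simulate_scan",
    "directional_spectrum_ratio",
    "edge_tail_length",
    "step_edge_specimen",
]


@dataclass(frozen=True)
class ScanConfig:
    """Raster scan parameters: image size (``ny`` rows × ``nx`` pixels),
    per-pixel dwell (ns), fast axis = x (left→right), ``frames`` repeats
    averaged."""

    nx: int
    ny: int
    dwell: float
    frames: int = 1
    fast_axis: str = "x"

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise InvalidParameterError("nx, ny must be >= 1")
        if self.dwell <= 0:
            raise InvalidParameterError("dwell must be > 0")
        if self.frames < 1:
            raise InvalidParameterError("frames must be >= 1")
        if self.fast_axis != "x":
            raise InvalidParameterError("fast axis is x (transpose the specimen instead)")

    @property
    def dwell_us(self) -> float:
        return self.dwell * 1e-3

    @property
    def row_duration_us(self) -> float:
        return self.nx * self.dwell_us


class SpecimenMap:
    """2-D grid of non-negative electron-rate multipliers, pixel-registered
    to the scan (0 = vacuum, 1 = nominal rate)."""

    def __init__(self, values):
        v = np.asarray(values, dtype=float)
        if v.ndim != 2:
            raise InvalidParameterError("specimen must be 2-D")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise InvalidParameterError("specimen values must be finite and >= 0")
        self.values = v

    @property
    def shape(self):
        return self.values.shape

    def transposed(self) -> "SpecimenMap":
        return SpecimenMap(self.values.T)


def step_edge_specimen(nx: int, ny: int, edge_col: int | None = None) -> SpecimenMap:
    """Bright material on the left, vacuum to the right of ``edge_col``
    (default: the middle column)."""
    if edge_col is None:
        edge_col = nx // 2
    v = np.zeros((ny, nx))
    v[:, :edge_col] = 1.0
    return SpecimenMap(v)


@dataclass(frozen=True)
class ScanResult:
    """Analog (trace mean per dwell window), counted (discriminated events
    per pixel) and truth (generated events per pixel) images, averaged over
    frames."""

    analog: np.ndarray
    counted: np.ndarray
    truth: np.ndarray
    scan: ScanConfig
    n_events_total: int


def _row_events(rates, dwell_us, rng, height_cv):
    """Inhomogeneous Poisson events along one scan row (piecewise-constant
    rate per pixel)."""
    n_per_pixel = rng.poisson(rates * dwell_us)
    n = int(n_per_pixel.sum())
    if n == 0:
        return np.empty(0), np.empty(0), n_per_pixel
    offsets = np.repeat(np.arange(len(rates)) * dwell_us, n_per_pixel)
    times = np.sort(offsets + rng.uniform(0.0, dwell_us, size=n))
    heights = sample_heights(n, cv=height_cv, rng_seed=rng)
    return times, heights, n_per_pixel


def simulate_scan(
    specimen: SpecimenMap,
    base_rate: float,
    scan: ScanConfig,
    kernel: PulseKernel,
    disc_config: DiscriminatorConfig,
    noise_sigma: float = 0.0,
    baseline: float = 0.0,
    rng_seed: int = 0,
    height_cv: float = 0.15,
    flyback_carryover: bool = False,
    flyback_time_us: float = 0.0,
) -> ScanResult:
    """Simulate a raster scan producing analog, counted and truth images.

    Per scan row, electron arrivals follow an inhomogeneous Poisson
    process with rate ``base_rate * specimen[row, col]`` (e⁻/µs) during
    each pixel's dwell; one continuous trace is synthesized for the whole
    row so pulses straddle pixel boundaries. The analog pixel value is the
    mean of the trace samples inside the dwell window (integrating-ADC
    behaviour); the counted value bins discriminated events per pixel;
    truth bins the generated events. Frames are independent and averaged.

    With ``flyback_carryover`` the whole frame is one timeline with
    ``flyback_time_us`` of idle between rows, so slow afterglow persists
    across row boundaries.
    """
    if specimen.shape != (scan.ny, scan.nx):
        raise InvalidParameterError(
            f"specimen shape {specimen.shape} != scan ({scan.ny}, {scan.nx})"
        )
    if scan.dwell < kernel.sample_period:
        raise InvalidParameterError("dwell must cover at least one sample period")
    dt_us = kernel.sample_period * 1e-3
    # pixel dwell windows need not be synchronous with the ADC clock;
    # pixel p spans samples [floor(p*dwell/dt), floor((p+1)*dwell/dt))
    bounds = np.floor(np.arange(scan.nx + 1) * scan.dwell_us / dt_us + 1e-9).astype(int)
    row_dur = scan.row_duration_us

    analog = np.zeros((scan.ny, scan.nx))
    counted = np.zeros((scan.ny, scan.nx))
    truth = np.zeros((scan.ny, scan.nx))
    n_total = 0

    for frame in range(scan.frames):
        rng = substream(rng_seed, "scan", frame)
        if flyback_carryover:
            a, c, t, n_ev = _simulate_frame_continuous(
                specimen, base_rate, scan, kernel, disc_config, noise_sigma,
                baseline, rng, height_cv, flyback_time_us, bounds)
        else:
            a = np.zeros((scan.ny, scan.nx))
            c = np.zeros((scan.ny, scan.nx))
            t = np.zeros((scan.ny, scan.nx))
            n_ev = 0
            for row in range(scan.ny):
                rates = base_rate * specimen.values[row]
                times, heights, n_pix = _row_events(rates, scan.dwell_us, rng, height_cv)
                t[row] = n_pix
                n_ev += len(times)
                ev = EventStream.monolithic(times, heights) if len(times) else \
                    EventStream.monolithic(np.empty(0), np.empty(0))
                trace = synthesize_trace(
                    ev, kernel, noise_sigma=noise_sigma, baseline=baseline,
                    duration=row_dur, rng_seed=rng)
                a[row] = _pixel_means(trace.samples, bounds)
                det = discriminate(trace, disc_config)
                c[row], _ = bin_events(det.event_times_us, scan.dwell_us, scan.nx)
        analog += a
        counted += c
        truth += t
        n_total += n_ev

    f = scan.frames
    return ScanResult(analog / f, counted / f, truth / f, scan, n_total)


def _pixel_means(samples, bounds):
    """Mean trace value per pixel window given cumulative sample bounds."""
    sums = np.add.reduceat(samples[: bounds[-1]], bounds[:-1])
    widths = np.diff(bounds)
    return sums / np.maximum(widths, 1)


def _simulate_frame_continuous(specimen, base_rate, scan, kernel, disc_config,
                               noise_sigma, baseline, rng, height_cv,
                               flyback_time_us, bounds):
    """One frame as a single timeline (afterglow persists through flyback)."""
    dt_us = kernel.sample_period * 1e-3
    row_dur = scan.row_duration_us
    period = row_dur + flyback_time_us
    all_times, all_heights = [], []
    truth = np.zeros((scan.ny, scan.nx))
    for row in range(scan.ny):
        rates = base_rate * specimen.values[row]
        times, heights, n_pix = _row_events(rates, scan.dwell_us, rng, height_cv)
        truth[row] = n_pix
        all_times.append(times + row * period)
        all_heights.append(heights)
    times = np.concatenate(all_times)
    heights = np.concatenate(all_heights)
    order = np.argsort(times, kind="stable")
    ev = EventStream.monolithic(times[order], heights[order])
    duration = scan.ny * period
    trace = synthesize_trace(ev, kernel, noise_sigma=noise_sigma,
                             baseline=baseline, duration=duration, rng_seed=rng)
    row_samples = int(round(period / dt_us))
    analog = np.zeros((scan.ny, scan.nx))
    counted = np.zeros((scan.ny, scan.nx))
    det = discriminate(trace, disc_config)
    det_t = det.event_times_us
    for row in range(scan.ny):
        seg = trace.samples[row * row_samples : (row + 1) * row_samples]
        analog[row] = _pixel_means(seg, bounds)
        in_row = det_t[(det_t >= row * period) & (det_t < row * period + row_dur)]
        counted[row], _ = bin_events(in_row - row * period, scan.dwell_us, scan.nx)
    return analog, counted, truth, len(ev)


def directional_spectrum_ratio(image) -> float:
    """Fast-axis vs slow-axis high-frequency power ratio.

    Row-wise 1-D periodograms along the fast axis (x) are averaged and the
    mean power in the top quartile of frequencies is compared with the
    same quantity along the slow axis (y). 1 = isotropic; < 1 means high
    frequencies are suppressed along the fast axis (temporal streaking).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 16:
        raise InvalidParameterError("image must be 2-D and >= 16x16")
    img = img - img.mean()
    if np.ptp(img) == 0:
        raise UndefinedRatioError("constant image: spectrum ratio undefined")

    def band_power(a, axis):
        p = np.abs(np.fft.rfft(a, axis=axis)) ** 2
        nf = p.shape[axis]
        sl = [slice(None)] * 2
        sl[axis] = slice(3 * nf // 4, nf)  # top-quartile frequency band
        return float(np.mean(p[tuple(sl)]))

    fast = band_power(img, axis=1)
    slow = band_power(img, axis=0)
    if slow == 0:
        raise UndefinedRatioError("no slow-axis power in band")
    return fast / slow


def edge_tail_length(image, edge_col: int, baseline: float = 0.0, frac: float = 0.1) -> int:
    """Length in pixels of the decaying tail past a step edge.

    The mean fast-axis profile is taken; the tail length is the number of
    consecutive pixels at or after ``edge_col`` whose excess over
    *baseline* stays above ``frac`` of the step amplitude.
    """
    img = np.asarray(image, dtype=float)
    prof = img.mean(axis=0) - baseline
    step = float(np.mean(prof[: edge_col]))
    if step <= 0:
        raise InvalidParameterError("no step amplitude before the edge")
    n = 0
    for v in prof[edge_col:]:
        if v > frac * step:
            n += 1
        else:
            break
    return n
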