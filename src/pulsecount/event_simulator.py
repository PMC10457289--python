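"""Ground-truth electron event generation and analog trace synthesis.

Electron arrivals at a STEM detector are a Poisson process in time whose
rate is proportional to beam current; each impact deposits a pulse whose
amplitude varies (scintillation statistics) and which lands somewhere on
the detector — for a segmented detector, on one of its segments. This
module draws such event streams, distributes them over a segment geometry
using a radial scattering profile (uniform in azimuth, Rutherford-like
``r^-3`` fall-off in scattering angle by default), and synthesizes the
uniformly sampled, optionally ADC-quantized voltage trace that the
discriminator sees: baseline + Σ height·kernel(t - t_event) + noise.

Event times are continuous; pulses are placed starting at the first ADC
sample instant at or after the arrival, mimicking a clocked converter
(sub-sample phase is below the 8 ns resolution of the emulated hardware).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._rng import substream
from .detector_response import PulseKernel
from .errors import InvalidParameterError, OutOfRangeError

__all__ = [
    "EventStream",
    "DetectorGeometry",
    "RadialProfile",
    "AnalogTrace",
    "full_annulus",
    "quadrant_ring_geometry",
    "sample_poisson_events",
    "sample_heights",
    "assign_segments",
    "synthesize_trace",
    "synthesize_segment_traces",
    "quantize_adc",
]


@dataclass(frozen=True)
class EventStream:
    """Ground-truth electron arrivals.

    ``times`` (µs, ascending), ``heights`` (unitless pulse amplitudes > 0)
    and ``segment_ids`` (index into a :class:`DetectorGeometry`, or -1 for
    monolithic / lost events) all have equal length.
    """

    times: np.ndarray
    heights: np.ndarray
    segment_ids: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        s = np.asarray(self.segment_ids, dtype=int)
        if not (len(t) == len(h) == len(s)):
            raise InvalidParameterError("times/heights/segment_ids length mismatch")
        if len(t) and (np.any(np.diff(t) < 0) or t[0] < 0):
            raise InvalidParameterError("times must be sorted ascending and >= 0")
        if np.any(h <= 0):
            raise InvalidParameterError("heights must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "segment_ids", s)

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def monolithic(cls, times, heights) -> "EventStream":
        times = np.asarray(times, dtype=float)
        return cls(times, heights, np.full(len(times), -1, dtype=int))

    def select_segment(self, segment_id: int) -> "EventStream":
        """Events landing on one segment (their own sub-stream)."""
        m = self.segment_ids == segment_id
        return EventStream(self.times[m], self.heights[m], self.segment_ids[m])


@dataclass(frozen=True)
class DetectorGeometry:
    """Annular-segment detector layout.

    Each segment is ``(inner_radius, outer_radius, azimuth_start_deg,
    azimuth_end_deg)`` in consistent radial units (interpreted as
    scattering angle, mrad). Azimuth spans may wrap through 360°; segments
    must not overlap, but the union need not cover the annulus.
    """

    segments: tuple

    def __post_init__(self):
        segs = tuple(tuple(float(x) for x in s) for s in self.segments)
        if not segs:
            raise InvalidParameterError("geometry needs >= 1 segment")
        for r0, r1, a0, a1 in segs:
            if not (0 <= r0 < r1):
                raise InvalidParameterError(f"need 0 <= inner < outer, got {r0}, {r1}")
            span = (a1 - a0) % 360.0 or 360.0
            if not (0 < span <= 360.0):
                raise InvalidParameterError("azimuth span must be in (0, 360]")
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                if self._overlap(segs[i], segs[j]):
                    raise InvalidParameterError(f"segments {i} and {j} overlap")
        object.__setattr__(self, "segments", segs)

    @staticmethod
    def _overlap(a, b) -> bool:
        r_ov = min(a[1], b[1]) - max(a[0], b[0])
        if r_ov <= 0:
            return False

        def arcs(a0, a1):
            a0m, a1m = a0 % 360.0, a1 % 360.0
            if a1m <= a0m:
                return [(a0m, 360.0), (0.0, a1m)] if a1m > 0 else [(a0m, 360.0)]
            return [(a0m, a1m)]

        for s0, s1 in arcs(a[2], a[3]):
            for t0, t1 in arcs(b[2], b[3]):
                if min(s1, t1) - max(s0, t0) > 1e-12:
                    return True
        return False

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def radial_span(self) -> tuple[float, float]:
        return (
            min(s[0] for s in self.segments),
            max(s[1] for s in self.segments),
        )

    def locate(self, radius: float, azimuth_deg: float) -> int:
        """Segment index containing (radius, azimuth), or -1 if none."""
        az = azimuth_deg % 360.0
        for i, (r0, r1, a0, a1) in enumerate(self.segments):
            if not (r0 <= radius < r1):
                continue
            a0m, a1m = a0 % 360.0, a1 % 360.0
            if a0m == a1m:  # full circle
                return i
            if a0m < a1m:
                if a0m <= az < a1m:
                    return i
            elif az >= a0m or az < a1m:  # wraps through 360
                return i
        return -1


def full_annulus(inner: float, outer: float) -> DetectorGeometry:
    """Single unsegmented annular detector."""
    return DetectorGeometry(((inner, outer, 0.0, 360.0),))


def quadrant_ring_geometry(
    radii: tuple[float, ...] = (25.0, 60.0, 110.0, 180.0),
) -> DetectorGeometry:
    """Four inner quadrants plus two outer rings (six segments).

    The inner annulus, which receives most of the Rutherford-scattered
    dose, is split azimuthally into quadrants; the two outer annuli stay
    whole. ``radii`` are the three annulus boundaries (mrad), innermost
    first.
    """
    r0, r1, r2, r3 = radii
    segs = [(r0, r1, 90.0 * q, 90.0 * (q + 1)) for q in range(4)]
    segs += [(r1, r2, 0.0, 360.0), (r2, r3, 0.0, 360.0)]
    return DetectorGeometry(tuple(segs))


@dataclass(frozen=True)
class RadialProfile:
    """Piecewise-linear radial weighting of electron dose vs scattering
    angle (mrad); weights need not be normalized."""

    radii: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if r.ndim != 1 or r.shape != w.shape or len(r) < 2:
            raise InvalidParameterError("radii/weights must be 1-D, same length >= 2")
        if np.any(np.diff(r) <= 0):
            raise InvalidParameterError("radii must be strictly ascending")
        if np.any(w < 0) or not np.any(w > 0):
            raise InvalidParameterError("weights must be >= 0 and not all zero")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "weights", w)

    @classmethod
    def power_law(
        cls, r_min: float, r_max: float, exponent: float = -3.0, n: int = 256
    ) -> "RadialProfile":
        """Rutherford-like ``r^exponent`` profile between two angles."""
        if not (0 < r_min < r_max):
            raise InvalidParameterError("need 0 < r_min < r_max")
        r = np.linspace(r_min, r_max, n)
        return cls(r, r**exponent)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw radii from the normalized piecewise-linear density."""
        r, w = self.radii, self.weights
        # trapezoid masses per knot interval
        dm = 0.5 * (w[1:] + w[:-1]) * np.diff(r)
        cdf = np.concatenate([[0.0], np.cumsum(dm)])
        total = cdf[-1]
        if total <= 0:
            raise InvalidParameterError("profile mass is zero")
        u = rng.uniform(0.0, total, size=n)
        idx = np.clip(np.searchsorted(cdf, u, side="right") - 1, 0, len(dm) - 1)
        # invert the linear-density CDF within each interval (quadratic)
        u0 = u - cdf[idx]
        w0, w1 = w[idx], w[idx + 1]
        dr = r[idx + 1] - r[idx]
        slope = (w1 - w0) / dr
        out = np.empty(n)
        lin = np.abs(slope) < 1e-30 * np.maximum(w0, 1.0)
        out[lin] = u0[lin] / np.where(w0[lin] > 0, w0[lin], 1.0)
        nl = ~lin
        disc = w0[nl] ** 2 + 2.0 * slope[nl] * u0[nl]
        out[nl] = (np.sqrt(np.maximum(disc, 0.0)) - w0[nl]) / slope[nl]
        return r[idx] + np.clip(out, 0.0, dr)


@dataclass(frozen=True)
class AnalogTrace:
    """Uniformly sampled detector signal.

    ``sample_period`` in ns; ``samples`` in signal units, or integer ADC
    codes in ``[0, 2**adc_bits - 1]`` after :func:`quantize_adc` (then
    ``adc_range`` records the full-scale signal value).
    """

    sample_period: float
    samples: np.ndarray
    baseline: float = 0.0
    adc_bits: int | None = None
    adc_range: float | None = None

    def __post_init__(self):
        if self.sample_period <= 0:
            raise InvalidParameterError("sample_period must be > 0")
        s = np.asarray(self.samples)
        if self.adc_bits is not None:
            if self.adc_bits < 1 or self.adc_range is None or self.adc_range <= 0:
                raise InvalidParameterError("quantized trace needs bits>=1, range>0")
            if not np.issubdtype(s.dtype, np.integer):
                raise InvalidParameterError("quantized samples must be integers")
            if s.size and (s.min() < 0 or s.max() > 2**self.adc_bits - 1):
                raise InvalidParameterError("ADC codes out of range")
        else:
            s = np.asarray(s, dtype=float)
        object.__setattr__(self, "samples", s)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_us(self) -> float:
        return len(self.samples) * self.sample_period * 1e-3

    @property
    def times_us(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.sample_period * 1e-3

    @property
    def is_quantized(self) -> bool:
        return self.adc_bits is not None


def sample_poisson_events(
    rate: float, duration: float, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Draw Poisson-process arrival times (µs) on ``[0, duration)``.

    The event count is Poisson(rate·duration); given the count, times are
    i.i.d. uniform, returned sorted. Deterministic per seed.
    """
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else substream(rng_seed, "poisson")
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def sample_heights(
    n: int, mean: float = 1.0, cv: float = 0.15, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Pulse heights from a zero-truncated Gaussian with given mean and
    coefficient of variation (cv=0 gives a constant sequence)."""
    if cv < 0:
        raise InvalidParameterError("cv must be >= 0")
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    if cv == 0:
        return np.full(n, float(mean))
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else substream(rng_seed, "heights")
    out = rng.normal(mean, cv * mean, size=n)
    bad = out <= 0
    while np.any(bad):  # rejection resampling = truncation at zero
        out[bad] = rng.normal(mean, cv * mean, size=int(bad.sum()))
        bad = out <= 0
    return out


def assign_segments(
    times,
    geometry: DetectorGeometry,
    radial: RadialProfile,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Assign each event a detector segment.

    Radius is drawn from the normalized radial profile, azimuth uniformly
    on [0°, 360°); the id is the containing segment's index, or -1 (lost)
    when the impact point lies on no segment.
    """
    times = np.asarray(times, dtype=float)
    n = len(times)
    r_lo, r_hi = geometry.radial_span
    r, w = radial.radii, radial.weights
    span_w = np.interp(np.linspace(r_lo, r_hi, 64), r, w, left=0.0, right=0.0)
    if not np.any(span_w > 0):
        raise InvalidParameterError("radial profile is zero over the detector span")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else substream(rng_seed, "segments")
    radii = radial.sample(n, rng)
    azimuths = rng.uniform(0.0, 360.0, size=n)
    ids = np.fromiter(
        (geometry.locate(rr, aa) for rr, aa in zip(radii, azimuths)),
        dtype=int,
        count=n,
    )
    return ids


def synthesize_trace(
    events: EventStream,
    kernel: PulseKernel,
    noise_sigma: float = 0.0,
    baseline: float = 0.0,
    duration: float | None = None,
    sample_period: float | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> AnalogTrace:
    """Synthesize the analog trace produced by an event stream.

    ``samples = baseline + Σ height·kernel(t - t_event) + N(0, noise_sigma)``
    with each pulse starting at the first sample instant at or after its
    (continuous) arrival time. Superposition is exact and linear; pulses
    extending past the trace end are clipped.

    Parameters
    ----------
    duration : float
        Trace length in µs; must cover the last event time.
    sample_period : float, optional
        ns; defaults to the kernel's. Must match the kernel's.
    """
    if sample_period is None:
        sample_period = kernel.sample_period
    if sample_period != kernel.sample_period:
        raise InvalidParameterError(
            "trace sample_period must equal the kernel's (resample the kernel first)"
        )
    if duration is None:
        duration = float(events.times[-1]) + kernel.duration_ns * 1e-3 if len(events) else 1.0
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if len(events) and events.times[-1] > duration:
        raise OutOfRangeError(
            f"event at {events.times[-1]} us beyond trace duration {duration} us"
        )
    dt_us = sample_period * 1e-3
    n = int(round(duration / dt_us))
    out = np.zeros(n)
    klen = len(kernel.samples)
    starts = np.ceil(events.times / dt_us - 1e-9).astype(int)
    for i0, h in zip(starts, events.heights):
        if i0 >= n:
            continue
        i1 = min(i0 + klen, n)
        out[i0:i1] += h * kernel.samples[: i1 - i0]
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    if noise_sigma > 0:
        rng = rng_seed if isinstance(rng_seed, np.random.Generator) else substream(rng_seed, "noise")
        out += rng.normal(0.0, noise_sigma, size=n)
    out += baseline
    return AnalogTrace(sample_period=float(sample_period), samples=out, baseline=float(baseline))


def synthesize_segment_traces(
    events: EventStream,
    geometry: DetectorGeometry,
    kernel: PulseKernel,
    noise_sigma: float = 0.0,
    baseline: float = 0.0,
    duration: float | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> list[AnalogTrace]:
    """One independent trace per detector segment (segments are separate
    electronic channels); noise is drawn independently per channel."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else substream(rng_seed, "segtraces")
    return [
        synthesize_trace(
            events.select_segment(i),
            kernel,
            noise_sigma=noise_sigma,
            baseline=baseline,
            duration=duration,
            rng_seed=rng,
        )
        for i in range(geometry.n_segments)
    ]


def quantize_adc(trace: AnalogTrace, bits: int = 14, adc_range: float | None = None) -> AnalogTrace:
    """Quantize a trace to an ideal ``bits``-bit ADC over ``[0, adc_range]``.

    Samples are clipped to the range, scaled to ``[0, 2**bits - 1]`` and
    rounded half-to-even.
    """
    if bits < 1:
        raise InvalidParameterError("bits must be >= 1")
    if adc_range is None:
        adc_range = float(np.max(trace.samples)) if len(trace) else 1.0
    if adc_range <= 0:
        raise InvalidParameterError("adc_range must be > 0")
    full_scale = 2**bits - 1
    codes = np.rint(np.clip(trace.samples, 0.0, adc_range) / adc_range * full_scale)
    dtype = np.uint16 if bits <= 16 else np.int64
    return replace(
        trace,
        samples=codes.astype(dtype),
        adc_bits=int(bits),
        adc_range=float(adc_range),
    )
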