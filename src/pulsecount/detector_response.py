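"""Parametric single-electron detector pulse models and decay fitting.

Scintillator-based STEM detectors answer a single electron impact with a
pulse that rises sharply (~100 ns) and decays roughly exponentially
(~0.4 µs time constant), sometimes followed by a much slower afterglow
component (~4.5 µs) attributed to charge trapping in the scintillator.
Solid-state detectors are an order of magnitude faster. This module
provides

* :func:`exponential_decay` — the decay law ``A·exp(-t/b) + c``,
* :func:`fit_exponential_decay` — damped least-squares estimation of
  ``(A, b, c)`` with standard errors from the local curvature,
* :func:`make_kernel` / :func:`make_afterglow_kernel` — unit-peak sampled
  pulse kernels used by the trace synthesizer,
* CSV exchange of sampled kernels.

The double-exponential pulse shape ``(1 - exp(-t/τ_r))·exp(-t/τ_f)`` is a
phenomenological choice: it has the right sharp-rise / exponential-fall
morphology, and its two time constants map directly onto measured rise and
fall times. Measured pulse responses can be loaded from CSV instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DataError,
    DegenerateInputError,
    FitError,
    FormatError,
    InvalidParameterError,
)

__all__ = [
    "DecayParams",
    "DecayFitResult",
    "PulseKernel",
    "exponential_decay",
    "fit_exponential_decay",
    "make_kernel",
    "make_afterglow_kernel",
    "SCINTILLATOR_RISE_NS",
    "SCINTILLATOR_FALL_US",
    "SOLID_STATE_RISE_NS",
    "SOLID_STATE_FALL_US",
    "AFTERGLOW_DECAY_US",
    "AFTERGLOW_FRACTION",
]

# Default pulse time constants (measured values for a typical scintillator
# ADF detector and a fast solid-state detector).
SCINTILLATOR_RISE_NS = 100.0
SCINTILLATOR_FALL_US = 0.413
SOLID_STATE_RISE_NS = 20.0
SOLID_STATE_FALL_US = 0.050
#: slow afterglow component of the scintillator response
AFTERGLOW_DECAY_US = 4.5
#: default amplitude fraction of the afterglow component (configurable; the
#: slow component is visible but much weaker than the primary pulse)
AFTERGLOW_FRACTION = 0.05

KERNEL_CSV_HEADER = "# pulsecount-kernel v1"


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the decay law ``A·exp(-t/b) + c``.

    Attributes
    ----------
    amplitude : float
        ``A``, in signal units. Any finite real.
    decay_time : float
        ``b``, the decay time in µs. Must be > 0.
    offset : float
        ``c``, the baseline offset in signal units.
    """

    amplitude: float
    decay_time: float
    offset: float

    def __post_init__(self):
        for name in ("amplitude", "decay_time", "offset"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        if self.decay_time <= 0:
            raise InvalidParameterError(
                f"decay_time must be > 0, got {self.decay_time}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.amplitude, self.decay_time, self.offset)


@dataclass(frozen=True)
class DecayFitResult:
    """Result of :func:`fit_exponential_decay`.

    ``stderr`` entries are per-parameter standard errors derived from the
    curvature (Jacobian-based covariance) of the least-squares objective at
    the optimum, in the order (amplitude, decay_time, offset).
    """

    params: DecayParams
    stderr: tuple[float, float, float]
    cov: np.ndarray = field(repr=False)
    n_obs: int = 0

    def summary(self) -> str:
        a, b, c = self.params.as_tuple()
        sa, sb, sc = self.stderr
        return (
            "Exponential decay fit  A*exp(-t/b) + c\n"
            f"  n = {self.n_obs}\n"
            f"  A = {a:.6g} +/- {sa:.2g}\n"
            f"  b = {b:.6g} us +/- {sb:.2g}\n"
            f"  c = {c:.6g} +/- {sc:.2g}"
        )


def exponential_decay(t, params: DecayParams):
    """Evaluate ``A·exp(-t/b) + c`` at time(s) *t* (µs).

    Parameters are validated by :class:`DecayParams`; *t* may be scalar or
    array-like with ``t >= 0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    a, b, c = params.as_tuple()
    out = a * np.exp(-t / b) + c
    return float(out) if out.ndim == 0 else out


def _initial_guess(times: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """Log-linear regression on the baseline-subtracted tail."""
    # baseline from the last decile of samples (closest to the asymptote)
    n_tail = max(1, len(values) // 10)
    c0 = float(np.mean(values[-n_tail:]))
    y = values - c0
    sign = 1.0 if y[0] >= 0 else -1.0
    y = sign * y
    keep = y > max(y.max(), 0) * 1e-2
    if keep.sum() >= 2 and y.max() > 0:
        slope, intercept = np.polyfit(times[keep], np.log(y[keep]), 1)
        if slope < 0:
            return (sign * float(np.exp(intercept)), -1.0 / slope, c0)
    # fallback: crude scales from the data span
    span = float(times[-1] - times[0])
    return (sign * float(np.ptp(values)), span / 3.0, c0)


def fit_exponential_decay(
    times,
    values,
    initial_guess: DecayParams | None = None,
) -> DecayFitResult:
    """Least-squares fit of ``A·exp(-t/b) + c`` to (times, values).

    Parameters
    ----------
    times : array-like
        Sample times in µs, strictly increasing, length >= 4.
    values : array-like
        Signal values, same length as *times*, not all equal.
    initial_guess : DecayParams, optional
        Starting point; when omitted it is derived from a log-linear
        regression on the baseline-subtracted tail.

    Returns
    -------
    DecayFitResult
        Fitted :class:`DecayParams` (``decay_time`` > 0 guaranteed) plus
        per-parameter standard errors from the Jacobian-based covariance.

    Raises
    ------
    DegenerateInputError
        Fewer than 4 samples, non-increasing times, or constant values
        (the decay time is then unidentifiable).
    FitError
        Optimizer did not converge; carries the last iterate in
        ``last_params``.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise InvalidParameterError("times and values must be 1-D and same length")
    if len(t) < 4:
        raise DegenerateInputError("need at least 4 samples to fit 3 parameters")
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("times must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise DataError("times/values contain non-finite entries")
    if np.ptp(v) == 0:
        raise DegenerateInputError("values are all equal; decay time unidentifiable")

    if initial_guess is not None:
        p0 = initial_guess.as_tuple()
    else:
        p0 = _initial_guess(t, v)

    def model(tt, a, b, c):
        return a * np.exp(-tt / b) + c

    popt = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:  # plain Levenberg-Marquardt first
            popt, pcov = curve_fit(model, t, v, p0=p0, maxfev=20000)
        except RuntimeError:
            popt = None
        if popt is None or popt[1] <= 0:
            # damped least squares with b constrained positive
            try:
                popt, pcov = curve_fit(
                    model,
                    t,
                    v,
                    p0=(p0[0], abs(p0[1]) or 1.0, p0[2]),
                    bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError) as exc:
                raise FitError(
                    f"decay fit did not converge: {exc}",
                    last_params=tuple(popt) if popt is not None else tuple(p0),
                ) from exc

    stderr = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
    params = DecayParams(float(popt[0]), float(popt[1]), float(popt[2]))
    return DecayFitResult(params=params, stderr=stderr, cov=pcov, n_obs=len(t))


@dataclass(frozen=True)
class PulseKernel:
    """Sampled unit-peak single-electron pulse response.

    Invariants (enforced): peak value exactly 1; first sample 0 (pulse
    starts at baseline); finite; trailing sample below ``1e-3`` of peak.
    Event height multiplies the kernel during trace synthesis, so the unit
    peak makes 'height' directly the pulse amplitude.

    Attributes
    ----------
    sample_period : float
        Sampling interval in ns.
    samples : numpy.ndarray
        Kernel amplitudes on the uniform grid ``t = k * sample_period``.
    kind : str
        ``"scintillator"``, ``"solid_state"`` or ``"custom"``.
    """

    sample_period: float
    samples: np.ndarray
    kind: str = "custom"
    _TAIL_CUTOFF = 1e-3

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if self.sample_period <= 0:
            raise InvalidParameterError("sample_period must be > 0")
        if s.ndim != 1 or len(s) < 2:
            raise InvalidParameterError("kernel needs >= 2 samples")
        if not np.all(np.isfinite(s)):
            raise InvalidParameterError("kernel samples must be finite")
        if s[0] != 0:
            raise InvalidParameterError("kernel must start at baseline (first sample 0)")
        if not np.isclose(s.max(), 1.0, rtol=0, atol=1e-12):
            raise InvalidParameterError("kernel peak must be exactly 1")
        if abs(s[-1]) >= self._TAIL_CUTOFF:
            raise InvalidParameterError(
                "kernel not truncated: trailing sample must be < 1e-3 of peak"
            )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.sample_period

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.samples))

    @property
    def duration_ns(self) -> float:
        return len(self.samples) * self.sample_period

    @classmethod
    def from_samples(cls, sample_period, samples, kind="custom") -> "PulseKernel":
        """Build a kernel from raw samples, normalizing the peak to 1 and
        truncating the tail below the cutoff."""
        s = np.asarray(samples, dtype=float)
        if len(s) < 2 or not np.all(np.isfinite(s)):
            raise InvalidParameterError("need >= 2 finite samples")
        peak = s.max()
        if peak <= 0:
            raise InvalidParameterError("kernel peak must be positive")
        s = s / peak
        p = int(np.argmax(s))
        below = np.nonzero(s[p:] < cls._TAIL_CUTOFF)[0]
        if below.size:
            s = s[: p + below[0] + 1]
        return cls(sample_period=float(sample_period), samples=s, kind=kind)

    def to_csv(self, path) -> None:
        """Write the two-column exchange format (time_ns, amplitude)."""
        with open(path, "w") as fh:
            fh.write(KERNEL_CSV_HEADER + "\n")
            fh.write("time_ns,amplitude\n")
            for t, a in zip(self.times_ns, self.samples):
                fh.write(f"{t:.6f},{a:.9g}\n")

    @classmethod
    def from_csv(cls, path) -> "PulseKernel":
        """Read a kernel from the exchange format; re-normalizes the peak."""
        with open(path) as fh:
            first = fh.readline().strip()
            if first != KERNEL_CSV_HEADER:
                raise FormatError(
                    f"missing kernel header {KERNEL_CSV_HEADER!r} in {path}"
                )
            data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
        if data.size == 0:
            raise DataError(f"empty kernel file {path}")
        t, a = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise DataError("kernel time axis must be uniform")
        return cls.from_samples(sample_period=float(dt[0]), samples=a)


def _double_exp(t_ns, tau_r_ns, tau_f_ns):
    return (1.0 - np.exp(-t_ns / tau_r_ns)) * np.exp(-t_ns / tau_f_ns)


def make_kernel(
    rise_time: float | None = None,
    fall_time: float | None = None,
    sample_period: float = 8.0,
    kind: str = "scintillator",
    tail_cutoff: float = 1e-3,
) -> PulseKernel:
    """Construct a double-exponential pulse kernel.

    The shape is ``s(t) = (1 - exp(-t/τ_r)) · exp(-t/τ_f)``, sampled at
    ``sample_period`` (ns), unit-peak normalized and truncated once the tail
    falls below ``tail_cutoff`` of the peak.

    Parameters
    ----------
    rise_time : float, optional
        τ_r in ns. Defaults per *kind*: scintillator 100 ns, solid_state 20 ns.
    fall_time : float, optional
        τ_f in µs. Defaults per *kind*: scintillator 0.413 µs, solid_state
        0.050 µs.
    sample_period : float
        ADC sampling period in ns (default 8 ns, a 125 MHz clock).
    kind : str
        Kernel family label; selects the defaults above.
    """
    if rise_time is None:
        rise_time = SOLID_STATE_RISE_NS if kind == "solid_state" else SCINTILLATOR_RISE_NS
    if fall_time is None:
        fall_time = SOLID_STATE_FALL_US if kind == "solid_state" else SCINTILLATOR_FALL_US
    if rise_time <= 0 or fall_time <= 0 or sample_period <= 0:
        raise InvalidParameterError("rise_time, fall_time, sample_period must be > 0")
    if not (0 < tail_cutoff < 1):
        raise InvalidParameterError("tail_cutoff must be in (0, 1)")

    tau_r = float(rise_time)
    tau_f = float(fall_time) * 1e3  # µs -> ns
    # analytic peak time of the double exponential
    t_peak = tau_r * np.log1p(tau_f / tau_r)
    s_peak = _double_exp(t_peak, tau_r, tau_f)
    # tail drops as exp(-t/τ_f); generous analytic bound for the end time
    t_end = t_peak + tau_f * (np.log(1.0 / tail_cutoff) + 1.0)
    if sample_period >= t_end:
        raise InvalidParameterError(
            f"sample_period {sample_period} ns >= kernel duration {t_end:.3g} ns"
        )
    t = np.arange(0.0, t_end + sample_period, sample_period)
    s = _double_exp(t, tau_r, tau_f) / s_peak
    p = int(np.argmax(s))
    below = np.nonzero(s[p:] < tail_cutoff)[0]
    s = s[: p + below[0] + 1] if below.size else s
    s = s / s.max()  # peak exactly 1 on the sampled grid
    s[0] = 0.0
    return PulseKernel(sample_period=float(sample_period), samples=s, kind=kind)


def make_afterglow_kernel(
    fast: PulseKernel,
    slow_decay_time: float = AFTERGLOW_DECAY_US,
    slow_fraction: float = AFTERGLOW_FRACTION,
    tail_cutoff: float = 1e-3,
) -> PulseKernel:
    """Add a slow afterglow tail to a fast pulse kernel.

    The result is the mixture ``(1 - f)·fast + f·slow`` where the slow
    component shares the fast kernel's rising edge and decays from the peak
    with time constant *slow_decay_time* (µs). ``f = slow_fraction`` is the
    amplitude fraction of the afterglow; the mixture keeps a unit peak.
    """
    if not (0 <= slow_fraction < 1):
        raise InvalidParameterError("slow_fraction must be in [0, 1)")
    if slow_decay_time <= 0:
        raise InvalidParameterError("slow_decay_time must be > 0")
    if slow_fraction == 0:
        return PulseKernel(fast.sample_period, fast.samples.copy(), kind=fast.kind)

    dt = fast.sample_period
    tau_s = slow_decay_time * 1e3  # ns
    p = fast.peak_index
    # slow tail must decay to tail_cutoff/f of its peak before truncation
    n_tail = int(np.ceil(tau_s * np.log(slow_fraction / tail_cutoff) / dt)) + 1
    n = max(len(fast), p + 1 + max(n_tail, 1))
    fast_ext = np.zeros(n)
    fast_ext[: len(fast)] = fast.samples
    slow = np.zeros(n)
    slow[: p + 1] = fast.samples[: p + 1]  # shared rising edge
    k = np.arange(1, n - p)
    slow[p + 1 :] = np.exp(-k * dt / tau_s)
    mix = (1.0 - slow_fraction) * fast_ext + slow_fraction * slow
    pm = int(np.argmax(mix))
    below = np.nonzero(mix[pm:] < tail_cutoff)[0]
    if below.size:
        mix = mix[: pm + below[0] + 1]
    mix = mix / mix.max()
    return PulseKernel(sample_period=dt, samples=mix, kind=fast.kind)
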