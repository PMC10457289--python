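"""Readers, writers and run configuration.

On-disk dialects (all plain text or raw binary + JSON sidecar):

* traces — two-column CSV (``time_ns,value``) with a commented metadata
  header, or raw little-endian float32/uint16 with a ``.json`` sidecar
  carrying ``sample_period_ns``, ``baseline``, ``adc_bits``, ``adc_range``;
* event lists — CSV ``time_us,height,segment_id``;
* kernels — the two-column exchange CSV handled by
  :class:`~pulsecount.detector_response.PulseKernel`;
* images — TIFF via :mod:`tifffile`;
* run configuration — YAML mirroring every module's parameter names, with
  unknown keys rejected; every run writes its resolved config + seed next
  to its outputs so any result can be reproduced bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import DataError, FormatError, InvalidParameterError
from .event_simulator import AnalogTrace, EventStream

__all__ = [
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "load_config",
    "dump_config",
    "CONFIG_SCHEMA",
]

TRACE_CSV_HEADER = "# pulsecount-trace v1"


def write_trace(trace: AnalogTrace, path, format: str | None = None) -> None:
    """Write a trace as CSV (default for ``.csv``) or raw binary + JSON
    sidecar (any other extension)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "bin"
    meta = {
        "sample_period_ns": trace.sample_period,
        "baseline": trace.baseline,
        "adc_bits": trace.adc_bits,
        "adc_range": trace.adc_range,
        "n_samples": len(trace),
    }
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(TRACE_CSV_HEADER + "\n")
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            fh.write("time_ns,value\n")
            fmt = "%d" if trace.is_quantized else "%.9g"
            for i, v in enumerate(trace.samples):
                fh.write(f"{i * trace.sample_period:.6f},{fmt % v}\n")
    elif format == "bin":
        dtype = "<u2" if trace.is_quantized else "<f4"
        trace.samples.astype(dtype).tofile(path)
        meta["dtype"] = dtype
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(meta, fh, indent=2)
    else:
        raise InvalidParameterError(f"unknown trace format {format!r}")


def _parse_meta(val: str):
    if val == "None":
        return None
    try:
        f = float(val)
        return int(f) if f == int(f) and "." not in val else f
    except ValueError:
        return val


def read_trace(path, format: str | None = None) -> AnalogTrace:
    """Read a trace written by :func:`write_trace` (lossless round trip)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "bin"
    if format == "csv":
        meta = {}
        rows = []
        with open(path) as fh:
            first = fh.readline().strip()
            if first != TRACE_CSV_HEADER:
                raise FormatError(f"missing trace header in {path}")
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    k, _, v = line[1:].strip().partition("=")
                    meta[k.strip()] = _parse_meta(v.strip())
                elif line and not line.startswith("time_ns"):
                    rows.append(line.split(","))
        if not rows:
            raise DataError(f"trace file {path} has a header but no samples")
        samples = np.array([float(r[1]) for r in rows])
    elif format == "bin":
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FormatError(f"missing JSON sidecar {sidecar} for binary trace")
        with open(sidecar) as fh:
            meta = json.load(fh)
        samples = np.fromfile(path, dtype=meta.get("dtype", "<f4")).astype(
            np.uint16 if meta.get("adc_bits") else float)
    else:
        raise InvalidParameterError(f"unknown trace format {format!r}")

    if np.any(~np.isfinite(np.asarray(samples, dtype=float))):
        raise DataError(f"trace {path} contains non-finite samples")
    bits = meta.get("adc_bits")
    if bits:
        samples = np.asarray(samples).astype(np.uint16)
        if samples.size and samples.max() > 2**int(bits) - 1:
            raise DataError(
                f"sample {samples.max()} exceeds {bits}-bit ADC range")
    return AnalogTrace(
        sample_period=float(meta.get("sample_period_ns", 8.0)),
        samples=samples,
        baseline=float(meta.get("baseline") or 0.0),
        adc_bits=int(bits) if bits else None,
        adc_range=float(meta["adc_range"]) if meta.get("adc_range") else None,
    )


def write_events(events: EventStream, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_us,height,segment_id\n")
        for t, h, s in zip(events.times, events.heights, events.segment_ids):
            fh.write(f"{t:.9g},{h:.9g},{s}\n")


def read_events(path) -> EventStream:
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "time_us,height,segment_id":
            raise FormatError(f"unexpected event CSV header in {path}: {header!r}")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.size == 0:
        return EventStream(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    return EventStream(data[:, 0], data[:, 1], data[:, 2].astype(int))


# Allowed configuration keys per section (None = scalar leaf).
CONFIG_SCHEMA = {
    "seed": None,
    "output_dir": None,
    "kernel": {
        "kind": None, "rise_time_ns": None, "fall_time_us": None,
        "sample_period_ns": None, "afterglow_fraction": None,
        "afterglow_decay_us": None, "csv_path": None,
    },
    "events": {
        "rate": None, "duration_us": None, "height_cv": None,
        "radial_exponent": None,
    },
    "trace": {"noise_sigma": None, "baseline": None, "adc_bits": None,
              "adc_range": None},
    "discriminator": {
        "mode": None, "threshold": None, "gradient_lag": None,
        "min_consecutive_above": None, "min_consecutive_below": None,
        "dead_time": None, "output_pulse_width": None, "hysteresis": None,
        "record_at": None,
    },
    "scan": {"nx": None, "ny": None, "dwell_ns": None, "frames": None,
             "base_rate": None, "specimen": None, "edge_col": None},
    "efficiency": {"rates": None, "n_reps": None, "duration_us": None,
                   "modes": None, "segmentations": None, "kernels": None},
    "qc": {"robust": None, "detrend": None},
    "fit": {"t_min_us": None, "t_max_us": None},
}


def _validate(cfg: dict, schema: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in schema:
            raise FormatError(f"unknown config key {path + key!r}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(val, dict):
                raise FormatError(f"config section {path + key!r} must be a mapping")
            _validate(val, sub, path + key + ".")


def load_config(path) -> dict:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config root must be a mapping")
    _validate(cfg, CONFIG_SCHEMA)
    return cfg


def dump_config(cfg: dict, path) -> None:
    """Write the resolved configuration (+ seed) next to run outputs."""
    _validate(cfg, CONFIG_SCHEMA)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
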