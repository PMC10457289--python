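"""Detector-map uniformity metrics.

Scanning the focused beam across the detector surface ("detector
mapping") images the detector's own sensitivity. Counted maps make the
classic uniformity metrics directly comparable across detectors:

* **ellipticity** — major/minor diameter ratio of the inner opening;
* **flatness** — radial uniformity of the azimuthally averaged sensitivity;
* **roundness** — azimuthal uniformity of the radially averaged sensitivity;
* **smoothness** — pixel-level dispersion of sensitivity.

The scalar scores are RMS fractional deviations from the normalized
active-region mean (lower is better); they are scale-invariant because
the map is first normalized so background → 0 and active mean → 1.

The active region is thresholded at the midpoint of the map intensities
and need not be contiguous. Flatness averages over *active* pixels per
radial bin (so azimuthal defects do not masquerade as radial ones) and is
evaluated only where the azimuthal coverage of the active mask is at
least 90%; roundness averages over all pixels of that valid radial
annulus so azimuthal defects (gaps, dead wedges) register fully.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._rng import substream
from .errors import (
    DegenerateInputError,
    InsufficientAnnulusError,
    InvalidParameterError,
    NoHoleError,
)
from .event_simulator import DetectorGeometry

__all__ = [
    "DetectorMap",
    "EllipseFit",
    "ProfileResult",
    "DetectorQCReport",
    "active_region_mask",
    "normalize_map",
    "ellipticity",
    "flatness",
    "roundness",
    "smoothness",
    "qc_report",
    "synth_detector_map",
]

#: minimum azimuthal coverage of the active mask for a radial bin to count
COVERAGE_LEVEL = 0.9


@dataclass(frozen=True)
class DetectorMap:
    """2-D detector sensitivity image (arbitrary units, isotropic pixels)."""

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidParameterError("detector map must be 2-D")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("detector map must be finite")
        object.__setattr__(self, "values", v)

    @property
    def shape(self):
        return self.values.shape


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, DetectorMap) else np.asarray(m, dtype=float)


def active_region_mask(detector_map, robust: bool = False) -> np.ndarray:
    """Binary active-region mask: pixels above the intensity midpoint.

    The midpoint is ``(min + max) / 2`` over the whole image, or the
    midpoint of the 1st/99th percentiles with ``robust=True`` (guards
    against isolated hot pixels). The mask may be discontinuous.
    """
    v = _values(detector_map)
    lo, hi = (np.percentile(v, [1, 99]) if robust else (v.min(), v.max()))
    if hi == lo:
        raise DegenerateInputError("constant map: no active region definable")
    return v > (lo + hi) / 2.0


def normalize_map(detector_map, mask: np.ndarray) -> np.ndarray:
    """Normalize so the background averages 0 and the active region 1.

    ``out = (map - bg) / (active_mean - bg)`` with ``bg`` the mean over
    the mask complement. Idempotent on already-normalized maps.
    """
    v = _values(detector_map)
    if mask.shape != v.shape:
        raise InvalidParameterError("mask shape mismatch")
    bg = float(v[~mask].mean()) if np.any(~mask) else 0.0
    active_mean = float(v[mask].mean())
    if active_mean == bg:
        raise DegenerateInputError("active mean equals background; cannot normalize")
    return (v - bg) / (active_mean - bg)


@dataclass(frozen=True)
class EllipseFit:
    """Second-moment ellipse fit of the detector inner opening."""

    ratio: float
    major_diameter: float
    minor_diameter: float
    center: tuple[float, float]  # (row, col)
    angle_deg: float


def ellipticity(mask: np.ndarray) -> EllipseFit:
    """Fit the enclosed inner opening of an annular detector mask.

    The hole is the set of background pixels fully enclosed by the active
    region. An ellipse is fitted by second-moment analysis of the hole
    pixels (for a filled ellipse the diameter along a principal axis is
    4·sqrt(eigenvalue)); the ratio is major/minor >= 1.
    """
    mask = np.asarray(mask, dtype=bool)
    hole = ndimage.binary_fill_holes(mask) & ~mask
    if not np.any(hole):
        raise NoHoleError("mask has no enclosed inner opening")
    # largest connected hole (small spurious holes from noise are ignored)
    lab, n = ndimage.label(hole)
    if n > 1:
        sizes = ndimage.sum_labels(hole, lab, index=np.arange(1, n + 1))
        hole = lab == (1 + int(np.argmax(sizes)))
    rr, cc = np.nonzero(hole)
    center = (float(rr.mean()), float(cc.mean()))
    coords = np.stack([rr - center[0], cc - center[1]])
    cov = coords @ coords.T / len(rr)
    evals, evecs = np.linalg.eigh(cov)
    minor, major = 4.0 * np.sqrt(np.maximum(evals, 1e-30))
    vmaj = evecs[:, 1]
    angle = float(np.degrees(np.arctan2(vmaj[0], vmaj[1])) % 180.0)
    return EllipseFit(
        ratio=float(major / minor),
        major_diameter=float(major),
        minor_diameter=float(minor),
        center=center,
        angle_deg=angle,
    )


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    rr, cc = np.nonzero(mask)
    if len(rr) == 0:
        raise DegenerateInputError("empty mask")
    return (float(rr.mean()), float(cc.mean()))


@dataclass(frozen=True)
class ProfileResult:
    """A 1-D uniformity profile (radial or azimuthal) and its RMS score."""

    coords: np.ndarray  # bin centers: radius (px) or azimuth (deg)
    profile: np.ndarray
    score: float


def _polar(shape, center):
    yy, xx = np.indices(shape)
    dy, dx = yy - center[0], xx - center[1]
    return np.hypot(dy, dx), np.degrees(np.arctan2(dy, dx)) % 360.0


def _valid_radial_bins(mask, center, bin_width=1.0):
    """Radial bins (1 px wide) whose azimuthal mask coverage >= 90%."""
    r, _ = _polar(mask.shape, center)
    n_bins = int(np.ceil(r.max() / bin_width))
    idx = np.minimum((r / bin_width).astype(int), n_bins - 1)
    count_all = np.bincount(idx.ravel(), minlength=n_bins)
    count_act = np.bincount(idx.ravel(), weights=mask.ravel(), minlength=n_bins)
    coverage = np.divide(count_act, count_all, out=np.zeros(n_bins),
                         where=count_all > 0)
    valid = coverage >= COVERAGE_LEVEL
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return idx, valid, centers


def flatness(normalized, mask, center, bin_width: float = 1.0) -> ProfileResult:
    """Radial sensitivity profile (azimuthal mean over active pixels per
    1-pixel radial bin) and its RMS deviation from 1 over the valid range
    (bins with >= 90% azimuthal mask coverage)."""
    v = np.asarray(normalized, dtype=float)
    idx, valid, centers = _valid_radial_bins(mask, center, bin_width)
    if valid.sum() < 3:
        raise InsufficientAnnulusError(
            f"only {int(valid.sum())} radial bins reach "
            f"{COVERAGE_LEVEL:.0%} mask coverage"
        )
    n_bins = len(centers)
    w_act = np.bincount(idx[mask].ravel(), weights=v[mask].ravel(), minlength=n_bins)
    n_act = np.bincount(idx[mask].ravel(), minlength=n_bins)
    prof = np.divide(w_act, n_act, out=np.zeros(n_bins), where=n_act > 0)
    prof = prof[valid]
    score = float(np.sqrt(np.mean((prof - 1.0) ** 2)))
    return ProfileResult(coords=centers[valid], profile=prof, score=score)


def roundness(normalized, mask, center, n_bins: int = 360) -> ProfileResult:
    """Azimuthal sensitivity profile (radial mean per azimuthal bin over
    the valid radial annulus, all pixels) and its RMS deviation from 1."""
    v = np.asarray(normalized, dtype=float)
    r, phi = _polar(mask.shape, center)
    ridx, valid, centers = _valid_radial_bins(mask, center)
    if valid.sum() < 3:
        raise InsufficientAnnulusError("valid radial annulus too thin")
    in_annulus = valid[ridx]
    bidx = np.minimum((phi[in_annulus] / (360.0 / n_bins)).astype(int), n_bins - 1)
    w = np.bincount(bidx, weights=v[in_annulus], minlength=n_bins)
    n = np.bincount(bidx, minlength=n_bins)
    prof = np.divide(w, n, out=np.ones(n_bins), where=n > 0)
    score = float(np.sqrt(np.mean((prof - 1.0) ** 2)))
    az = (np.arange(n_bins) + 0.5) * (360.0 / n_bins)
    return ProfileResult(coords=az, profile=prof, score=score)


def smoothness(normalized, mask, detrend: bool = False, median_size: int = 5) -> float:
    """RMS deviation of active-region pixel sensitivities from 1.

    With ``detrend=True`` a median-filtered version of the map is
    subtracted first, isolating pixel-scale roughness from smooth radial
    or azimuthal trends.
    """
    v = np.asarray(normalized, dtype=float)
    if not np.any(mask):
        raise DegenerateInputError("empty mask")
    if detrend:
        trend = ndimage.median_filter(v, size=median_size)
        resid = (v - trend)[mask]
        return float(np.sqrt(np.mean(resid**2)))
    return float(np.sqrt(np.mean((v[mask] - 1.0) ** 2)))


@dataclass(frozen=True)
class DetectorQCReport:
    """The four uniformity metrics of one detector map."""

    ellipticity: float | None
    ellipse: EllipseFit | None
    flatness_profile: ProfileResult
    roundness_profile: ProfileResult
    flatness_score: float
    roundness_score: float
    smoothness_score: float
    active_mask: np.ndarray
    center: tuple[float, float]
    inner_active_radius: float
    outer_active_radius: float

    def to_dict(self) -> dict:
        return {
            "ellipticity": self.ellipticity,
            "flatness_score": self.flatness_score,
            "roundness_score": self.roundness_score,
            "smoothness_score": self.smoothness_score,
            "center": list(self.center),
            "inner_active_radius": self.inner_active_radius,
            "outer_active_radius": self.outer_active_radius,
            "flatness_profile": {
                "radius_px": self.flatness_profile.coords.tolist(),
                "sensitivity": self.flatness_profile.profile.tolist(),
            },
            "roundness_profile": {
                "azimuth_deg": self.roundness_profile.coords.tolist(),
                "sensitivity": self.roundness_profile.profile.tolist(),
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def qc_report(detector_map, robust: bool = False, detrend: bool = False) -> DetectorQCReport:
    """Full QC pipeline: mask → normalize → ellipse → profiles → scores.

    Ellipticity is skipped (None) for detectors without an enclosed inner
    opening; the profile center then falls back to the mask centroid.
    """
    mask = active_region_mask(detector_map, robust=robust)
    norm = normalize_map(detector_map, mask)
    try:
        ell = ellipticity(mask)
        center = ell.center
        ratio = ell.ratio
    except NoHoleError:
        ell, ratio = None, None
        center = mask_centroid(mask)
    flat = flatness(norm, mask, center)
    rnd = roundness(norm, mask, center)
    smooth = smoothness(norm, mask, detrend=detrend)
    return DetectorQCReport(
        ellipticity=ratio,
        ellipse=ell,
        flatness_profile=flat,
        roundness_profile=rnd,
        flatness_score=flat.score,
        roundness_score=rnd.score,
        smoothness_score=smooth,
        active_mask=mask,
        center=center,
        inner_active_radius=float(flat.coords[0]),
        outer_active_radius=float(flat.coords[-1]),
    )


def synth_detector_map(
    geometry: DetectorGeometry,
    sensitivities=None,
    shape=(256, 256),
    gap_deg: float = 0.0,
    ellipticity_factor: float = 1.0,
    radial_ramp: float = 0.0,
    azimuth_sin_amp: float = 0.0,
    wedge: tuple[float, float, float] | None = None,
    noise_sigma: float = 0.0,
    background: float = 0.0,
    rng_seed: int = 0,
) -> DetectorMap:
    """Render a synthetic detector map from a segment geometry.

    Parameters
    ----------
    sensitivities : sequence, optional
        Per-segment sensitivity (default all 1).
    gap_deg : float
        Dead azimuthal gap rendered at each segment boundary (0 sensitivity).
    ellipticity_factor : float
        Stretches the map along x so the inner opening has this
        major/minor ratio.
    radial_ramp : float
        Sensitivity slope ``1 + ramp·(r - r_mid)/(r_out - r_in)`` across
        the active annulus.
    azimuth_sin_amp : float
        Sinusoidal azimuthal sensitivity ``1 + amp·sin(φ)``.
    wedge : (start_deg, end_deg, factor), optional
        Multiplies sensitivity by *factor* inside the azimuthal wedge.
    noise_sigma : float
        Gaussian pixel noise added over the whole map.
    """
    ny, nx = shape
    if ellipticity_factor < 1.0:
        raise InvalidParameterError("ellipticity_factor must be >= 1")
    sens = np.ones(geometry.n_segments) if sensitivities is None else np.asarray(
        sensitivities, dtype=float)
    if len(sens) != geometry.n_segments:
        raise InvalidParameterError("one sensitivity per segment required")
    r_lo, r_hi = geometry.radial_span
    # scale geometry radii to pixels, leaving a small border
    scale = 0.45 * min(ny, nx) / (r_hi * ellipticity_factor)
    if r_hi * scale < 8:
        raise InvalidParameterError("grid too small for geometry")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.indices(shape)
    dy = (yy - cy) / scale
    dx = (xx - cx) / scale / ellipticity_factor  # stretch along x
    r = np.hypot(dy, dx)
    phi = np.degrees(np.arctan2(dy, dx)) % 360.0

    v = np.full(shape, float(background))
    r_mid = 0.5 * (r_lo + r_hi)
    for i, (s0, s1, a0, a1) in enumerate(geometry.segments):
        in_r = (r >= s0) & (r < s1)
        a0m, a1m = a0 % 360.0, a1 % 360.0
        full = (a0m == a1m) or ((a1 - a0) % 360.0 == 0 and a1 != a0)
        if full:
            in_a = np.ones(shape, dtype=bool)
        elif a0m < a1m:
            in_a = (phi >= a0m) & (phi < a1m)
        else:
            in_a = (phi >= a0m) | (phi < a1m)
        seg = in_r & in_a
        if gap_deg > 0 and not full:
            for edge in (a0m, a1m):
                d = np.abs((phi - edge + 180.0) % 360.0 - 180.0)
                seg &= d > gap_deg / 2.0
        val = sens[i] * (
            1.0
            + radial_ramp * (r - r_mid) / (r_hi - r_lo)
            + azimuth_sin_amp * np.sin(np.radians(phi))
        )
        if wedge is not None:
            w0, w1, factor = wedge
            in_w = ((phi - w0) % 360.0) < ((w1 - w0) % 360.0)
            val = np.where(in_w, val * factor, val)
        v[seg] = val[seg]
    if noise_sigma > 0:
        rng = substream(rng_seed, "detmap")
        v = v + rng.normal(0.0, noise_sigma, size=shape)
    return DetectorMap(values=v)
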