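"""Detector-map uniformity metrics: null calibration, recovery, invariances."""

import numpy as np
import pytest

from pulsecount.detector_map_qc import (
    DetectorMap,
    active_region_mask,
    ellipticity,
    flatness,
    normalize_map,
    qc_report,
    roundness,
    smoothness,
    synth_detector_map,
)
from pulsecount.errors import (
    DegenerateInputError,
    InsufficientAnnulusError,
    NoHoleError,
)
from pulsecount.event_simulator import full_annulus, quadrant_ring_geometry


def annulus_mask(shape, r_in, r_out):
    c = (shape[0] - 1) / 2.0
    yy, xx = np.indices(shape)
    r = np.hypot(yy - c, xx - c)
    return (r >= r_in) & (r < r_out)


class TestActiveRegionMask:
    def test_binary_annulus(self):
        m = annulus_mask((128, 128), 20, 50).astype(float)
        np.testing.assert_array_equal(active_region_mask(m), m.astype(bool))

    def test_midpoint_threshold(self):
        ann = annulus_mask((128, 128), 20, 50)
        v = np.where(ann, 30.0, 10.0)
        np.testing.assert_array_equal(active_region_mask(v), ann)

    def test_hot_pixel_robust_option(self):
        ann = annulus_mask((128, 128), 20, 50)
        v = np.where(ann, 30.0, 10.0)
        v[0, 0] = 100.0  # hot pixel drives the plain midpoint to 55
        assert active_region_mask(v).sum() == 1
        robust = active_region_mask(v, robust=True)
        # percentile midpoint restores the annulus (hot pixel itself still
        # clears any sane threshold)
        assert np.array_equal(robust & ann, ann)
        assert (robust ^ ann).sum() <= 1

    def test_constant_map_degenerate(self):
        with pytest.raises(DegenerateInputError):
            active_region_mask(np.full((64, 64), 2.0))


class TestNormalizeMap:
    def test_two_level_map(self):
        ann = annulus_mask((128, 128), 20, 50)
        v = np.where(ann, 30.0, 10.0)
        out = normalize_map(v, ann)
        assert np.allclose(out[ann], 1.0)
        assert np.allclose(out[~ann], 0.0)

    def test_idempotent(self):
        ann = annulus_mask((128, 128), 20, 50)
        v = np.where(ann, 1.0, 0.0)
        out = normalize_map(normalize_map(v, ann), ann)
        np.testing.assert_allclose(out, v)

    def test_gradient_active_mean_is_one(self):
        ann = annulus_mask((128, 128), 20, 50)
        yy, xx = np.indices((128, 128))
        r = np.hypot(yy - 63.5, xx - 63.5)
        v = np.where(ann, 1.0 + 0.01 * (r - 35), 0.0)
        out = normalize_map(v, ann)
        assert out[ann].mean() == pytest.approx(1.0, abs=1e-12)


class TestEllipticity:
    def test_circular_hole(self):
        mask = annulus_mask((256, 256), 40, 100)
        assert ellipticity(mask).ratio == pytest.approx(1.0, abs=0.01)

    def test_axes_80_by_40(self):
        yy, xx = np.indices((256, 256))
        hole = ((xx - 128) / 40.0) ** 2 + ((yy - 128) / 20.0) ** 2 < 1
        outer = np.hypot(yy - 128, xx - 128) < 100
        mask = outer & ~hole
        fit = ellipticity(mask)
        assert fit.ratio == pytest.approx(2.0, rel=0.02)
        assert fit.major_diameter == pytest.approx(80.0, rel=0.05)

    def test_rotation_invariance(self):
        th = np.radians(30)
        yy, xx = np.indices((256, 256))
        u = (xx - 128) * np.cos(th) + (yy - 128) * np.sin(th)
        w = -(xx - 128) * np.sin(th) + (yy - 128) * np.cos(th)
        hole = (u / 40.0) ** 2 + (w / 20.0) ** 2 < 1
        mask = (np.hypot(yy - 128, xx - 128) < 100) & ~hole
        fit = ellipticity(mask)
        assert fit.ratio == pytest.approx(2.0, rel=0.02)
        assert fit.angle_deg == pytest.approx(30.0, abs=3.0)

    def test_no_hole_error(self):
        disk = np.hypot(*np.indices((128, 128)) - 63.5) < 40
        with pytest.raises(NoHoleError):
            ellipticity(disk)


class TestProfiles:
    def setup_method(self):
        self.shape = (256, 256)
        self.center = (127.5, 127.5)
        self.mask = annulus_mask(self.shape, 48, 115)
        yy, xx = np.indices(self.shape)
        self.r = np.hypot(yy - self.center[0], xx - self.center[1])

    def test_uniform_annulus_scores_zero(self):
        v = np.where(self.mask, 1.0, 0.0)
        assert flatness(v, self.mask, self.center).score == pytest.approx(0.0, abs=1e-9)
        assert roundness(v, self.mask, self.center).score == pytest.approx(0.0, abs=1e-9)
        assert smoothness(v, self.mask) == pytest.approx(0.0, abs=1e-12)

    def test_radial_ramp_flatness_closed_form(self):
        ramp = 1.0 + 0.2 * (self.r - 81.5) / 67.0
        v = np.where(self.mask, ramp, 0.0)
        res = flatness(v, self.mask, self.center)
        # oracle: same ramp evaluated at the valid bin centres
        expected = np.sqrt(np.mean((0.2 * (res.coords - 81.5) / 67.0) ** 2))
        assert res.score == pytest.approx(expected, rel=0.05)

    def test_sinusoidal_roundness_closed_form(self):
        yy, xx = np.indices(self.shape)
        phi = np.arctan2(yy - self.center[0], xx - self.center[1])
        v = np.where(self.mask, 1.0 + 0.1 * np.sin(phi), 0.0)
        res = roundness(v, self.mask, self.center)
        assert res.score == pytest.approx(0.1 / np.sqrt(2), rel=0.05)

    def test_dead_wedge_separates_metrics(self):
        g = full_annulus(25, 60)
        m = synth_detector_map(g, shape=(256, 256), wedge=(0, 20, 0.0))
        rep = qc_report(m)
        assert rep.flatness_score == pytest.approx(0.0, abs=0.01)
        # dead 20 deg wedge: azimuthal profile dips to 0 over 20/360 of bins
        assert rep.roundness_score == pytest.approx(np.sqrt(20 / 360), rel=0.1)

    def test_insufficient_annulus(self):
        thin = annulus_mask(self.shape, 60, 62)
        v = np.where(thin, 1.0, 0.0)
        with pytest.raises(InsufficientAnnulusError):
            flatness(v, thin, self.center)


class TestSmoothness:
    def test_gaussian_noise_level(self, rng):
        mask = annulus_mask((256, 256), 48, 115)
        v = np.where(mask, 1.0 + rng.normal(0, 0.05, (256, 256)), 0.0)
        assert smoothness(v, mask) == pytest.approx(0.05, rel=0.1)

    def test_single_dead_pixel_arithmetic(self):
        mask = annulus_mask((256, 256), 48, 115)
        n_active = int(mask.sum())
        v = np.where(mask, 1.0, 0.0)
        rr, cc = np.nonzero(mask)
        v[rr[0], cc[0]] = 0.0  # one dead pixel
        norm = normalize_map(v, mask)
        expected = np.sqrt(1.0 / n_active)  # RMS of one unit deviation
        assert smoothness(norm, mask) == pytest.approx(expected, rel=0.05)


class TestSynthAndReport:
    def test_ideal_annulus_null_report(self):
        m = synth_detector_map(full_annulus(25, 60), shape=(256, 256))
        rep = qc_report(m)
        assert rep.ellipticity == pytest.approx(1.0, abs=0.01)
        assert rep.flatness_score == pytest.approx(0.0, abs=1e-6)
        assert rep.roundness_score == pytest.approx(0.0, abs=1e-6)
        assert rep.smoothness_score == pytest.approx(0.0, abs=1e-9)

    def test_injected_ellipticity_recovered(self):
        m = synth_detector_map(full_annulus(25, 60), shape=(256, 256),
                               ellipticity_factor=1.5)
        assert qc_report(m).ellipticity == pytest.approx(1.5, rel=0.02)

    def test_gap_dominated_map_roundness_exceeds_flatness(self):
        m = synth_detector_map(quadrant_ring_geometry(), shape=(256, 256),
                               gap_deg=4.0)
        rep = qc_report(m)
        assert rep.roundness_score > rep.flatness_score

    def test_scale_invariance(self):
        m = synth_detector_map(full_annulus(25, 60), shape=(256, 256),
                               radial_ramp=0.2, azimuth_sin_amp=0.05)
        rep1 = qc_report(m)
        rep2 = qc_report(DetectorMap(m.values * 7.25))
        assert rep2.flatness_score == pytest.approx(rep1.flatness_score, rel=1e-9)
        assert rep2.roundness_score == pytest.approx(rep1.roundness_score, rel=1e-9)
        assert rep2.smoothness_score == pytest.approx(rep1.smoothness_score, rel=1e-9)
        assert rep2.ellipticity == pytest.approx(rep1.ellipticity, rel=1e-9)

    def test_rotation_covariance(self):
        m = synth_detector_map(full_annulus(25, 60), shape=(256, 256),
                               azimuth_sin_amp=0.1)
        rep = qc_report(m)
        rep90 = qc_report(DetectorMap(np.ascontiguousarray(np.rot90(m.values))))
        assert rep90.flatness_score == pytest.approx(rep.flatness_score, abs=5e-3)
        assert rep90.roundness_score == pytest.approx(rep.roundness_score, abs=5e-3)
        assert rep90.smoothness_score == pytest.approx(rep.smoothness_score, abs=5e-3)
        # azimuthal profile is permuted by a quarter turn (rot90 is a -90
        # degree rotation in image azimuth)
        rolled = np.roll(rep.roundness_profile.profile, -90)
        assert np.corrcoef(rolled, rep90.roundness_profile.profile)[0, 1] > 0.99

    def test_report_json_round_trip(self, tmp_path):
        import json

        m = synth_detector_map(full_annulus(25, 60), shape=(128, 128),
                               azimuth_sin_amp=0.05)
        rep = qc_report(m)
        rep.to_json(tmp_path / "r.json")
        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["roundness_score"] == pytest.approx(rep.roundness_score)
        assert len(loaded["roundness_profile"]["azimuth_deg"]) == 360
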