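"""Trajectory metrology: differentiation, body-axis regression, stereo."""

import math

import numpy as np
import pytest

from hoverfall.metrics import (
    DEFAULT_RIG,
    StereoRig,
    accel_from_positions,
    body_axis_pitch,
    grating_spatial_frequency,
    quantization_uncertainty,
    stereo_min_distance,
    theoretical_of,
)

TS = 1.0 / 1600.0
EDGE = 6  # half the Savitzky-Golay window: filter edge effects


class TestAccelFromPositions:
    def _t(self, dur=0.3):
        return np.arange(0, dur, TS)

    def test_ballistic_fall_cancels_gravity(self):
        t = self._t()
        pos = np.stack([np.zeros_like(t), np.zeros_like(t),
                        0.4 - 0.5 * 9.81 * t**2], axis=1)
        _, _, f = accel_from_positions(pos, TS)
        assert np.max(np.abs(f[EDGE:-EDGE])) < 1e-6

    def test_hover_reads_body_weight(self):
        t = self._t()
        pos = np.stack([np.full_like(t, 0.1)] * 3, axis=1)
        _, _, f = accel_from_positions(pos, TS)
        assert np.allclose(f[EDGE:-EDGE], 9.81)

    def test_horizontal_quadratic_closed_form(self):
        a = 3.0
        t = self._t()
        pos = np.stack([0.5 * a * t**2, np.zeros_like(t), np.zeros_like(t)], axis=1)
        axy, az, f = accel_from_positions(pos, TS)
        assert np.allclose(axy[EDGE:-EDGE], a, atol=1e-6)
        assert np.allclose(f[EDGE:-EDGE], math.hypot(a, 9.81), atol=1e-6)

    def test_exact_on_any_quadratic(self, rng):
        # polynomial oracle: double differentiation + SG smoothing is exact
        # on quadratics away from the edges
        t = self._t()
        coefs = rng.normal(size=(3, 3))  # per-axis quadratic
        pos = np.stack(
            [c[0] + c[1] * t + 0.5 * c[2] * t**2 for c in coefs], axis=1
        )
        axy, az, _ = accel_from_positions(pos, TS)
        assert np.allclose(axy[EDGE:-EDGE], math.hypot(coefs[0][2], coefs[1][2]),
                           atol=1e-6)
        assert np.allclose(az[EDGE:-EDGE], coefs[2][2], atol=1e-6)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            accel_from_positions(np.zeros((5, 3)), TS)


class TestBodyAxisPitch:
    def _axis_points(self, yaw, pitch, length=0.013, n=7):
        s = np.linspace(-length / 2, length / 2, n)
        ux = math.cos(pitch) * math.cos(yaw)
        uy = math.cos(pitch) * math.sin(yaw)
        uz = math.sin(pitch)
        pts = np.stack([s * ux, s * uy, s * uz], axis=1)
        head, tail = pts[-1:], pts[:1]
        centroid = pts[n // 2 : n // 2 + 1]
        return head, centroid, tail, pts

    def test_level_axis_along_x(self):
        head, centroid, tail, _ = self._axis_points(0.0, 0.0)
        yaw, pitch, degen = body_axis_pitch(head, centroid, tail)
        assert yaw == pytest.approx(0.0, abs=1e-12)
        assert pitch == pytest.approx(0.0, abs=1e-12)
        assert not degen

    def test_known_orientation_recovered_exactly(self):
        yaw0, pitch0 = math.radians(45.0), math.radians(-30.0)
        head, centroid, tail, _ = self._axis_points(yaw0, pitch0)
        yaw, pitch, _ = body_axis_pitch(head, centroid, tail)
        assert yaw == pytest.approx(yaw0, abs=1e-9)
        assert pitch == pytest.approx(pitch0, abs=1e-9)

    def test_rotation_equivariance_in_yaw(self):
        phi = math.radians(25.0)
        head, centroid, tail, _ = self._axis_points(0.2, -0.4)
        c, s = math.cos(phi), math.sin(phi)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        yaw0, pitch0, _ = body_axis_pitch(head, centroid, tail)
        yaw1, pitch1, _ = body_axis_pitch(head @ R.T, centroid @ R.T, tail @ R.T)
        assert yaw1 - yaw0 == pytest.approx(phi, abs=1e-9)
        assert pitch1 == pytest.approx(pitch0, abs=1e-9)

    def test_vertical_cloud_falls_back_to_pca(self):
        head = np.array([[0.0, 0.006, 0.0]])
        centroid = np.array([[0.0, 0.0, 0.0]])
        tail = np.array([[0.0, -0.006, 0.0]])
        yaw, pitch, degen = body_axis_pitch(head, centroid, tail)
        assert degen
        assert abs(abs(yaw) - math.pi / 2) < 1e-6

    def test_noise_induced_pitch_error_on_13mm_body(self, rng):
        # 0.5 mm landmark noise on a 13 mm body axis: the stereo calibration
        # put the resulting pitch error around +/-5 degrees (0.08 rad)
        errs = []
        for _ in range(300):
            head, centroid, tail, _ = self._axis_points(0.3, -0.35)
            noise = lambda a: a + rng.normal(0.0, 0.0005, a.shape)
            _, pitch, _ = body_axis_pitch(noise(head), noise(centroid), noise(tail))
            errs.append(pitch - (-0.35))
        sd = float(np.std(errs))
        assert 0.02 < sd < 0.12  # on the order of the reported 0.08 rad

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            body_axis_pitch(np.zeros((1, 3)), np.zeros((0, 3)), np.zeros((1, 3)))


class TestTheoreticalOF:
    def test_equidistant_walls(self):
        df = theoretical_of(np.array([[0.0, -1.0]]), (0.2, 0.2))
        assert df["omega_mag"].iloc[0] == pytest.approx(5.0)

    def test_nearest_wall_rule(self):
        df = theoretical_of(np.array([[1.0, 0.0]]), (0.1, 0.3))
        assert df["omega_mag"].iloc[0] == pytest.approx(10.0)

    def test_agrees_with_model_optic_flow(self):
        from hoverfall.model import optic_flow

        vel = np.array([[0.4, -0.7]])
        pitch = np.array([-0.3])
        df = theoretical_of(vel, (0.2, 0.2), pitch)
        of = optic_flow(0.4, -0.7, -0.3, 0.2)
        assert df["omega_x"].iloc[0] == pytest.approx(of.omega_x)
        assert df["omega_z"].iloc[0] == pytest.approx(of.omega_z)

    def test_invalid_distances_rejected(self):
        with pytest.raises(ValueError):
            theoretical_of(np.zeros((1, 2)), (0.0, 0.2))


class TestStereoMetrology:
    def test_reproduces_both_printed_range_endpoints(self):
        assert stereo_min_distance(DEFAULT_RIG, 1131.0) == pytest.approx(2.56, abs=0.005)
        assert stereo_min_distance(DEFAULT_RIG, 1531.0) == pytest.approx(4.68, abs=0.01)

    def test_quadratic_distance_scaling(self):
        assert stereo_min_distance(DEFAULT_RIG, 2000.0) == pytest.approx(
            4 * stereo_min_distance(DEFAULT_RIG, 1000.0)
        )

    def test_invalid_rig_rejected(self):
        with pytest.raises(ValueError):
            StereoRig(baseline=0.0)
        with pytest.raises(ValueError):
            stereo_min_distance(DEFAULT_RIG, -1.0)


class TestQuantizationUncertainty:
    def test_printed_formula_at_range_minimum(self):
        assert quantization_uncertainty(2.56) == pytest.approx(0.739, abs=1e-3)

    def test_zero_and_linearity(self):
        assert quantization_uncertainty(0.0) == 0.0
        assert quantization_uncertainty(5.0) == pytest.approx(
            2 * quantization_uncertainty(2.5)
        )


class TestGrating:
    def test_stripes_at_wall_distance(self):
        assert grating_spatial_frequency(0.028, 0.20) == pytest.approx(0.06, abs=0.005)

    def test_one_degree_cycle_identity(self):
        # a cycle constructed to subtend exactly 1 degree
        period = 2 * 0.20 * math.tan(math.radians(0.5))
        assert grating_spatial_frequency(period / 2, 0.20) == pytest.approx(1.0)

    def test_small_angle_halving(self):
        f1 = grating_spatial_frequency(0.028, 0.20)
        f2 = grating_spatial_frequency(0.028, 0.10)
        assert f2 == pytest.approx(f1 / 2, rel=0.02)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            grating_spatial_frequency(0.0, 0.2)
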