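"""Coordinate transforms, differentiation and foveal geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazekit.kinematics import (
    EyeGeometry,
    cartesian_to_spherical,
    eye_cartesian_to_plane,
    foveal_visual_radius,
    fvr_series,
    ocular_angles,
    pitch_yaw_rotation,
    plane_to_eye_cartesian,
    scalar_visual_angle,
    spherical_kinematics,
    spherical_rotation,
    spherical_to_cartesian,
)

DEG = 180.0 / np.pi


def rotation_about_x(angle_deg):
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


class TestPlaneToEye:
    def test_origin_maps_to_vertical_drop(self):
        geom = EyeGeometry(0.6)
        assert np.allclose(plane_to_eye_cartesian(0.0, 0.0, geom), [[0, 0, 0.6]])

    def test_identity_rotation_is_translation(self):
        geom = EyeGeometry(0.6)
        assert np.allclose(
            plane_to_eye_cartesian(0.1, 0.2, geom), [[0.1, 0.2, 0.6]]
        )

    def test_head_tilt_matches_direct_matrix_product(self):
        r = rotation_about_x(10.0)
        geom = EyeGeometry(0.6, r_head=r)
        expected = np.array([0, 0, 0.6]) + r @ np.array([0.1, 0.2, 0.0])
        assert np.allclose(plane_to_eye_cartesian(0.1, 0.2, geom)[0], expected)

    def test_non_orthonormal_head_matrix_rejected(self):
        with pytest.raises(ValueError):
            EyeGeometry(0.6, r_head=np.eye(3) * 2.0)

    @given(st.floats(-0.3, 0.3), st.floats(-0.3, 0.5), st.floats(-15, 15))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_with_head_tilt(self, x, y, tilt):
        geom = EyeGeometry(0.45, r_head=rotation_about_x(tilt))
        xyz = plane_to_eye_cartesian(x, y, geom)
        bx, by = eye_cartesian_to_plane(xyz, geom)
        assert abs(bx[0] - x) < 1e-10 and abs(by[0] - y) < 1e-10


class TestSpherical:
    def test_worked_example(self):
        rho, theta, phi = cartesian_to_spherical([[0.1, 0.2, 0.6]])
        assert rho[0] == pytest.approx(0.640312, abs=1e-6)
        assert theta[0] * DEG == pytest.approx(63.4349, abs=1e-4)
        assert phi[0] * DEG == pytest.approx(20.4393, abs=1e-4)

    def test_pole_convention(self):
        rho, theta, phi = cartesian_to_spherical([[0.0, 0.0, 0.55]])
        assert rho[0] == 0.55 and theta[0] == 0.0 and phi[0] == 0.0

    def test_rho_zero_rejected(self):
        with pytest.raises(ValueError):
            cartesian_to_spherical([[0.0, 0.0, 0.0]])

    def test_azimuth_covers_full_circle(self):
        rho, theta, _ = cartesian_to_spherical([[-0.1, -0.1, 0.5]])
        assert np.pi < theta[0] < 1.5 * np.pi

    @given(
        st.floats(0.2, 1.0),
        st.floats(0.0, 2 * np.pi - 1e-6),
        st.floats(1e-3, np.pi / 2),
    )
    @settings(max_examples=100, deadline=None)
    def test_roundtrip(self, rho, theta, phi):
        xyz = spherical_to_cartesian(rho, theta, phi)
        r2, t2, p2 = cartesian_to_spherical(xyz)
        assert abs(r2[0] - rho) < 1e-10
        assert abs(p2[0] - phi) < 1e-10
        dtheta = np.mod(t2[0] - theta + np.pi, 2 * np.pi) - np.pi
        assert abs(dtheta) < 1e-9


class TestSphericalKinematics:
    def test_stationary_gaze_has_zero_speed(self):
        xyz = np.tile([0.1, 0.2, 0.6], (200, 1))
        kin = spherical_kinematics(xyz, 500.0)
        assert np.allclose(kin.v, 0.0, atol=1e-9)
        assert np.allclose(kin.a, 0.0, atol=1e-6)

    def test_circular_trajectory_closed_form(self):
        # constant elevation 30 deg, azimuthal rate 2 rad/s -> v = 2 sin(30 deg)
        rate = 1000.0
        t = np.arange(3000) / rate
        phi = np.deg2rad(30.0)
        theta = 2.0 * t
        xyz = spherical_to_cartesian(np.full_like(t, 0.6), theta, np.full_like(t, phi))
        kin = spherical_kinematics(xyz, rate)
        interior = slice(100, -100)
        assert np.allclose(kin.v[interior], 1.0 * DEG, rtol=1e-3)

    def test_speed_matches_geometric_oracle(self):
        # independent oracle: angle between successive unit gaze vectors x rate
        rate = 500.0
        t = np.arange(2000) / rate
        x = 0.05 * np.sin(2 * np.pi * 1.3 * t) + 0.02
        y = 0.3 + 0.04 * np.cos(2 * np.pi * 0.7 * t)
        geom = EyeGeometry(0.4)
        xyz = plane_to_eye_cartesian(x, y, geom)
        kin = spherical_kinematics(xyz, rate)
        u = xyz / np.linalg.norm(xyz, axis=1, keepdims=True)
        dots = np.clip((u[1:] * u[:-1]).sum(axis=1), -1, 1)
        oracle = np.degrees(np.arccos(dots)) * rate
        mid = 0.5 * (oracle[1:] + oracle[:-1])
        assert np.max(np.abs((kin.v[1:-1] - mid)[100:-100])) < 0.5

    def test_spherical_rates_match_finite_difference_oracle(self):
        # analytic trajectory at 10 kHz: closed-form rates vs central differences
        rate = 10000.0
        t = np.arange(30000) / rate
        x = 0.06 * np.cos(2 * np.pi * 0.9 * t)
        y = 0.25 + 0.05 * np.sin(2 * np.pi * 1.1 * t)
        z = np.full_like(t, 0.45)
        dx = -0.06 * 2 * np.pi * 0.9 * np.sin(2 * np.pi * 0.9 * t)
        dy = 0.05 * 2 * np.pi * 1.1 * np.cos(2 * np.pi * 1.1 * t)
        rho = np.sqrt(x**2 + y**2 + z**2)
        planar2 = x**2 + y**2
        d_phi_closed = (z * (x * dx + y * dy)) / (rho**2 * np.sqrt(planar2))
        d_theta_closed = (x * dy - y * dx) / planar2
        _, theta, phi = cartesian_to_spherical(np.column_stack([x, y, z]))
        d_phi_fd = np.gradient(phi, 1.0 / rate)
        d_theta_fd = np.gradient(np.unwrap(theta), 1.0 / rate)
        assert np.max(np.abs(d_phi_closed[5:-5] - d_phi_fd[5:-5])) < 1e-6
        assert np.max(np.abs(d_theta_closed[5:-5] - d_theta_fd[5:-5])) < 1e-6

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            spherical_kinematics(np.tile([0.1, 0.2, 0.6], (5, 1)), 500.0,
                                 sg_window_ms=100.0)


class TestOcularAngles:
    def test_worked_example_mapping(self):
        alpha, gamma = ocular_angles(np.deg2rad(63.4349), np.deg2rad(20.4393))
        assert alpha == pytest.approx(20.4393, abs=1e-4)
        assert gamma == pytest.approx(26.5651, abs=1e-4)

    def test_straight_ahead_azimuth_gives_zero_yaw(self):
        _, gamma = ocular_angles(np.deg2rad(90.0), np.deg2rad(10.0))
        assert gamma == pytest.approx(0.0, abs=1e-12)

    def test_rotation_matrix_equivalence(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            theta = rng.uniform(0, 2 * np.pi)
            phi = rng.uniform(0, np.pi / 2)
            r_sph = spherical_rotation(theta, phi)
            alpha, gamma = ocular_angles(theta, phi)
            r_oc = pitch_yaw_rotation(alpha, gamma)
            assert np.max(np.abs(r_sph - r_oc)) < 1e-12

    def test_rotation_matrices_orthonormal(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            r = spherical_rotation(rng.uniform(0, 2 * np.pi), rng.uniform(0, np.pi))
            assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
            assert abs(np.linalg.det(r) - 1) < 1e-12


class TestFovealRadius:
    def test_direct_evaluation(self):
        # rho=0.65, delta=3 deg, eps=60 deg -> 0.65 tan(1.5 deg)/sin(60 deg)
        eps = np.deg2rad(60.0)
        por = np.array([0.65 * np.cos(eps), 0.0, 0.65 * np.sin(eps)])
        fc = foveal_visual_radius(por, 3.0, EyeGeometry(por[2]))
        assert fc.fvr_m == pytest.approx(0.019654, abs=1e-6)

    def test_nadir_collapses_cosecant(self):
        fc = foveal_visual_radius([0.0, 0.0, 0.5], 3.0, EyeGeometry(0.5))
        assert fc.fvr_m == pytest.approx(0.5 * np.tan(np.deg2rad(1.5)), abs=1e-12)

    def test_grows_with_distance(self):
        geom = EyeGeometry(0.4)
        ys = np.linspace(0.05, 0.6, 30)
        xyz = plane_to_eye_cartesian(np.zeros_like(ys), ys, geom)
        fvr = fvr_series(xyz, 3.0, geom)
        assert np.all(np.diff(fvr) > 0)

    def test_gaze_parallel_to_plane_rejected(self):
        with pytest.raises(ValueError):
            foveal_visual_radius([0.5, 0.0, 0.0], 3.0, EyeGeometry(0.4))


class TestScalarVisualAngle:
    def test_zero_extent(self):
        assert scalar_visual_angle(0.0, 0.5) == 0.0

    def test_inverse_identity(self):
        b = 0.6
        a = 2 * b * np.tan(np.deg2rad(1.5))
        assert scalar_visual_angle(a, b) == pytest.approx(3.0, abs=1e-12)

    def test_direct_evaluation(self):
        assert scalar_visual_angle(0.02, 0.60) == pytest.approx(1.90968, abs=1e-4)

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            scalar_visual_angle(0.1, 0.0)


def test_small_angle_consistency_with_planar_speed():
    # near the nadir, angular speed x distance approximates planar speed
    rate = 2000.0
    t = np.arange(4000) / rate
    geom = EyeGeometry(0.5)
    x = 0.005 * np.sin(2 * np.pi * 0.5 * t)
    y = 0.005 * np.cos(2 * np.pi * 0.5 * t)
    xyz = plane_to_eye_cartesian(x, y, geom)
    kin = spherical_kinematics(xyz, rate)
    planar_speed = 0.005 * 2 * np.pi * 0.5
    angular_speed = np.deg2rad(np.median(kin.v[200:-200]))
    assert angular_speed * 0.5 == pytest.approx(planar_speed, rel=0.01)
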