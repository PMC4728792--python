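"""Eye-based spherical kinematics inverse-computed from planar point-of-regard data.

The gaze POR ``(x, y)`` in the transverse stimulus plane is lifted to an eye-centred
Cartesian frame (X' rightward, Y' anterior, Z' pointing down toward the plane, so that
``z' = H`` everywhere when the head is untilted), converted to spherical coordinates
(radial distance ρ, azimuth θ in [0, 2π) from X', elevation ϕ from the +Z' axis), and
differentiated.  Cartesian derivatives come from Savitzky-Golay smoothing
differentiation; the spherical rates follow from the closed forms

    ϕ̇ = [z'(x'ẋ' + y'ẏ') − (x'² + y'²)ż'] / [ρ² √(x'² + y'²)]
    θ̇ = (x'ẏ' − y'ẋ') / (x'² + y'²)

and the angular speed and acceleration magnitudes from the transverse components of the
spherical velocity/acceleration.  Ocular pitch and yaw are α = ϕ and γ = 90° − θ, the
unique pitch-then-yaw decomposition of the gaze rotation under Listing's law.

The foveal visual radius (FVR) is the plane-projected radius of the foveal region
around the POR: FVR ≈ ρ·tan(δ/2)·cosec(ε), with δ the foveal visual angle (default 3°
plus the session's mean calibration error) and ε the angle between the gaze vector and
the plane.  The FVR grows with viewing distance and obliquity and is the spatial
tolerance used by the event classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

DEG = 180.0 / np.pi


@dataclass
class EyeGeometry:
    """Fixed viewing geometry: eye height above the plane and head orientation.

    ``r_head`` maps robot-frame (plane) coordinates into the eye frame; identity
    when the head is untilted.  ``calib_err_deg`` is added to the base foveal
    visual angle.
    """

    height_m: float
    r_head: np.ndarray = None
    calib_err_deg: float = 0.0

    def __post_init__(self):
        if self.height_m <= 0:
            raise ValueError("eye height must be positive")
        if self.r_head is None:
            self.r_head = np.eye(3)
        self.r_head = np.asarray(self.r_head, dtype=float)
        _check_rotation(self.r_head)


def _check_rotation(r: np.ndarray, tol: float = 1e-10) -> None:
    if r.shape != (3, 3):
        raise ValueError("head-orientation matrix must be 3x3")
    if not np.allclose(r @ r.T, np.eye(3), atol=tol) or abs(np.linalg.det(r) - 1) > tol:
        raise ValueError("head-orientation matrix must be orthonormal with det +1")


@dataclass
class SphericalKinematics:
    """Per-sample spherical coordinates, derivatives, and derived ocular kinematics.

    Angles in the ``theta``/``phi`` arrays are radians; the interface quantities
    ``v`` (angular speed, deg/s), ``a`` (angular acceleration magnitude, deg/s²),
    ``alpha``/``gamma`` (pitch/yaw, deg) and ``fvr`` (m) are in display units.
    """

    t: np.ndarray
    rate_hz: float
    xyz: np.ndarray          # (n, 3) eye-frame Cartesian POR
    d_xyz: np.ndarray        # first derivatives (m/s)
    dd_xyz: np.ndarray       # second derivatives (m/s²)
    rho: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    d_rho: np.ndarray
    d_theta: np.ndarray
    d_phi: np.ndarray
    dd_rho: np.ndarray
    dd_theta: np.ndarray
    dd_phi: np.ndarray
    v: np.ndarray
    a: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    fvr: np.ndarray = None
    valid: np.ndarray = None
    geom: "EyeGeometry" = None
    sg_window_ms: float = 21.0
    sg_order: int = 2

    def __len__(self):
        return self.t.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    def unit_gaze(self) -> np.ndarray:
        """Unit gaze vectors (n, 3)."""
        return self.xyz / self.rho[:, None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t,
                "rho_m": self.rho,
                "theta_deg": self.theta * DEG,
                "phi_deg": self.phi * DEG,
                "alpha_deg": self.alpha,
                "gamma_deg": self.gamma,
                "v_degps": self.v,
                "a_degps2": self.a,
                "fvr_m": self.fvr if self.fvr is not None else np.nan,
            }
        )


@dataclass
class FovealCircle:
    """Foveal visual circle on the stimulus plane around a POR."""

    center: tuple[float, float]
    fvr_m: float
    delta_deg: float
    epsilon_rad: float


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def plane_to_eye_cartesian(x, y, geom: EyeGeometry) -> np.ndarray:
    """Lift plane POR to the eye-centred Cartesian frame.

    ``[x'; y'; z'] = [0; 0; H] + R_head · [x; y; 0]`` per sample; returns (n, 3).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    p = np.column_stack([x, y, np.zeros_like(x)])
    offset = np.array([0.0, 0.0, geom.height_m])
    return p @ geom.r_head.T + offset


def eye_cartesian_to_plane(xyz: np.ndarray, geom: EyeGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`plane_to_eye_cartesian` for points lying in the plane."""
    offset = np.array([0.0, 0.0, geom.height_m])
    p = (np.atleast_2d(xyz) - offset) @ geom.r_head
    return p[:, 0], p[:, 1]


def cartesian_to_spherical(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eye-frame Cartesian -> spherical (ρ, θ, ϕ), θ in [0, 2π), ϕ in [0, π].

    θ is the full-quadrant azimuth from the X' axis (two-argument arctangent);
    at the pole (x' = y' = 0) the convention θ = 0 is used.
    """
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    rho = np.linalg.norm(xyz, axis=1)
    if np.any(rho == 0):
        raise ValueError("rho = 0: POR coincides with the eye")
    theta = np.mod(np.arctan2(xyz[:, 1], xyz[:, 0]), 2 * np.pi)
    pole = (xyz[:, 0] == 0) & (xyz[:, 1] == 0)
    theta[pole] = 0.0
    phi = np.arccos(np.clip(xyz[:, 2] / rho, -1.0, 1.0))
    return rho, theta, phi


def spherical_to_cartesian(rho, theta, phi) -> np.ndarray:
    """Spherical -> eye-frame Cartesian; inverse of :func:`cartesian_to_spherical`."""
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    return np.column_stack(
        [
            rho * np.sin(phi) * np.cos(theta),
            rho * np.sin(phi) * np.sin(theta),
            rho * np.cos(phi),
        ]
    )


def scalar_visual_angle(a, b) -> np.ndarray | float:
    """Scalar visual angle β (deg) subtended by extent ``a`` at viewing distance ``b``.

    tan(β/2) = a / (2b).  This is the constant-depth baseline used by frontal-plane
    trackers; it ignores the depth variation of a transverse workspace.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr <= 0):
        raise ValueError("viewing distance must be positive")
    beta = 2.0 * np.arctan(np.asarray(a, dtype=float) / (2.0 * b_arr)) * DEG
    return float(beta) if np.isscalar(a) and np.isscalar(b) else beta


# ---------------------------------------------------------------------------
# Differentiation
# ---------------------------------------------------------------------------

def _sg_window_samples(window_ms: float, rate_hz: float, order: int) -> int:
    w = int(round(window_ms * rate_hz / 1000.0))
    w = max(w, order + 1)
    if w % 2 == 0:
        w += 1
    return w


def spherical_kinematics(
    xyz: np.ndarray,
    rate_hz: float,
    t: np.ndarray | None = None,
    sg_window_ms: float = 21.0,
    sg_order: int = 2,
    geom: EyeGeometry | None = None,
    delta_deg: float | None = None,
    valid: np.ndarray | None = None,
) -> SphericalKinematics:
    """Differentiate an eye-frame Cartesian POR series into spherical kinematics.

    Cartesian first and second derivatives are obtained with one Savitzky-Golay
    smoothing-differentiation filter (default window 21 ms rounded to an odd sample
    count, polynomial order 2).  Spherical rates use the closed forms above; the
    second derivatives of ρ, θ, ϕ are obtained by applying the same Savitzky-Golay
    derivative to the first-derivative series.  ``v`` and ``a`` are the magnitudes
    of the transverse (angular) velocity and acceleration in deg/s and deg/s².

    When ``geom`` is given the per-sample foveal visual radius is attached using
    ``delta_deg`` (default 3° + calibration error).
    """
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    n = xyz.shape[0]
    window = _sg_window_samples(sg_window_ms, rate_hz, sg_order)
    if window > n:
        raise ValueError("Savitzky-Golay window longer than trace")
    dt = 1.0 / rate_hz
    if t is None:
        t = np.arange(n) * 1000.0 * dt

    d_xyz = savgol_filter(xyz, window, sg_order, deriv=1, delta=dt, axis=0)
    dd_xyz = savgol_filter(xyz, window, sg_order, deriv=2, delta=dt, axis=0)

    rho, theta, phi = cartesian_to_spherical(xyz)
    x, y, z = xyz.T
    dx, dy, dz = d_xyz.T
    planar2 = x**2 + y**2
    planar = np.sqrt(planar2)
    safe_planar2 = np.where(planar2 > 0, planar2, np.finfo(float).tiny)
    safe_planar = np.sqrt(safe_planar2)

    d_rho = (x * dx + y * dy + z * dz) / rho
    d_phi = (z * (x * dx + y * dy) - planar2 * dz) / (rho**2 * safe_planar)
    d_theta = (x * dy - y * dx) / safe_planar2

    dd_rho = savgol_filter(d_rho, window, sg_order, deriv=1, delta=dt)
    dd_phi = savgol_filter(d_phi, window, sg_order, deriv=1, delta=dt)
    dd_theta = savgol_filter(d_theta, window, sg_order, deriv=1, delta=dt)

    sin_phi = np.sin(phi)
    cos_phi = np.cos(phi)
    v = np.sqrt((d_theta * sin_phi) ** 2 + d_phi**2) * DEG
    a_theta = 2 * d_rho * d_theta * sin_phi / rho + dd_theta * sin_phi - 2 * d_theta * d_phi * cos_phi
    a_phi = 2 * d_rho * d_phi / rho + d_theta**2 * sin_phi * cos_phi + dd_phi
    a = np.sqrt(a_theta**2 + a_phi**2) * DEG

    alpha = phi * DEG
    gamma = 90.0 - theta * DEG

    fvr = None
    if geom is not None:
        if delta_deg is None:
            delta_deg = 3.0 + geom.calib_err_deg
        fvr = fvr_series(xyz, delta_deg, geom)

    return SphericalKinematics(
        t=np.asarray(t, dtype=float), rate_hz=rate_hz, xyz=xyz, d_xyz=d_xyz,
        dd_xyz=dd_xyz, rho=rho, theta=theta, phi=phi, d_rho=d_rho,
        d_theta=d_theta, d_phi=d_phi, dd_rho=dd_rho, dd_theta=dd_theta,
        dd_phi=dd_phi, v=v, a=a, alpha=alpha, gamma=gamma, fvr=fvr,
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool),
        geom=geom, sg_window_ms=sg_window_ms, sg_order=sg_order,
    )


def trace_kinematics(trace, geom: EyeGeometry, delta_deg: float | None = None,
                     sg_window_ms: float = 21.0, sg_order: int = 2) -> SphericalKinematics:
    """Full chain from a repaired/filtered :class:`GazeTrace` to kinematics."""
    xyz = plane_to_eye_cartesian(trace.x, trace.y, geom)
    return spherical_kinematics(
        xyz, trace.rate_hz, t=trace.t, sg_window_ms=sg_window_ms,
        sg_order=sg_order, geom=geom, delta_deg=delta_deg, valid=trace.valid,
    )


# ---------------------------------------------------------------------------
# Ocular angles and rotation matrices
# ---------------------------------------------------------------------------

def rotation_x(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def rotation_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def spherical_rotation(theta_rad: float, phi_rad: float) -> np.ndarray:
    """Gaze rotation as R_Z'(90°−θ) · R_X'(ϕ): the spherical-coordinate route."""
    return rotation_z(np.pi / 2 - theta_rad) @ rotation_x(phi_rad)


def pitch_yaw_rotation(alpha_deg: float, gamma_deg: float) -> np.ndarray:
    """Gaze rotation as R_Z(γ) · R_X(α): the ocular pitch/yaw route."""
    return rotation_z(np.deg2rad(gamma_deg)) @ rotation_x(np.deg2rad(alpha_deg))


def ocular_angles(theta, phi) -> tuple[np.ndarray, np.ndarray]:
    """Map spherical (θ, ϕ) in radians to ocular pitch α and yaw γ in degrees.

    α = ϕ and γ = 90° − θ; under this substitution the spherical rotation and the
    pitch/yaw rotation matrices coincide element-wise.
    """
    alpha = np.asarray(phi, dtype=float) * DEG
    gamma = 90.0 - np.asarray(theta, dtype=float) * DEG
    return alpha, gamma


# ---------------------------------------------------------------------------
# Foveal visual radius
# ---------------------------------------------------------------------------

def foveal_visual_radius(por_eye, delta_deg: float, geom: EyeGeometry) -> FovealCircle:
    """Foveal visual circle around a POR given in eye-frame Cartesian coordinates.

    ε = arcsin(z'/ρ) is the gaze-to-plane angle (exact for an untilted head);
    FVR = ρ·tan(δ/2)/sin(ε).  Grows monotonically with distance from the point
    directly below the eye.
    """
    por_eye = np.asarray(por_eye, dtype=float).ravel()
    rho = float(np.linalg.norm(por_eye))
    if rho == 0:
        raise ValueError("rho = 0: POR coincides with the eye")
    eps = float(np.arcsin(np.clip(por_eye[2] / rho, -1.0, 1.0)))
    if eps <= 0:
        raise ValueError("gaze parallel to (or above) the plane: epsilon <= 0")
    fvr = rho * np.tan(np.deg2rad(delta_deg) / 2.0) / np.sin(eps)
    px, py = eye_cartesian_to_plane(por_eye[None, :], geom)
    return FovealCircle((float(px[0]), float(py[0])), float(fvr), delta_deg, eps)


def fvr_series(xyz: np.ndarray, delta_deg: float, geom: EyeGeometry) -> np.ndarray:
    """Vectorised foveal visual radius for an (n, 3) eye-frame POR series."""
    xyz = np.atleast_2d(xyz)
    rho = np.linalg.norm(xyz, axis=1)
    eps = np.arcsin(np.clip(xyz[:, 2] / rho, -1.0, 1.0))
    if np.any(eps <= 0):
        raise ValueError("gaze parallel to (or above) the plane: epsilon <= 0")
    return rho * np.tan(np.deg2rad(delta_deg) / 2.0) / np.sin(eps)
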