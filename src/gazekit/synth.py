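"""Synthetic gaze sessions in the transverse plane with exact ground-truth labels.

Sessions emulate the statistical structure of remote video-tracker recordings from
robotic-workspace eye-hand coordination tasks: a *static* mode (connect-the-dots style visual search:
fixations on scattered static stimuli linked by saccades) and a *dynamic* mode
(trials with a static fixation circle followed by two objects approaching the
participant at 24-42 cm/s, foveated by saccades, brief post-saccadic fixations, and
smooth pursuits).

Gaze is assembled segment-wise in gaze-direction space: fixations hold a direction,
saccades follow a minimum-jerk angular profile between directions with durations
from the main-sequence duration law D = d₀ + d₁·A (so peak velocity saturates with
amplitude as 1.875·A/D), and pursuits track the target path with ~100 ms onset lag
bridged by a catch-up saccade.  The clean angular trajectory is perturbed by a
two-component noise model — slow oculomotor instability (drift-like, band-limited
at ~1 Hz, carrying most of the configured positional RMS) plus small white
measurement noise — and projected to plane POR by intersecting the gaze ray with
the stimulus plane (the analytic inverse of the plane→eye→spherical transform).
Blinks (sentinel-coded gaps) and one-sample corneal-reflection spikes are injected
last.  Every sample carries a ground-truth label; a fixed seed makes the session
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from gazekit.classify import GazeEvent, labels_to_events
from gazekit.io_preprocess import DEFAULT_SENTINEL, GazeTrace, StimulusTrack
from gazekit.kinematics import (
    EyeGeometry,
    cartesian_to_spherical,
    plane_to_eye_cartesian,
    spherical_to_cartesian,
)


@dataclass
class SessionScenario:
    """Parameters of a simulated gaze session.

    Defaults reproduce the study conditions the generator emulates: 500 Hz
    sampling, an eye ~0.35 m above the plane (stimuli then sit ~0.6 m from the
    eye), objects approaching at 0.24-0.42 m/s, 0.3° RMS fixational instability,
    ~100 ms pursuit onset lag, and main-sequence saccades via the duration law
    D = 21 ms + 2.2 ms/deg · A.  Setting ``ms_slope_degps_per_deg`` switches the
    main sequence to the linear regime Vp = min(slope·A, vmax).
    """

    mode: str = "dynamic"  # "static" or "dynamic"
    rate_hz: float = 500.0
    geometry: EyeGeometry = None
    seed: int = 0

    # static mode
    n_static_targets: int = 25
    static_passes: int = 2
    static_fix_ms: tuple[float, float] = (250.0, 450.0)
    target_radius_m: float = 0.008
    workspace: tuple[float, float, float, float] = (-0.25, 0.25, 0.12, 0.55)
    min_target_spacing_m: float = 0.06

    # dynamic mode
    n_trials: int = 32
    objects_move: bool = True  # False: identical trial/saccade structure, no pursuit
    fixation_phase_ms: tuple[float, float] = (500.0, 1000.0)
    object_speed_mps: tuple[float, float] = (0.24, 0.42)
    object_radius_m: float = 0.01
    fixation_circle: tuple[float, float] = (0.0, 0.50)
    fixation_circle_radius_m: float = 0.01
    object_start_y_m: float = 0.50
    object_stop_y_m: float = 0.18
    object_x_m: float = 0.10
    object_x_jitter_m: float = 0.03
    pursuit_ms: tuple[float, float] = (350.0, 800.0)
    pursuit_lag_ms: float = 100.0
    # target/distractor discrimination time before the orienting saccade
    decision_ms: tuple[float, float] = (100.0, 180.0)
    intertrial_ms: float = 250.0
    # fraction of the drift instability retained during pursuit (the pursuit
    # loop closes on the target; its error dynamics are modelled explicitly)
    pursuit_drift_weight: float = 0.2
    # pursuit positional error: gaze trails (or, less often, leads) the target
    # by a slowly wandering offset; magnitude |N(mean, sd)| per segment, clipped
    pursuit_pos_lag_deg: tuple[float, float] = (0.9, 0.7)
    pursuit_pos_lag_max_deg: float = 3.5
    pursuit_lead_prob: float = 0.2
    pursuit_lag_wander_deg: float = 0.15
    # ongoing pursuit gain fluctuation: the eye's speed oscillates around the
    # target's by ±(gain sd)·Ṫ at the given frequency band, so the ripple is
    # proportional to target speed and stays inside the η·Ṫ matching tolerance
    pursuit_gain_sd: float = 0.08
    pursuit_osc_hz: tuple[float, float] = (1.2, 2.5)

    # noise model: slow oculomotor drift (sub-0.5 Hz wander carrying most of the
    # positional RMS, drift velocities ~1-4 deg/s) plus white measurement noise;
    # microsaccades are generated as explicit events during holds
    noise_rms_deg: float = 0.3
    noise_band_hz: float = 0.5
    measurement_noise_deg: float = 0.05
    noise_envelope_sd_log: float = 0.3
    noise_envelope_band_hz: float = 0.5
    microsaccade_rate_hz: float = 2.5
    # lognormal amplitude distribution (median, sd of log), clipped to [0.05, 1.2]
    microsaccade_amp_deg: tuple[float, float] = (0.3, 0.65)
    # primary saccades land off-target with sd = min(frac·A, cap); the pursuit
    # catch-up saccade (dynamic mode) absorbs the error
    landing_error_frac: float = 0.08
    landing_error_cap_deg: float = 0.8
    # per-saccade main-sequence scatter: durations scaled by exp(N(0, sd))
    ms_scatter_log: float = 0.12

    # main sequence
    msd_intercept_ms: float = 21.0
    msd_slope_ms_per_deg: float = 2.2
    ms_slope_degps_per_deg: float = None  # linear-regime alternative
    ms_vmax_degps: float = 700.0

    # artifacts
    blink_rate_hz: float = 0.1
    blink_ms: tuple[float, float] = (80.0, 200.0)
    spike_rate_hz: float = 0.2
    spike_jump_m: float = 0.05
    sentinel: float = DEFAULT_SENTINEL

    def __post_init__(self):
        if self.mode not in ("static", "dynamic"):
            raise ValueError("mode must be 'static' or 'dynamic'")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.noise_rms_deg < 0 or self.measurement_noise_deg < 0:
            raise ValueError("noise levels must be non-negative")
        if self.geometry is None:
            self.geometry = EyeGeometry(0.35)

    def saccade_profile(self, amplitude_deg: float) -> tuple[float, float]:
        """(duration_s, peak_velocity_degps) for a saccade of given amplitude."""
        if self.ms_slope_degps_per_deg is not None:
            vp = min(self.ms_slope_degps_per_deg * amplitude_deg, self.ms_vmax_degps)
            dur = 1.875 * amplitude_deg / vp
        else:
            dur = (self.msd_intercept_ms + self.msd_slope_ms_per_deg * amplitude_deg) / 1000.0
            vp = 1.875 * amplitude_deg / dur
        return dur, vp


@dataclass
class SimulatedSession:
    """A generated session: raw trace, stimulus tracks, and ground truth."""

    trace: GazeTrace
    tracks: list[StimulusTrack]
    labels: np.ndarray          # per-sample ground-truth label
    events: list[GazeEvent]
    scenario: SessionScenario


# ---------------------------------------------------------------------------
# Geometry: gaze directions <-> plane POR
# ---------------------------------------------------------------------------

def _directions_to_plane(d: np.ndarray, geom: EyeGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Intersect unit gaze rays (n, 3, eye frame) with the stimulus plane."""
    d = np.atleast_2d(d)
    h = np.array([0.0, 0.0, geom.height_m])
    dz_plane = d @ geom.r_head[2]          # (R^T d)_z
    hz_plane = float(h @ geom.r_head[2])   # (R^T h)_z
    if np.any(dz_plane <= 1e-12):
        raise ValueError("gaze ray does not intersect the stimulus plane")
    s = hz_plane / dz_plane
    p = (s[:, None] * d - h) @ geom.r_head
    return p[:, 0], p[:, 1]


def angular_to_plane(phi, theta, geom: EyeGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Plane POR hit by gaze directions given as spherical angles (radians).

    Analytic inverse of the plane→eye→spherical pipeline: the forward transform
    applied to the returned (x, y) recovers (ϕ, θ) to round-off.  ϕ = 0 maps to
    the point directly below the eye; rays with ϕ ≥ 90° (parallel to or away
    from the plane) raise.
    """
    d = spherical_to_cartesian(np.ones_like(np.atleast_1d(phi), dtype=float), theta, phi)
    return _directions_to_plane(d, geom)


def _plane_to_directions(x, y, geom: EyeGeometry) -> np.ndarray:
    xyz = plane_to_eye_cartesian(x, y, geom)
    return xyz / np.linalg.norm(xyz, axis=1, keepdims=True)


def _slerp(u0: np.ndarray, u1: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Spherical linear interpolation between unit vectors for fractions s."""
    cosw = float(np.clip(np.dot(u0, u1), -1.0, 1.0))
    w = np.arccos(cosw)
    if w < 1e-12:
        return np.tile(u0, (s.size, 1))
    a = np.sin((1.0 - s) * w) / np.sin(w)
    b = np.sin(s * w) / np.sin(w)
    return a[:, None] * u0 + b[:, None] * u1


def _min_jerk(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1] (zero end velocity/acceleration)."""
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _offset_point(anchor: tuple[float, float], amp_deg: float, direction_rad: float,
                  geom: EyeGeometry) -> tuple[float, float]:
    """Plane point whose gaze direction sits ``amp_deg`` away from the anchor's."""
    u = _plane_to_directions(*anchor, geom)[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    offset = np.tan(np.deg2rad(amp_deg)) * (
        np.cos(direction_rad) * e1 + np.sin(direction_rad) * e2
    )
    d = u + offset
    d /= np.linalg.norm(d)
    x, y = _directions_to_plane(d[None, :], geom)
    return float(x[0]), float(y[0])


# ---------------------------------------------------------------------------
# Trajectory builder
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates plane-coordinate gaze segments with ground-truth labels."""

    def __init__(self, scenario: SessionScenario, rng=None):
        self.sc = scenario
        self.geom = scenario.geometry
        self.rng = rng
        self.dt = 1.0 / scenario.rate_hz
        self.xs: list[np.ndarray] = []
        self.ys: list[np.ndarray] = []
        self.labels: list[str] = []
        self.segments: list[tuple[str, int, int, str | None]] = []
        self.n = 0
        self.cur: tuple[float, float] | None = None

    def _push(self, x: np.ndarray, y: np.ndarray, label: str, target: str | None):
        if x.size == 0:
            return
        self.xs.append(x)
        self.ys.append(y)
        self.segments.append((label, self.n, self.n + x.size - 1, target))
        self.n += x.size
        self.cur = (float(x[-1]), float(y[-1]))

    def hold(self, point: tuple[float, float], n: int, label: str = "fixation",
             target: str | None = None, rng=None):
        """Fixational hold of ``n`` samples, optionally peppered with microsaccades.

        Microsaccades are miniature main-sequence movements around the anchor
        point; they stay part of the fixation (they are not a separate event
        class) but contribute realistic intermediate peaks to the velocity-peak
        distribution.
        """
        sc = self.sc
        if (
            rng is None
            or label != "fixation"
            or sc.microsaccade_rate_hz <= 0
            or n < int(0.15 / self.dt)
        ):
            self._push(np.full(n, point[0]), np.full(n, point[1]), label, target)
            return
        end = self.n + n
        anchor = point
        current = point
        while self.n < end:
            gap = max(
                int(0.05 / self.dt),
                int(rng.exponential(1.0 / sc.microsaccade_rate_hz) / self.dt),
            )
            seg = min(gap, end - self.n)
            self._push(np.full(seg, current[0]), np.full(seg, current[1]), label, target)
            if end - self.n > int(0.06 / self.dt):
                med, sd = sc.microsaccade_amp_deg
                amp = float(np.clip(med * np.exp(sd * rng.standard_normal()), 0.05, 1.2))
                current = _offset_point(anchor, amp, rng.uniform(0, 2 * np.pi), self.geom)
                self.saccade_to(current, label=label, target=target)

    def follow(self, px: np.ndarray, py: np.ndarray, target: str | None):
        self._push(np.asarray(px, float), np.asarray(py, float), "smooth_pursuit", target)

    def saccade_with_error(self, point: tuple[float, float], rng,
                           depart_fn=None) -> tuple[float, float]:
        """Saccade toward ``point`` with a physiological landing error; returns
        the landed POR."""
        sc = self.sc
        u0 = _plane_to_directions(*self.cur, self.geom)[0]
        u1 = _plane_to_directions(*point, self.geom)[0]
        amp = float(np.degrees(np.arccos(np.clip(np.dot(u0, u1), -1, 1))))
        err = abs(rng.normal(0.0, min(sc.landing_error_frac * amp, sc.landing_error_cap_deg)))
        land = _offset_point(point, err, rng.uniform(0, 2 * np.pi), self.geom) if err > 1e-6 else point
        self.saccade_to(land, depart_fn=depart_fn)
        return land

    def _saccade_samples(self, amp: float) -> int:
        dur, _ = self.sc.saccade_profile(amp)
        if self.rng is not None and self.sc.ms_scatter_log > 0:
            dur *= float(np.exp(self.sc.ms_scatter_log * self.rng.standard_normal()))
        return max(3, int(round(dur / self.dt)))

    def saccade_to(self, point: tuple[float, float] | None = None,
                   label: str = "saccade", target: str | None = None,
                   depart_fn=None, arrive_fn=None) -> float:
        """Minimum-jerk saccade from the current POR.

        By default both endpoints are stationary and the gaze direction is
        interpolated along the great circle.  ``depart_fn``/``arrive_fn``
        (sample index -> plane point) describe moving endpoints: the saccade is
        then a minimum-jerk blend between the two paths, so the eye leaves with
        the departure path's velocity and lands with the arrival path's — the
        superposition of a saccade onto ongoing pursuit.
        """
        start = self.cur
        probe = self.n + int(0.03 / self.dt)
        end_est = arrive_fn(probe) if arrive_fn is not None else point
        u0 = _plane_to_directions(*start, self.geom)[0]
        u1 = _plane_to_directions(*end_est, self.geom)[0]
        amp = float(np.degrees(np.arccos(np.clip(np.dot(u0, u1), -1, 1))))
        if amp < 1e-9 and depart_fn is None and arrive_fn is None:
            return 0.0
        n = self._saccade_samples(max(amp, 0.2))
        s = _min_jerk(np.arange(1, n + 1) / n)
        if depart_fn is None and arrive_fn is None:
            d = _slerp(u0, u1, s)
            x, y = _directions_to_plane(d, self.geom)
        else:
            idx = self.n + np.arange(1, n + 1)
            if depart_fn is not None:
                ax, ay = np.array([depart_fn(i) for i in idx]).T
            else:
                ax, ay = np.full(n, start[0]), np.full(n, start[1])
            if arrive_fn is not None:
                bx, by = np.array([arrive_fn(i) for i in idx]).T
            else:
                bx, by = np.full(n, point[0]), np.full(n, point[1])
            x = ax + s * (bx - ax)
            y = ay + s * (by - ay)
        self._push(x, y, label, target)
        return amp

    def finish(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = np.concatenate(self.xs)
        y = np.concatenate(self.ys)
        labels = np.full(self.n, "unclassified", dtype=object)
        for label, s, e, _ in self.segments:
            labels[s : e + 1] = label
        return x, y, labels


# ---------------------------------------------------------------------------
# Noise and artifacts
# ---------------------------------------------------------------------------

def _bandlimited_noise(rng, n: int, rate_hz: float, band_hz: float, rms: float) -> np.ndarray:
    """Low-pass filtered Gaussian noise rescaled to the requested RMS.

    The filter runs on a padded sequence and only the settled interior is kept:
    at sub-hertz cutoffs the filter transient would otherwise dominate the
    trace edges.
    """
    if rms == 0 or n < 30:
        return np.zeros(n)
    pad = int(4.0 * rate_hz / band_hz)
    w = rng.standard_normal(n + 2 * pad)
    b, a = butter(2, band_hz / (rate_hz / 2.0))
    slow = filtfilt(b, a, w)[pad : pad + n]
    sd = slow.std()
    return slow * (rms / sd) if sd > 0 else np.zeros(n)


def _apply_angular_noise(x, y, scenario: SessionScenario, rng,
                         drift_weight=None) -> tuple[np.ndarray, np.ndarray]:
    """Perturb the clean trajectory by instability + measurement noise in angle space.

    ``drift_weight`` scales the slow instability per sample (drift is suppressed
    while the pursuit loop is closed on a target).
    """
    sc = scenario
    n = x.size
    if drift_weight is None:
        drift_weight = np.ones(n)
    xyz = plane_to_eye_cartesian(x, y, sc.geometry)
    rho, theta, phi = cartesian_to_spherical(xyz)
    sin_phi = np.maximum(np.sin(phi), 0.1)
    noise = np.zeros((n, 2))
    if sc.noise_rms_deg > 0:
        slow_rms = np.sqrt(max(sc.noise_rms_deg**2 - sc.measurement_noise_deg**2, 0.0))
        # slow lognormal amplitude envelope: gaze noise is nonstationary, with
        # velocity lognormally distributed over time; normalised to keep the RMS
        if sc.noise_envelope_sd_log > 0:
            g = _bandlimited_noise(
                rng, n, sc.rate_hz, sc.noise_envelope_band_hz, sc.noise_envelope_sd_log
            )
            env = np.exp(g - sc.noise_envelope_sd_log**2)
        else:
            env = 1.0
        for k in range(2):
            noise[:, k] += drift_weight * env * _bandlimited_noise(
                rng, n, sc.rate_hz, sc.noise_band_hz, slow_rms
            )
            noise[:, k] += sc.measurement_noise_deg * rng.standard_normal(n)
    d_phi = np.deg2rad(noise[:, 0])
    d_theta = np.deg2rad(noise[:, 1]) / sin_phi
    return angular_to_plane(np.clip(phi + d_phi, 0.0, np.pi / 2 - 0.05), theta + d_theta,
                            sc.geometry)


def _inject_artifacts(x, y, labels, scenario: SessionScenario, rng):
    """Sentinel-coded blinks and one-sample position spikes; updates labels/valid."""
    sc = scenario
    n = x.size
    valid = np.ones(n, dtype=bool)
    duration_s = n / sc.rate_hz
    n_blinks = rng.poisson(sc.blink_rate_hz * duration_s)
    for _ in range(n_blinks):
        dur = int(rng.uniform(*sc.blink_ms) / 1000.0 * sc.rate_hz)
        start = int(rng.integers(0, max(1, n - dur)))
        end = min(n - 1, start + dur - 1)
        x[start : end + 1] = sc.sentinel
        y[start : end + 1] = sc.sentinel
        labels[start : end + 1] = "blink"
        valid[start : end + 1] = False
    n_spikes = rng.poisson(sc.spike_rate_hz * duration_s)
    for _ in range(n_spikes):
        i = int(rng.integers(1, n - 1))
        if not (valid[i - 1] and valid[i] and valid[i + 1]):
            continue
        ang = rng.uniform(0, 2 * np.pi)
        x[i] += sc.spike_jump_m * np.cos(ang)
        y[i] += sc.spike_jump_m * np.sin(ang)
    return x, y, labels, valid


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

def _ms(scenario, value_ms: float) -> int:
    return max(1, int(round(value_ms / 1000.0 * scenario.rate_hz)))


def _build_static(sc: SessionScenario, rng, b: _Builder) -> list[StimulusTrack]:
    xmin, xmax, ymin, ymax = sc.workspace
    # rejection-sample target positions with a minimum spacing
    pts: list[tuple[float, float]] = []
    while len(pts) < sc.n_static_targets:
        p = (rng.uniform(xmin + 0.02, xmax - 0.02), rng.uniform(ymin + 0.02, ymax - 0.02))
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= sc.min_target_spacing_m for q in pts):
            pts.append(p)
    order = np.concatenate([rng.permutation(len(pts)) for _ in range(sc.static_passes)])

    first = pts[order[0]]
    b.cur = first
    b.hold(first, _ms(sc, rng.uniform(*sc.static_fix_ms)), "fixation", f"T{order[0]:02d}", rng=rng)
    prev = order[0]
    for k in order[1:]:
        if k == prev:
            continue
        land = b.saccade_with_error(pts[k], rng)
        b.hold(land, _ms(sc, rng.uniform(*sc.static_fix_ms)), "fixation", f"T{k:02d}", rng=rng)
        prev = k

    n = b.n
    t = np.arange(n) * 1000.0 / sc.rate_hz
    return [
        StimulusTrack(
            f"T{k:02d}", t, np.full(n, p[0]), np.full(n, p[1]),
            np.full(n, sc.target_radius_m),
        )
        for k, p in enumerate(pts)
    ]


def _pursuit_path(sc: SessionScenario, rng, obj_xy, t_app: int, move_n: int):
    """Gaze path while pursuing a moving object: the target track plus a slowly
    wandering positional lag (gaze trails the target along its motion, or leads
    it with probability ``pursuit_lead_prob``)."""
    lag0 = min(abs(rng.normal(*sc.pursuit_pos_lag_deg)), sc.pursuit_pos_lag_max_deg)
    if rng.random() < sc.pursuit_lead_prob:
        lag0 = -0.5 * lag0
    freq = rng.uniform(0.3, 0.8)
    phase = rng.uniform(0, 2 * np.pi)
    osc_f = rng.uniform(*sc.pursuit_osc_hz)
    osc_phase = rng.uniform(0, 2 * np.pi)
    jmid = move_n // 2
    xyz = plane_to_eye_cartesian(obj_xy[0][jmid], obj_xy[1][jmid], sc.geometry)[0]
    rho = float(np.linalg.norm(xyz))
    eps = float(np.arcsin(xyz[2] / rho))
    m_per_deg = np.deg2rad(1.0) * rho / np.sin(eps)

    # target angular speed along the track (deg/s), for gain-proportional ripple
    xyz_all = plane_to_eye_cartesian(obj_xy[0], obj_xy[1], sc.geometry)
    u = xyz_all / np.linalg.norm(xyz_all, axis=1, keepdims=True)
    dots = np.clip((u[1:] * u[:-1]).sum(axis=1), -1, 1)
    ang_speed = np.degrees(np.arccos(dots)) * sc.rate_hz
    ang_speed = np.append(ang_speed, ang_speed[-1])

    def fn(i: int) -> tuple[float, float]:
        j = int(np.clip(i - t_app, 0, move_n - 1))
        t = i / sc.rate_hz
        osc_amp = sc.pursuit_gain_sd * ang_speed[j] / (2 * np.pi * osc_f)
        lag = (
            lag0
            + sc.pursuit_lag_wander_deg * np.sin(2 * np.pi * freq * t + phase)
            + osc_amp * np.sin(2 * np.pi * osc_f * t + osc_phase)
        )
        # targets move toward the participant (-y): positive lag trails behind
        return float(obj_xy[0][j]), float(obj_xy[1][j] + lag * m_per_deg)

    return fn


def _build_dynamic(sc: SessionScenario, rng, b: _Builder) -> list[StimulusTrack]:
    # three persistent tracks: the fixation circle and two moving objects
    tids = ("FIX", "OBJ_L", "OBJ_R")
    track_x = {tid: [] for tid in tids}
    track_y = {tid: [] for tid in tids}
    track_active = {tid: [] for tid in tids}
    radius = {"FIX": sc.fixation_circle_radius_m, "OBJ_L": sc.object_radius_m,
              "OBJ_R": sc.object_radius_m}
    sides = [("OBJ_L", -sc.object_x_m), ("OBJ_R", sc.object_x_m)]  # updated per trial
    cx, cy = sc.fixation_circle

    def park(n, fix_active=False):
        """Extend all tracks by n held samples (objects inactive)."""
        if n <= 0:
            return
        for tid in tids:
            last_x = track_x[tid][-1][-1] if track_x[tid] else dict(sides).get(tid, cx)
            last_y = track_y[tid][-1][-1] if track_y[tid] else (
                cy if tid == "FIX" else sc.object_start_y_m
            )
            track_x[tid].append(np.full(n, last_x))
            track_y[tid].append(np.full(n, last_y))
            track_active[tid].append(np.full(n, fix_active if tid == "FIX" else False,
                                             dtype=bool))

    def track_len() -> int:
        return sum(a.size for a in track_x["FIX"])

    dt = b.dt
    b.cur = (cx, cy)
    for trial in range(sc.n_trials):
        # --- fixation phase: circle active, gaze fixates it ---------------
        fix_n = _ms(sc, rng.uniform(*sc.fixation_phase_ms))
        park(b.n - track_len())
        park(fix_n, fix_active=True)
        b.hold(b.cur, fix_n, "fixation", "FIX", rng=rng)

        # --- objects appear and approach the participant -------------------
        speed = rng.uniform(*sc.object_speed_mps)
        ox_mag = sc.object_x_m + rng.uniform(-sc.object_x_jitter_m, sc.object_x_jitter_m)
        sides = [("OBJ_L", -ox_mag), ("OBJ_R", ox_mag)]
        move_n = int((sc.object_start_y_m - sc.object_stop_y_m) / speed / dt)
        t_app = b.n
        obj_pos = {}
        for tid, ox in sides:
            if sc.objects_move:
                ys = sc.object_start_y_m - speed * dt * np.arange(move_n)
            else:
                ys = np.full(move_n, sc.object_start_y_m)
            track_x[tid].append(np.full(move_n, ox))
            track_y[tid].append(ys)
            track_active[tid].append(np.ones(move_n, dtype=bool))
            obj_pos[tid] = (np.full(move_n, ox), ys)
        track_x["FIX"].append(np.full(move_n, cx))
        track_y["FIX"].append(np.full(move_n, cy))
        track_active["FIX"].append(np.zeros(move_n, dtype=bool))
        last_active = t_app + move_n - 1

        def obj_at(tid, i):
            j = int(np.clip(i - t_app, 0, move_n - 1))
            return float(obj_pos[tid][0][j]), float(obj_pos[tid][1][j])

        # gaze keeps fixating while the objects are discriminated
        b.hold(b.cur, _ms(sc, sc.pursuit_lag_ms + rng.uniform(*sc.decision_ms)),
               "fixation", "FIX", rng=rng)

        # one object is tracked per trial (alternating sides); the other keeps
        # moving, so the classifier still faces a multi-target scene
        tid = ("OBJ_L", "OBJ_R")[trial % 2]
        prev_path_fn = None
        # primary saccade programmed from the object's position at saccade
        # onset (retinal snapshot) with ~10% undershoot; the object keeps
        # moving during the saccade and post-saccadic hold, so the later
        # catch-up saccade is a few degrees
        sx, sy = obj_at(tid, b.n)
        gx_, gy_ = b.cur
        land = (gx_ + 0.9 * (sx - gx_), gy_ + 0.9 * (sy - gy_))
        b.saccade_with_error(land, rng)
        # short post-saccadic fixation while the pursuit system engages
        b.hold(b.cur, _ms(sc, sc.pursuit_lag_ms), "fixation", tid)
        if sc.objects_move:
            pursue_fn = _pursuit_path(sc, rng, obj_pos[tid], t_app, move_n)
            # catch-up saccade blending onto the (lagging) pursuit path so
            # the eye lands already moving at target velocity
            b.saccade_to(arrive_fn=pursue_fn)
            p_n = min(_ms(sc, rng.uniform(*sc.pursuit_ms)), last_active - b.n - 5)
            if p_n >= _ms(sc, 60):
                pts = np.array([pursue_fn(i) for i in b.n + np.arange(p_n)])
                b.follow(pts[:, 0], pts[:, 1], tid)
                prev_path_fn = pursue_fn
        else:
            # fixation-only variant: refixation jump of matched amplitude
            # keeps the saccade populations of the two variants identical
            ox_, oy_ = obj_at(tid, b.n)
            gap_m = speed * (sc.pursuit_lag_ms + 85.0) / 1000.0
            ang = rng.uniform(0, 2 * np.pi)
            b.saccade_to((ox_ + gap_m * np.cos(ang), oy_ + gap_m * np.sin(ang)))
            p_n = min(_ms(sc, rng.uniform(*sc.pursuit_ms)), last_active - b.n - 5)
            if p_n >= _ms(sc, 60):
                b.hold(b.cur, p_n, "fixation", tid, rng=rng)

        # --- return saccade to the circle, then inter-trial hold -----------
        b.saccade_with_error((cx, cy), rng, depart_fn=prev_path_fn)
        end_n = max(track_len(), b.n) + _ms(sc, sc.intertrial_ms)
        b.hold(b.cur, end_n - b.n, "fixation", None, rng=rng)
        park(end_n - track_len())
        # teleport objects back to their start while inactive
        for tid, ox in sides:
            track_x[tid].append(np.array([ox]))
            track_y[tid].append(np.array([sc.object_start_y_m]))
            track_active[tid].append(np.array([False]))
        track_x["FIX"].append(np.array([cx]))
        track_y["FIX"].append(np.array([cy]))
        track_active["FIX"].append(np.array([False]))
        b.hold(b.cur, 1, "fixation", None)

    park(b.n - track_len())
    n = b.n
    t = np.arange(n) * 1000.0 / sc.rate_hz
    tracks = []
    for tid in tids:
        x = np.concatenate(track_x[tid])[:n]
        y = np.concatenate(track_y[tid])[:n]
        act = np.concatenate(track_active[tid])[:n]
        tracks.append(StimulusTrack(tid, t, x, y, np.full(n, radius[tid]), "circle", act))
    return tracks


def simulate_session(scenario: SessionScenario) -> SimulatedSession:
    """Generate a synthetic session with exact per-sample ground truth.

    Raises when the configured segment durations fall below the classifier's
    minimum event durations (such a session could not carry valid labels).
    """
    sc = scenario
    if sc.static_fix_ms[0] < 40 or (sc.mode == "dynamic" and sc.pursuit_ms[0] < 40):
        raise ValueError("scenario durations shorter than minimum event durations")
    rng = np.random.default_rng(sc.seed)
    b = _Builder(sc, rng=rng)
    if sc.mode == "static":
        tracks = _build_static(sc, rng, b)
    else:
        tracks = _build_dynamic(sc, rng, b)
    x, y, labels = b.finish()
    if sc.noise_rms_deg > 0 or sc.measurement_noise_deg > 0:
        weight = np.where(labels == "smooth_pursuit", sc.pursuit_drift_weight, 1.0)
        x, y = _apply_angular_noise(x, y, sc, rng, drift_weight=weight)
    x, y, labels, valid = _inject_artifacts(x.copy(), y.copy(), labels, sc, rng)
    t = np.arange(x.size) * 1000.0 / sc.rate_hz
    trace = GazeTrace(t, x, y, valid=valid, rate_hz=sc.rate_hz)
    events = labels_to_events(labels, t)
    # truncate tracks defensively to the gaze length (they are built to match)
    for tr in tracks:
        assert len(tr) == len(trace)
    return SimulatedSession(trace, tracks, labels, events, sc)
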