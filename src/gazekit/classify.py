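"""Rule-based gaze-event classification: pursuits, saccades, fixations.

Saccades are velocity peaks exceeding the adaptive saccade velocity threshold whose
peak acceleration also exceeds the acceleration threshold and whose duration is at
least 5 ms; their extent runs between the velocity minima flanking the peak.  Static
tasks then label fixations: maximal sub-threshold runs whose POR stays within the
foveal visual circle plus target radius of a static stimulus for at least 40 ms.

Dynamic tasks classify smooth pursuits first (fixations being rare when all stimuli
move), then saccades, then post-saccadic fixations.  A pursuit requires, continuously
for at least 40 ms and for one target:

    ‖G − T‖ ≤ (1 + η)(FVR + T_R)          position match (gaze may lag or lead)
    |v − Ṫ| ≤ η·Ṫ                         angular-speed match
    v < v_thr,  v̇ < a_thr                 sub-saccadic kinematics

with η the noise-tolerance coefficient (default 0.2) and Ṫ the target's angular speed
through the same plane→eye→spherical pipeline.  Post-saccadic fixations are sought
within 100 ms of each saccade offset: sub-saccadic samples where the target is pulling
away from a stationary gaze (Ṫ > η·v and T̈ > η·v̇), ending at the first violation,
and whose gaze convex hull stays within η·π·FVR² of the starting foveal circle.

A fixed-threshold two-class baseline (0.3°, 30°/s, 8000°/s², the commercial parser's
settings) is provided for comparison; it knows nothing about pursuits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from gazekit.io_preprocess import StimulusTrack, _runs
from gazekit.kinematics import (
    DEG,
    SphericalKinematics,
    eye_cartesian_to_plane,
    plane_to_eye_cartesian,
    spherical_kinematics,
)

LABELS = ("fixation", "saccade", "smooth_pursuit", "blink", "unclassified")


@dataclass
class ClassifierConfig:
    """Tunable parameters of the event classifier.

    ``eta`` expands the spatial and velocity tolerances against noise; ``delta_deg``
    is the foveal visual angle defining the FVR.  Minimum durations follow the
    oculomotor literature: saccades 5 ms, fixations and pursuits 40 ms.  ``v_thr``
    and ``a_thr`` come from a fitted :class:`~gazekit.thresholds.ThresholdModel`.
    ``pursuit_floor_degps`` guards the relative speed-match tolerance for nearly
    static targets (tolerance = η·max(Ṫ, floor)).
    """

    v_thr: float
    a_thr: float = 6000.0
    eta: float = 0.2
    delta_deg: float = 3.0
    min_saccade_ms: float = 5.0
    min_fixation_ms: float = 40.0
    min_pursuit_ms: float = 40.0
    post_saccade_fixation_window_ms: float = 100.0
    pursuit_floor_degps: float = 10.0
    merge_gap_ms: float = 0.0

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        for name in ("min_saccade_ms", "min_fixation_ms", "min_pursuit_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GazeEvent:
    """A labelled, inclusive sample interval with per-event metrics."""

    label: str
    onset_idx: int
    offset_idx: int
    onset_ms: float
    offset_ms: float
    target_id: str | None = None
    peak_v: float = np.nan
    peak_a: float = np.nan
    amplitude_deg: float = np.nan

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown event label {self.label!r}")
        if self.onset_idx > self.offset_idx:
            raise ValueError("event onset after offset")

    @property
    def n_samples(self) -> int:
        return self.offset_idx - self.onset_idx + 1

    def duration_ms(self, rate_hz: float) -> float:
        return self.n_samples * 1000.0 / rate_hz


# ---------------------------------------------------------------------------
# Event/label conversions and I/O
# ---------------------------------------------------------------------------

def events_to_labels(events: list[GazeEvent], n: int) -> np.ndarray:
    """Per-sample label array; samples not covered by any event are unclassified."""
    labels = np.full(n, "unclassified", dtype=object)
    for ev in events:
        labels[ev.onset_idx : ev.offset_idx + 1] = ev.label
    return labels


def labels_to_events(labels: np.ndarray, t: np.ndarray) -> list[GazeEvent]:
    """Maximal same-label runs as events (unclassified runs included)."""
    labels = np.asarray(labels, dtype=object)
    events = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            events.append(
                GazeEvent(str(labels[start]), start, i - 1, float(t[start]), float(t[i - 1]))
            )
            start = i
    return events


def write_events(events: list[GazeEvent], path) -> None:
    pd.DataFrame(
        {
            "label": [e.label for e in events],
            "onset_ms": [e.onset_ms for e in events],
            "offset_ms": [e.offset_ms for e in events],
            "target_id": [e.target_id if e.target_id is not None else "" for e in events],
            "peak_v_degps": [e.peak_v for e in events],
            "peak_a_degps2": [e.peak_a for e in events],
            "amplitude_deg": [e.amplitude_deg for e in events],
        }
    ).to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Saccade detection
# ---------------------------------------------------------------------------

def _delimit_saccade(v: np.ndarray, peak: int) -> tuple[int, int]:
    """Extent of the saccade containing the velocity peak.

    Walks outward to the flanking local minima of v (the sign change of v̇); the
    saccade starts on the first sample after the pre-peak minimum and ends on the
    last sample before the post-peak minimum, so the minima themselves belong to
    the neighbouring events.
    """
    n = v.size
    i = peak
    while i - 1 >= 0 and v[i - 1] < v[i]:
        i -= 1
    onset = i if i == 0 else min(i + 1, max(peak - 1, i))
    j = peak
    while j + 1 < n and v[j + 1] < v[j]:
        j += 1
    offset = j if j == n - 1 else max(j - 1, min(peak + 1, j))
    return onset, offset


def _angular_amplitude(kin: SphericalKinematics, onset: int, offset: int) -> float:
    u = kin.unit_gaze()
    c = float(np.clip(np.dot(u[onset], u[offset]), -1.0, 1.0))
    return float(np.arccos(c) * DEG)


def detect_saccades(kin: SphericalKinematics, cfg: ClassifierConfig) -> list[GazeEvent]:
    """Saccade events from supra-threshold velocity peaks.

    Each candidate peak above ``v_thr`` is delimited by its flanking velocity
    minima; it is kept when the peak acceleration within the interval exceeds
    ``a_thr`` and the duration is at least the minimum saccade duration.
    Overlapping candidates are merged.  Peaks on repaired (blink) samples are
    ignored.
    """
    v, a = kin.v, kin.a
    n = v.size
    above = v > cfg.v_thr
    peaks = [
        i
        for i in range(1, n - 1)
        if above[i] and v[i] >= v[i - 1] and v[i] > v[i + 1] and kin.valid[i]
    ]
    intervals = []
    for p in peaks:
        onset, offset = _delimit_saccade(v, p)
        intervals.append([onset, offset, p])
    # merge overlapping candidate extents (double-peaked saccades)
    merged: list[list[int]] = []
    for onset, offset, p in sorted(intervals):
        if merged and onset <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], offset)
            if v[p] > v[merged[-1][2]]:
                merged[-1][2] = p
        else:
            merged.append([onset, offset, p])

    min_samples = max(1, int(round(cfg.min_saccade_ms * kin.rate_hz / 1000.0)))
    events = []
    for onset, offset, p in merged:
        if offset - onset + 1 < min_samples:
            continue
        peak_a = float(np.max(a[onset : offset + 1]))
        if peak_a <= cfg.a_thr:
            continue
        events.append(
            GazeEvent(
                "saccade", onset, offset, float(kin.t[onset]), float(kin.t[offset]),
                peak_v=float(v[p]), peak_a=peak_a,
                amplitude_deg=_angular_amplitude(kin, onset, offset),
            )
        )
    return events


# ---------------------------------------------------------------------------
# Target kinematics and geometry helpers
# ---------------------------------------------------------------------------

def target_kinematics(track: StimulusTrack, kin: SphericalKinematics) -> SphericalKinematics:
    """Angular kinematics of a stimulus target through the same pipeline as gaze."""
    if track.t.size != kin.t.size or np.max(np.abs(track.t - kin.t)) > 1e-6:
        raise ValueError(
            f"target track {track.target_id!r} does not share the gaze time base"
        )
    xyz = plane_to_eye_cartesian(track.x, track.y, kin.geom)
    return spherical_kinematics(
        xyz, kin.rate_hz, t=kin.t, sg_window_ms=kin.sg_window_ms,
        sg_order=kin.sg_order, geom=kin.geom,
    )


def _gaze_plane_xy(kin: SphericalKinematics) -> tuple[np.ndarray, np.ndarray]:
    return eye_cartesian_to_plane(kin.xyz, kin.geom)


def _require_fvr(kin: SphericalKinematics, cfg: ClassifierConfig) -> np.ndarray:
    if kin.fvr is not None:
        return kin.fvr
    from gazekit.kinematics import fvr_series

    return fvr_series(kin.xyz, cfg.delta_deg, kin.geom)


def _blink_events(kin: SphericalKinematics) -> list[GazeEvent]:
    return [
        GazeEvent("blink", s, e, float(kin.t[s]), float(kin.t[e]))
        for s, e in _runs(~kin.valid)
    ]


def _claim(mask: np.ndarray, events: list[GazeEvent]) -> None:
    for ev in events:
        mask[ev.onset_idx : ev.offset_idx + 1] = True


def _trim_saccades(
    events: list[GazeEvent], claimed: np.ndarray, kin: SphericalKinematics,
    cfg: ClassifierConfig,
) -> list[GazeEvent]:
    """Clip saccade extents to the free run containing each peak.

    Keeps saccade events disjoint from already-claimed samples (blinks,
    pursuits); a candidate whose peak is claimed, or whose clipped extent falls
    below the minimum saccade duration, is dropped.
    """
    min_samples = max(1, int(round(cfg.min_saccade_ms * kin.rate_hz / 1000.0)))
    out = []
    for ev in events:
        peak = ev.onset_idx + int(np.argmax(kin.v[ev.onset_idx : ev.offset_idx + 1]))
        if claimed[peak]:
            continue
        onset, offset = peak, peak
        while onset - 1 >= ev.onset_idx and not claimed[onset - 1]:
            onset -= 1
        while offset + 1 <= ev.offset_idx and not claimed[offset + 1]:
            offset += 1
        if offset - onset + 1 < min_samples:
            continue
        out.append(
            GazeEvent(
                "saccade", onset, offset, float(kin.t[onset]), float(kin.t[offset]),
                peak_v=float(np.max(kin.v[onset : offset + 1])),
                peak_a=float(np.max(kin.a[onset : offset + 1])),
                amplitude_deg=_angular_amplitude(kin, onset, offset),
            )
        )
    return out


def _finalize(events: list[GazeEvent]) -> list[GazeEvent]:
    return sorted(events, key=lambda e: e.onset_idx)


# ---------------------------------------------------------------------------
# Static-task classification (fixations after saccades)
# ---------------------------------------------------------------------------

def classify_static_task(
    kin: SphericalKinematics,
    targets: list[StimulusTrack] | None,
    cfg: ClassifierConfig,
) -> list[GazeEvent]:
    """Saccades then fixations against static stimuli.

    Fixations are maximal non-saccade runs with sub-threshold velocity and
    acceleration whose POR stays within ``FVR + T_R`` of a static target for at
    least the minimum fixation duration; each is bound to the nearest qualifying
    target.  Without targets, fixations fall back to a velocity-plus-dispersion
    rule (gaze confined to one foveal circle) and carry no target binding.
    """
    n = len(kin)
    fvr = _require_fvr(kin, cfg)
    blink = ~kin.valid
    saccades = _trim_saccades(detect_saccades(kin, cfg), blink, kin, cfg)
    claimed = blink.copy()
    _claim(claimed, saccades)

    quiet = (kin.v < cfg.v_thr) & (kin.a < cfg.a_thr) & ~claimed
    gx, gy = _gaze_plane_xy(kin)
    min_samples = max(1, int(round(cfg.min_fixation_ms * kin.rate_hz / 1000.0)))

    fixations: list[GazeEvent] = []
    if targets:
        dists = np.full((len(targets), n), np.inf)
        for k, tr in enumerate(targets):
            if tr.t.size != n or np.max(np.abs(tr.t - kin.t)) > 1e-6:
                raise ValueError(
                    f"target track {tr.target_id!r} does not share the gaze time base"
                )
            d = np.hypot(gx - tr.x, gy - tr.y)
            ok = tr.active & (d <= fvr + tr.radius_m)
            dists[k, ok] = d[ok]
        eligible = quiet & np.isfinite(dists.min(axis=0))
        for s, e in _runs(eligible):
            if e - s + 1 < min_samples:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean_d = np.nanmean(
                    np.where(np.isfinite(dists[:, s : e + 1]), dists[:, s : e + 1], np.nan),
                    axis=1,
                )
            mean_d = np.where(np.isnan(mean_d), np.inf, mean_d)
            k = int(np.argmin(mean_d))
            fixations.append(
                GazeEvent(
                    "fixation", s, e, float(kin.t[s]), float(kin.t[e]),
                    target_id=targets[k].target_id,
                    peak_v=float(np.max(kin.v[s : e + 1])),
                    peak_a=float(np.max(kin.a[s : e + 1])),
                )
            )
    else:
        warnings.warn(
            "no stimulus targets supplied: classifying target-free fixations "
            "by velocity and dispersion only",
            stacklevel=2,
        )
        for s, e in _runs(quiet):
            if e - s + 1 < min_samples:
                continue
            cx, cy = np.mean(gx[s : e + 1]), np.mean(gy[s : e + 1])
            spread = np.max(np.hypot(gx[s : e + 1] - cx, gy[s : e + 1] - cy))
            if spread <= np.mean(fvr[s : e + 1]):
                fixations.append(
                    GazeEvent(
                        "fixation", s, e, float(kin.t[s]), float(kin.t[e]),
                        peak_v=float(np.max(kin.v[s : e + 1])),
                        peak_a=float(np.max(kin.a[s : e + 1])),
                    )
                )
    return _finalize(saccades + fixations + _blink_events(kin))


# ---------------------------------------------------------------------------
# Dynamic-task classification (pursuits, then saccades, then fixations)
# ---------------------------------------------------------------------------

def _convex_hull_area(px: np.ndarray, py: np.ndarray) -> float:
    pts = np.column_stack([px, py])
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D: volume is the area
    except QhullError:
        return 0.0  # collinear points enclose no area


def classify_dynamic_task(
    kin: SphericalKinematics,
    targets: list[StimulusTrack],
    cfg: ClassifierConfig,
) -> list[GazeEvent]:
    """Pursuits first, then saccades, then post-saccadic fixations.

    Target angular kinematics are computed through the identical transform and
    differentiation pipeline as the gaze.  See the module docstring for the rule
    set; samples claimed by no rule remain unclassified, repaired blink intervals
    are labelled blink and excluded from every rule.
    """
    if not targets:
        raise ValueError("dynamic classification requires stimulus tracks")
    n = len(kin)
    fvr = _require_fvr(kin, cfg)
    blink = ~kin.valid
    gx, gy = _gaze_plane_xy(kin)

    tkins = [target_kinematics(tr, kin) for tr in targets]
    dists = np.stack([np.hypot(gx - tr.x, gy - tr.y) for tr in targets])

    quiet = (kin.v < cfg.v_thr) & (kin.a < cfg.a_thr) & ~blink

    # --- 1. smooth pursuits -------------------------------------------------
    eligible = np.zeros((len(targets), n), dtype=bool)
    for k, (tr, tk) in enumerate(zip(targets, tkins)):
        pos_ok = dists[k] <= (1.0 + cfg.eta) * (fvr + tr.radius_m)
        vel_tol = cfg.eta * np.maximum(tk.v, cfg.pursuit_floor_degps)
        vel_ok = np.abs(kin.v - tk.v) <= vel_tol
        eligible[k] = tr.active & pos_ok & vel_ok & quiet

    any_eligible = eligible.any(axis=0)
    masked = np.where(eligible, dists, np.inf)
    best = np.argmin(masked, axis=0)  # ties -> lowest target index / target_id order

    min_pursuit = max(1, int(round(cfg.min_pursuit_ms * kin.rate_hz / 1000.0)))
    pursuits: list[GazeEvent] = []
    for s, e in _runs(any_eligible):
        # split where the bound target changes
        seg_start = s
        for i in range(s + 1, e + 2):
            if i > e or best[i] != best[seg_start]:
                if i - seg_start >= min_pursuit:
                    k = int(best[seg_start])
                    pursuits.append(
                        GazeEvent(
                            "smooth_pursuit", seg_start, i - 1,
                            float(kin.t[seg_start]), float(kin.t[i - 1]),
                            target_id=targets[k].target_id,
                            peak_v=float(np.max(kin.v[seg_start:i])),
                            peak_a=float(np.max(kin.a[seg_start:i])),
                        )
                    )
                seg_start = i

    claimed = blink.copy()
    _claim(claimed, pursuits)

    # --- 2. saccades on unclaimed samples ----------------------------------
    saccades = _trim_saccades(detect_saccades(kin, cfg), claimed, kin, cfg)
    _claim(claimed, saccades)

    # --- 3. post-saccadic fixations -----------------------------------------
    window = max(1, int(round(cfg.post_saccade_fixation_window_ms * kin.rate_hz / 1000.0)))
    min_fix = max(1, int(round(cfg.min_fixation_ms * kin.rate_hz / 1000.0)))
    fixations: list[GazeEvent] = []
    active_any = np.stack([tr.active for tr in targets]).any(axis=0)
    for sac in sorted(saccades, key=lambda e: e.onset_idx):
        limit = min(n - 1, sac.offset_idx + window)
        start = None
        for i in range(sac.offset_idx + 1, limit + 1):
            if claimed[i] or not active_any[i] or not quiet[i]:
                continue
            cand = [k for k in range(len(targets)) if targets[k].active[i]]
            k = min(cand, key=lambda kk: dists[kk, i])
            tk = tkins[k]
            if tk.v[i] > cfg.eta * kin.v[i] and tk.a[i] > cfg.eta * kin.a[i]:
                start = i
                break
        if start is None:
            continue
        end = start
        while end < n and not claimed[end]:
            if not quiet[end]:
                break
            if not (tk.v[end] > cfg.eta * kin.v[end] and tk.a[end] > cfg.eta * kin.a[end]):
                break
            end += 1
        end -= 1  # last satisfying sample
        if end - start + 1 < min_fix:
            continue
        hull = _convex_hull_area(gx[start : end + 1], gy[start : end + 1])
        if hull > cfg.eta * np.pi * fvr[start] ** 2:
            continue
        fixations.append(
            GazeEvent(
                "fixation", start, end, float(kin.t[start]), float(kin.t[end]),
                target_id=targets[k].target_id,
                peak_v=float(np.max(kin.v[start : end + 1])),
                peak_a=float(np.max(kin.a[start : end + 1])),
            )
        )
        claimed[start : end + 1] = True

    return _finalize(pursuits + saccades + fixations + _blink_events(kin))


# ---------------------------------------------------------------------------
# Fixed-threshold baseline
# ---------------------------------------------------------------------------

def baseline_fixed_threshold(
    kin: SphericalKinematics,
    disp_deg: float = 0.3,
    v_thr: float = 30.0,
    a_thr: float = 8000.0,
) -> list[GazeEvent]:
    """Two-class fixed-threshold comparator (saccade/fixation only).

    Supra-threshold velocity runs whose peak acceleration exceeds ``a_thr`` and
    whose angular displacement exceeds ``disp_deg`` are saccades; everything else
    is fixation.  Slow smooth pursuits fall below the 30 deg/s velocity threshold
    and are therefore labelled fixation by this baseline.
    """
    n = len(kin)
    is_saccade = np.zeros(n, dtype=bool)
    for s, e in _runs(kin.v > v_thr):
        if np.max(kin.a[s : e + 1]) > a_thr and _angular_amplitude(kin, s, e) > disp_deg:
            is_saccade[s : e + 1] = True
    events = []
    for s, e in _runs(is_saccade):
        events.append(
            GazeEvent(
                "saccade", s, e, float(kin.t[s]), float(kin.t[e]),
                peak_v=float(np.max(kin.v[s : e + 1])),
                peak_a=float(np.max(kin.a[s : e + 1])),
                amplitude_deg=_angular_amplitude(kin, s, e),
            )
        )
    for s, e in _runs(~is_saccade):
        events.append(
            GazeEvent(
                "fixation", s, e, float(kin.t[s]), float(kin.t[e]),
                peak_v=float(np.max(kin.v[s : e + 1])),
                peak_a=float(np.max(kin.a[s : e + 1])),
            )
        )
    return _finalize(events)
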