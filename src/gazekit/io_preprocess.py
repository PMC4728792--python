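"""Reading, artifact repair and filtering of planar gaze point-of-regard logs.

Gaze logs are delimited text with columns ``t_ms,x_m,y_m,pupil,valid``.  Trackers code
lost-pupil samples (blinks) with a sentinel value (conventionally -100) in both POR
coordinates.  The preprocessing chain is: detect artifacts (blinks, screen outliers,
one-sample corneal-reflection spikes), repair them (cubic spline across blink/outlier
gaps fitted to the five flanking valid samples on each side; spikes replaced by the
closer neighbour), zero-phase low-pass filter at 20 Hz, and optionally resample to a
uniform target rate.  Times are in milliseconds, positions in metres throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

DEFAULT_SENTINEL = -100.0

_ARTIFACT_KINDS = ("blink", "outlier", "spike")


@dataclass
class GazeTrace:
    """Uniformly sampled POR time series in plane coordinates.

    Attributes
    ----------
    t : ndarray
        Sample times in ms, strictly increasing with a constant step of
        ``1000 / rate_hz``.
    x, y : ndarray
        POR coordinates in the stimulus plane (m).
    pupil : ndarray
        Pupil size in arbitrary tracker units (NaN where unavailable).
    valid : ndarray of bool
        False on samples that were sentinel-coded or interpolated during repair.
    rate_hz : float
        Sampling rate.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray = None
    valid: np.ndarray = None
    rate_hz: float = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.t.size
        if self.x.size != n or self.y.size != n:
            raise ValueError("t, x, y must have equal length")
        if n < 2:
            raise ValueError("trace needs at least two samples")
        if self.pupil is None:
            self.pupil = np.full(n, np.nan)
        else:
            self.pupil = np.asarray(self.pupil, dtype=float)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.rate_hz is None:
            self.rate_hz = 1000.0 / float(np.median(steps))
        dt = 1000.0 / self.rate_hz
        if np.max(np.abs(steps - dt)) > 1e-6:
            raise ValueError("trace is not uniformly sampled at rate_hz")

    def __len__(self):
        return self.t.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    def copy(self) -> "GazeTrace":
        return GazeTrace(
            self.t.copy(), self.x.copy(), self.y.copy(),
            self.pupil.copy(), self.valid.copy(), self.rate_hz,
        )


@dataclass
class StimulusTrack:
    """Per-target time series of position and circumscribing radius in the plane.

    ``radius_m`` is the radius of the smallest circle circumscribing the stimulus
    shape; ``active`` flags samples on which the target is displayed.
    """

    target_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    radius_m: np.ndarray
    shape: str = "circle"
    active: np.ndarray = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.radius_m = np.broadcast_to(
            np.asarray(self.radius_m, dtype=float), self.t.shape
        ).copy()
        if self.active is None:
            self.active = np.ones(self.t.size, dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool)
        if np.any(self.radius_m[self.active] <= 0):
            raise ValueError("circumscribing radius must be positive while active")
        if not np.all(np.isfinite(self.x[self.active])) or not np.all(
            np.isfinite(self.y[self.active])
        ):
            raise ValueError("target positions must be finite while active")

    def __len__(self):
        return self.t.size


@dataclass(frozen=True)
class ArtifactInterval:
    """Inclusive sample-index interval labelled with its artifact class."""

    start: int
    end: int
    kind: str

    def __post_init__(self):
        if self.kind not in _ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError("artifact interval start > end")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gaze_log(path, unit: str = "m", sep: str = ",") -> GazeTrace:
    """Read a gaze log (columns ``t_ms,x_m,y_m,pupil,valid``; header required).

    ``unit='mm'`` divides positions by 1000 on input; sentinel values are never
    rescaled (they are magic numbers, not positions).
    """
    df = pd.read_csv(path, sep=sep)
    required = {"t_ms", "x_m", "y_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gaze log missing columns: {sorted(missing)}")
    x = df["x_m"].to_numpy(float)
    y = df["y_m"].to_numpy(float)
    if unit == "mm":
        sentinel_mask = (x == DEFAULT_SENTINEL) & (y == DEFAULT_SENTINEL)
        x = np.where(sentinel_mask, x, x / 1000.0)
        y = np.where(sentinel_mask, y, y / 1000.0)
    elif unit != "m":
        raise ValueError("unit must be 'm' or 'mm'")
    pupil = df["pupil"].to_numpy(float) if "pupil" in df.columns else None
    valid = df["valid"].to_numpy(bool) if "valid" in df.columns else None
    return GazeTrace(df["t_ms"].to_numpy(float), x, y, pupil, valid)


def write_gaze_log(trace: GazeTrace, path) -> None:
    pd.DataFrame(
        {
            "t_ms": trace.t,
            "x_m": trace.x,
            "y_m": trace.y,
            "pupil": trace.pupil,
            "valid": trace.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_stimulus_tracks(path, sep: str = ",") -> list[StimulusTrack]:
    """Read stimulus tracks (columns ``t_ms,target_id,x_m,y_m,radius_m,shape,active``)."""
    df = pd.read_csv(path, sep=sep)
    required = {"t_ms", "target_id", "x_m", "y_m", "radius_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stimulus track missing columns: {sorted(missing)}")
    tracks = []
    for tid, g in df.groupby("target_id", sort=True):
        g = g.sort_values("t_ms")
        shape = str(g["shape"].iloc[0]) if "shape" in g.columns else "circle"
        active = g["active"].to_numpy(bool) if "active" in g.columns else None
        tracks.append(
            StimulusTrack(
                str(tid),
                g["t_ms"].to_numpy(float),
                g["x_m"].to_numpy(float),
                g["y_m"].to_numpy(float),
                g["radius_m"].to_numpy(float),
                shape,
                active,
            )
        )
    return tracks


def write_stimulus_tracks(tracks: list[StimulusTrack], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "t_ms": tr.t,
                "target_id": tr.target_id,
                "x_m": tr.x,
                "y_m": tr.y,
                "radius_m": tr.radius_m,
                "shape": tr.shape,
                "active": tr.active.astype(int),
            }
        )
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_artifact_report(artifacts: list[ArtifactInterval], trace: GazeTrace, path) -> None:
    pd.DataFrame(
        {
            "start_ms": [trace.t[a.start] for a in artifacts],
            "end_ms": [trace.t[a.end] for a in artifacts],
            "kind": [a.kind for a in artifacts],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Artifact detection and repair
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of True runs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def detect_artifacts(
    trace: GazeTrace,
    sentinel: float = DEFAULT_SENTINEL,
    workspace: tuple[float, float, float, float] | None = None,
    spike_factor: float = 5.0,
) -> list[ArtifactInterval]:
    """Locate blinks (sentinel-coded runs), screen outliers and one-sample spikes.

    Parameters
    ----------
    workspace : (xmin, xmax, ymin, ymax), optional
        Plane rectangle; samples outside it are screen outliers.
    spike_factor : float
        A sample is a spike when its step to *both* neighbours exceeds
        ``spike_factor`` times the median absolute sample-to-sample step while the
        neighbours agree with each other within that scale.
    """
    x, y = trace.x, trace.y
    sent = (x == sentinel) | (y == sentinel) | ~np.isfinite(x) | ~np.isfinite(y)
    if sent.all():
        raise ValueError("no usable samples: entire trace is sentinel-coded")
    artifacts = [ArtifactInterval(s, e, "blink") for s, e in _runs(sent)]

    if workspace is not None:
        xmin, xmax, ymin, ymax = workspace
        out = ~sent & ((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax))
        artifacts += [ArtifactInterval(s, e, "outlier") for s, e in _runs(out)]

    claimed = sent.copy()
    for a in artifacts:
        claimed[a.start : a.end + 1] = True
    dx = np.diff(np.where(claimed, np.nan, x))
    dy = np.diff(np.where(claimed, np.nan, y))
    step = np.hypot(dx, dy)
    finite_steps = step[np.isfinite(step)]
    if finite_steps.size:
        scale = np.median(finite_steps)
        if scale == 0.0:
            scale = np.finfo(float).eps
        thr = spike_factor * scale
        for i in range(1, len(trace) - 1):
            if claimed[i - 1] or claimed[i] or claimed[i + 1]:
                continue
            to_prev = np.hypot(x[i] - x[i - 1], y[i] - y[i - 1])
            to_next = np.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
            neighbors = np.hypot(x[i + 1] - x[i - 1], y[i + 1] - y[i - 1])
            if to_prev > thr and to_next > thr and neighbors <= thr:
                artifacts.append(ArtifactInterval(i, i, "spike"))

    return sorted(artifacts, key=lambda a: a.start)


def _spline_fill(values: np.ndarray, t: np.ndarray, start: int, end: int,
                 bad: np.ndarray, n_flank: int = 5) -> np.ndarray:
    """Fill ``values[start:end+1]`` from a cubic spline through the ``n_flank``
    nearest good samples on each side (fewer if fewer exist)."""
    good = np.flatnonzero(~bad)
    left = good[good < start][-n_flank:]
    right = good[good > end][:n_flank]
    support = np.concatenate((left, right))
    if support.size == 0:
        raise ValueError("no usable samples flank the gap")
    if left.size == 0 or right.size == 0:
        warnings.warn(
            "artifact at trace boundary: filling by nearest-edge extrapolation",
            stacklevel=3,
        )
    if support.size == 1:
        values[start : end + 1] = values[support[0]]
        return values
    kind = min(3, support.size - 1)
    if left.size and right.size and kind == 3:
        cs = CubicSpline(t[support], values[support])
        values[start : end + 1] = cs(t[start : end + 1])
    else:
        # too few points for a cubic, or one-sided gap: low-order polynomial fit
        coef = np.polyfit(t[support], values[support], kind)
        values[start : end + 1] = np.polyval(coef, t[start : end + 1])
    return values


def repair_trace(
    trace: GazeTrace,
    artifacts: list[ArtifactInterval],
    blink_margin_ms: float = 20.0,
) -> GazeTrace:
    """Repair detected artifacts in place of the raw samples.

    Blink and outlier gaps (extended by ``blink_margin_ms`` on both sides, because
    pupil-size distortion precedes and follows full occlusion) are replaced by a
    cubic spline fitted to the five valid samples flanking each side.  One-sample
    spikes are replaced by whichever neighbouring sample is closest in value.
    Repaired samples get ``valid=False``.  Repair is idempotent.
    """
    out = trace.copy()
    n = len(out)
    margin = int(round(blink_margin_ms / out.dt_ms))

    bad = np.zeros(n, dtype=bool)
    gaps = []
    for a in artifacts:
        if a.kind == "spike":
            continue
        s = max(0, a.start - margin)
        e = min(n - 1, a.end + margin)
        bad[s : e + 1] = True
    gaps = _runs(bad)

    for s, e in gaps:
        for arr in (out.x, out.y):
            _spline_fill(arr, out.t, s, e, bad)
        out.valid[s : e + 1] = False

    for a in artifacts:
        if a.kind != "spike":
            continue
        i = a.start
        if i == 0 or i == n - 1:
            j = 1 if i == 0 else n - 2
        else:
            d_prev = np.hypot(out.x[i] - out.x[i - 1], out.y[i] - out.y[i - 1])
            d_next = np.hypot(out.x[i] - out.x[i + 1], out.y[i] - out.y[i + 1])
            j = i - 1 if d_prev <= d_next else i + 1
        out.x[i] = out.x[j]
        out.y[i] = out.y[j]
        out.valid[i] = False

    if not (np.all(np.isfinite(out.x)) and np.all(np.isfinite(out.y))):
        raise ValueError("repair left non-finite samples")
    return out


def preprocess(
    trace: GazeTrace,
    sentinel: float = DEFAULT_SENTINEL,
    workspace: tuple[float, float, float, float] | None = None,
    cutoff_hz: float = 20.0,
    blink_margin_ms: float = 20.0,
) -> tuple[GazeTrace, list[ArtifactInterval]]:
    """Convenience chain: detect -> repair -> 20 Hz zero-phase low-pass."""
    artifacts = detect_artifacts(trace, sentinel=sentinel, workspace=workspace)
    repaired = repair_trace(trace, artifacts, blink_margin_ms=blink_margin_ms)
    return lowpass_filter(repaired, cutoff_hz=cutoff_hz), artifacts


# ---------------------------------------------------------------------------
# Filtering and resampling
# ---------------------------------------------------------------------------

def lowpass_filter(trace: GazeTrace, cutoff_hz: float = 20.0, order: int = 2) -> GazeTrace:
    """Zero-phase Butterworth low-pass of the POR coordinates (DC gain 1).

    Applied forward-backward (``filtfilt``) so event onsets are not delayed.
    """
    nyq = trace.rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    b, a = butter(order, cutoff_hz / nyq)
    out = trace.copy()
    out.x = filtfilt(b, a, out.x)
    out.y = filtfilt(b, a, out.y)
    return out


def resample(trace: GazeTrace, new_rate_hz: float) -> GazeTrace:
    """Linear resampling onto a uniform grid at ``new_rate_hz``.

    Output validity is False wherever the interpolation support includes an
    invalid input sample.
    """
    if new_rate_hz <= 0:
        raise ValueError("new rate must be positive")
    if abs(new_rate_hz - trace.rate_hz) < 1e-12:
        return trace.copy()
    new_dt = 1000.0 / new_rate_hz
    n_new = int(np.floor((trace.t[-1] - trace.t[0]) / new_dt)) + 1
    t_new = trace.t[0] + new_dt * np.arange(n_new)
    x_new = np.interp(t_new, trace.t, trace.x)
    y_new = np.interp(t_new, trace.t, trace.y)
    pupil_new = np.interp(t_new, trace.t, trace.pupil)
    # a new sample is invalid if either bracketing input sample is invalid
    idx_right = np.searchsorted(trace.t, t_new, side="left")
    idx_right = np.clip(idx_right, 0, len(trace) - 1)
    idx_left = np.clip(idx_right - 1, 0, len(trace) - 1)
    exact = np.isclose(trace.t[idx_right], t_new, atol=1e-9)
    valid_new = np.where(
        exact,
        trace.valid[idx_right],
        trace.valid[idx_left] & trace.valid[idx_right],
    )
    return GazeTrace(t_new, x_new, y_new, pupil_new, valid_new, new_rate_hz)


def resample_track(track: StimulusTrack, t_new: np.ndarray) -> StimulusTrack:
    """Interpolate a stimulus track onto the gaze time base."""
    x = np.interp(t_new, track.t, track.x)
    y = np.interp(t_new, track.t, track.y)
    r = np.interp(t_new, track.t, track.radius_m)
    active = np.interp(t_new, track.t, track.active.astype(float)) >= 0.999
    return StimulusTrack(track.target_id, t_new, x, y, r, track.shape, active)
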