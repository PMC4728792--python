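"""Event classification rules: saccades, fixations, pursuits, baseline."""

import numpy as np
import pytest

from gazekit.classify import (
    ClassifierConfig,
    baseline_fixed_threshold,
    classify_dynamic_task,
    classify_static_task,
    detect_saccades,
    events_to_labels,
)
from gazekit.io_preprocess import GazeTrace, StimulusTrack
from gazekit.kinematics import EyeGeometry, trace_kinematics

RATE = 500.0
GEOM = EyeGeometry(0.35)


def kin_from_plane(x, y, geom=GEOM, rate=RATE, **kw):
    t = np.arange(len(x)) * 1000.0 / rate
    return trace_kinematics(GazeTrace(t, x, y, rate_hz=rate), geom, **kw)


def minjerk_path(p0, p1, n):
    s = np.arange(1, n + 1) / n
    s = 10 * s**3 - 15 * s**4 + 6 * s**5
    return p0 + s[:, None] * (np.asarray(p1) - np.asarray(p0))


def gaze_with_saccade(amp_m=0.06, sacc_ms=40, hold_ms=300):
    """Hold, minimum-jerk jump, hold; returns plane coordinates."""
    nh = int(hold_ms / 1000 * RATE)
    ns = int(sacc_ms / 1000 * RATE)
    p0, p1 = np.array([0.0, 0.40]), np.array([amp_m, 0.40])
    path = minjerk_path(p0, p1, ns)
    x = np.concatenate([np.full(nh, p0[0]), path[:, 0], np.full(nh, p1[0])])
    y = np.concatenate([np.full(nh, p0[1]), path[:, 1], np.full(nh, p1[1])])
    return x, y, nh, nh + ns - 1


class TestDetectSaccades:
    def test_slow_trace_yields_no_saccades(self):
        t = np.arange(1000) / RATE
        # gentle drift, a few deg/s
        kin = kin_from_plane(0.01 * np.sin(2 * np.pi * 0.3 * t), np.full(1000, 0.4))
        cfg = ClassifierConfig(v_thr=40.0)
        assert detect_saccades(kin, cfg) == []

    def test_injected_saccade_bracketed_within_4ms(self):
        x, y, onset, offset = gaze_with_saccade()
        kin = kin_from_plane(x, y, sg_window_ms=3.0, sg_order=1)
        cfg = ClassifierConfig(v_thr=50.0)
        events = detect_saccades(kin, cfg)
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_v > 200.0
        assert abs(ev.onset_idx - onset) <= 2
        assert abs(ev.offset_idx - offset) <= 2
        assert ev.onset_idx < np.argmax(kin.v) < ev.offset_idx

    def test_subthreshold_acceleration_rejected(self):
        # a long, gentle movement: supra-threshold speed, sub-threshold acceleration
        n = 700
        t = np.arange(n) / RATE
        y = np.full(n, 0.40)
        x = 0.20 * 0.5 * (1 - np.cos(np.pi * np.minimum(t / 1.0, 1.0)))
        kin = kin_from_plane(x, y)
        assert kin.v.max() > 20.0
        cfg = ClassifierConfig(v_thr=15.0, a_thr=6000.0)
        assert detect_saccades(kin, cfg) == []
        # the same movement passes once the acceleration gate is lowered
        cfg_low = ClassifierConfig(v_thr=15.0, a_thr=float(kin.a.max()) / 2)
        assert len(detect_saccades(kin, cfg_low)) >= 1

    def test_two_ms_blip_rejected_by_minimum_duration(self):
        # a supra-threshold 2 ms excursion at 1 kHz spans fewer samples than
        # the 5 ms minimum saccade duration
        n = 600
        x = np.zeros(n)
        x[300:302] += 0.01
        t = np.arange(n)  # 1 kHz -> 1 ms steps
        kin = trace_kinematics(GazeTrace(t.astype(float), x, np.full(n, 0.4),
                                         rate_hz=1000.0), GEOM,
                               sg_window_ms=3.0, sg_order=1)
        cfg = ClassifierConfig(v_thr=30.0)
        assert detect_saccades(kin, cfg) == []

    def test_raising_threshold_never_adds_saccades(self, dynamic_run):
        counts = []
        for v_thr in (40.0, 60.0, 90.0, 150.0, 300.0):
            cfg = ClassifierConfig(v_thr=v_thr)
            counts.append(len(detect_saccades(dynamic_run.kin, cfg)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def static_target(n, pos=(0.0, 0.40), radius=0.01, tid="T0"):
    t = np.arange(n) * 1000.0 / RATE
    return StimulusTrack(tid, t, np.full(n, pos[0]), np.full(n, pos[1]),
                         np.full(n, radius))


class TestStaticTask:
    def test_hold_on_target_is_a_fixation(self):
        n = 200  # 400 ms
        kin = kin_from_plane(np.zeros(n), np.full(n, 0.40))
        cfg = ClassifierConfig(v_thr=40.0)
        events = classify_static_task(kin, [static_target(n)], cfg)
        fixes = [e for e in events if e.label == "fixation"]
        assert len(fixes) == 1
        assert fixes[0].target_id == "T0"
        assert fixes[0].n_samples == n

    def test_short_hold_is_not_a_fixation(self):
        # target only displayed for 20 ms < the 40 ms minimum fixation duration
        n = 200
        kin = kin_from_plane(np.zeros(n), np.full(n, 0.40))
        target = static_target(n)
        target.active[:] = False
        target.active[100:110] = True
        cfg = ClassifierConfig(v_thr=40.0)
        events = classify_static_task(kin, [target], cfg)
        assert not any(e.label == "fixation" for e in events)

    def test_hold_outside_foveal_circle_not_bound(self):
        n = 200
        kin = kin_from_plane(np.zeros(n), np.full(n, 0.40))
        fvr = float(kin.fvr[0])
        # target displaced just beyond FVR + T_R
        far = static_target(n, pos=(fvr + 0.01 + 0.001, 0.40), radius=0.01)
        cfg = ClassifierConfig(v_thr=40.0)
        events = classify_static_task(kin, [far], cfg)
        assert not any(e.label == "fixation" for e in events)

    def test_target_free_fallback_warns(self):
        n = 200
        kin = kin_from_plane(np.zeros(n), np.full(n, 0.40))
        cfg = ClassifierConfig(v_thr=40.0)
        with pytest.warns(UserWarning, match="target-free"):
            events = classify_static_task(kin, None, cfg)
        assert any(e.label == "fixation" for e in events)


def moving_target(n, speed=0.30, x0=0.0, y0=0.48, radius=0.01, tid="M0"):
    t = np.arange(n) * 1000.0 / RATE
    y = y0 - speed * t / 1000.0
    return StimulusTrack(tid, t, np.full(n, x0), y, np.full(n, radius))


class TestDynamicTask:
    def test_tracking_gaze_is_a_pursuit(self):
        n = 300
        target = moving_target(n)
        kin = kin_from_plane(target.x.copy(), target.y.copy())
        cfg = ClassifierConfig(v_thr=80.0)
        events = classify_dynamic_task(kin, [target], cfg)
        purs = [e for e in events if e.label == "smooth_pursuit"]
        assert purs and purs[0].target_id == "M0"
        labels = events_to_labels(events, n)
        assert (labels == "smooth_pursuit").mean() > 0.8

    def test_speed_mismatch_is_not_a_pursuit(self):
        n = 150
        target = moving_target(n)
        # gaze moves at half the target's speed from the same start point
        half = moving_target(n, speed=0.15)
        kin = kin_from_plane(half.x.copy(), half.y.copy())
        cfg = ClassifierConfig(v_thr=80.0)
        events = classify_dynamic_task(kin, [target], cfg)
        assert not any(e.label == "smooth_pursuit" for e in events)

    def test_post_saccadic_fixation_detected(self):
        # saccade lands near the moving target; gaze then stays put
        n_pre, n_sacc, n_post = 150, 20, 200
        n = n_pre + n_sacc + n_post
        target = moving_target(n, speed=0.30, x0=0.12, y0=0.45)
        land = (target.x[n_pre + n_sacc], target.y[n_pre + n_sacc])
        path = minjerk_path(np.array([0.0, 0.45]), np.array(land), n_sacc)
        x = np.concatenate([np.zeros(n_pre), path[:, 0], np.full(n_post, land[0])])
        y = np.concatenate([np.full(n_pre, 0.45), path[:, 1], np.full(n_post, land[1])])
        kin = kin_from_plane(x, y)
        cfg = ClassifierConfig(v_thr=60.0)
        events = classify_dynamic_task(kin, [target], cfg)
        assert any(e.label == "saccade" for e in events)
        fixes = [e for e in events if e.label == "fixation"]
        assert fixes and fixes[0].target_id == "M0"
        # the fixation starts within the 100 ms post-saccadic window
        sacc = [e for e in events if e.label == "saccade"][0]
        assert fixes[0].onset_idx - sacc.offset_idx <= int(0.1 * RATE) + 1

    def test_missing_targets_rejected(self, dynamic_run):
        cfg = ClassifierConfig(v_thr=80.0)
        with pytest.raises(ValueError):
            classify_dynamic_task(dynamic_run.kin, [], cfg)

    def test_track_time_base_mismatch_rejected(self):
        n = 200
        target = moving_target(n)
        kin = kin_from_plane(target.x.copy(), target.y.copy())
        short = moving_target(n - 10)
        cfg = ClassifierConfig(v_thr=80.0)
        with pytest.raises(ValueError, match="time base"):
            classify_dynamic_task(kin, [short], cfg)


class TestBaseline:
    def test_slow_pursuit_called_fixation_by_baseline(self):
        n = 400
        target = moving_target(n, speed=0.18, y0=0.50)  # ~20 deg/s angular
        kin = kin_from_plane(target.x.copy(), target.y.copy())
        assert 10 < np.median(kin.v[50:-50]) < 30
        baseline = events_to_labels(baseline_fixed_threshold(kin), n)
        assert (baseline == "fixation").mean() > 0.95
        # the full classifier labels the same samples pursuit
        events = classify_dynamic_task(kin, [target], ClassifierConfig(v_thr=80.0))
        full = events_to_labels(events, n)
        assert (full == "smooth_pursuit").mean() > 0.8

    def test_fast_saccade_detected_by_both(self):
        x, y, onset, offset = gaze_with_saccade(amp_m=0.08)
        kin = kin_from_plane(x, y)
        base = baseline_fixed_threshold(kin)
        assert any(e.label == "saccade" and e.peak_v > 200 for e in base)
        full = detect_saccades(kin, ClassifierConfig(v_thr=60.0))
        assert len(full) == 1

    def test_stationary_hold_is_fixation(self):
        n = 300
        kin = kin_from_plane(np.zeros(n), np.full(n, 0.4))
        events = baseline_fixed_threshold(kin)
        assert len(events) == 1 and events[0].label == "fixation"


class TestEventPartition:
    @pytest.mark.parametrize("run_name", ["static_run", "dynamic_run"])
    def test_events_are_disjoint_and_labels_cover(self, run_name, request):
        run = request.getfixturevalue(run_name)
        spans = sorted((e.onset_idx, e.offset_idx) for e in run.events)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2, "events overlap"
        assert run.candidate.shape[0] == len(run.kin)
        assert set(run.candidate) <= {
            "fixation", "saccade", "smooth_pursuit", "blink", "unclassified"
        }

    def test_minimum_durations_respected(self, dynamic_run):
        rate = dynamic_run.kin.rate_hz
        for ev in dynamic_run.events:
            if ev.label == "saccade":
                assert ev.duration_ms(rate) >= 5.0
            elif ev.label in ("fixation", "smooth_pursuit"):
                assert ev.duration_ms(rate) >= 40.0

    def test_blink_samples_labelled_blink(self, dynamic_run):
        invalid = ~dynamic_run.kin.valid
        assert np.all(dynamic_run.candidate[invalid] == "blink")


def test_sample_agreement_on_session_recovery(static_run, dynamic_run):
    """The classifier recovers most ground-truth samples of the classes each
    task contains."""
    for run, classes, floor in (
        (static_run, ("fixation", "saccade"), 0.90),
        (dynamic_run, ("smooth_pursuit", "saccade"), 0.85),
    ):
        mask = np.isin(run.truth, classes)
        agreement = (run.candidate[mask] == run.truth[mask]).mean()
        assert agreement >= floor
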