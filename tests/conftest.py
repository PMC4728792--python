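"""Shared fixtures: simulated sessions run through the full analysis pipeline."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from gazekit import (
    ClassifierConfig,
    SessionScenario,
    classify_dynamic_task,
    classify_static_task,
    events_to_labels,
    extract_velocity_peaks,
    fit_lognormal_mixture,
    simulate_session,
)
from gazekit.io_preprocess import preprocess
from gazekit.kinematics import trace_kinematics


@dataclass
class PipelineRun:
    """A simulated session pushed through preprocessing, kinematics,
    threshold fitting and classification."""

    scenario: SessionScenario
    session: object
    kin: object
    model: object
    events: list
    candidate: np.ndarray  # per-sample labels from the classifier

    @property
    def truth(self) -> np.ndarray:
        return self.session.labels


_CACHE: dict = {}


def run_pipeline(mode: str, seed: int, **overrides) -> PipelineRun:
    """Simulate a session and classify it with session-fitted thresholds."""
    key = (mode, seed, tuple(sorted(overrides.items())))
    if key in _CACHE:
        return _CACHE[key]
    scenario = SessionScenario(mode=mode, seed=seed, **overrides)
    session = simulate_session(scenario)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trace, _ = preprocess(session.trace)
        kin = trace_kinematics(trace, scenario.geometry)
        peaks = extract_velocity_peaks(kin.v, kin.rate_hz, t=kin.t, exclude=~kin.valid)
        model = fit_lognormal_mixture(peaks)
        cfg = ClassifierConfig(v_thr=model.v_thr, a_thr=model.a_thr)
        if mode == "static":
            events = classify_static_task(kin, session.tracks, cfg)
        else:
            events = classify_dynamic_task(kin, session.tracks, cfg)
    run = PipelineRun(
        scenario, session, kin, model, events, events_to_labels(events, len(kin))
    )
    _CACHE[key] = run
    return run


@pytest.fixture(scope="session")
def static_run() -> PipelineRun:
    return run_pipeline("static", 1)


@pytest.fixture(scope="session")
def dynamic_run() -> PipelineRun:
    return run_pipeline("dynamic", 1)


@pytest.fixture(scope="session")
def fixation_only_run() -> PipelineRun:
    """Dynamic trial structure without target motion (no pursuit)."""
    return run_pipeline("dynamic", 1, objects_move=False)


# Deterministic property testing: derandomised Hypothesis profile.
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("det", derandomize=True, deadline=None)
_hyp_settings.load_profile("det")
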