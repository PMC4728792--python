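"""Quantitative scores comparing a candidate labelling against a reference.

For each oculomotor event class c (fixation, saccade, smooth pursuit) and trial i:

    QnS_c  = mean_i [ 100 · overlap_i / reference_i ]
    misQnS_c = mean_i [ 100 · cross_i / reference_i ]

where ``reference_i`` counts reference samples of class c, ``overlap_i`` counts samples
both labellings assign to c, and ``cross_i`` counts reference-c samples the candidate
assigns to a *different* oculomotor event class.  Candidate samples left unclassified
(or masked as blink) reduce the overlap but never count as misclassification.  Sample
intervals are inclusive at both ends, so a reference fixation spanning samples 201-800
contributes 600 reference samples.  Trials with no reference samples of a class are
excluded from that class's average.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EVENT_CLASSES = {"fixation": "FQnS", "saccade": "SQnS", "smooth_pursuit": "SPQnS"}
_NONEVENT = {"unclassified", "blink"}

logger = logging.getLogger(__name__)


@dataclass
class LabeledTrial:
    """Reference and candidate per-sample labels for one trial."""

    trial_id: str
    reference: np.ndarray
    candidate: np.ndarray

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=object)
        self.candidate = np.asarray(self.candidate, dtype=object)
        if self.reference.size != self.candidate.size:
            raise ValueError("reference and candidate label vectors differ in length")


@dataclass
class ScoreReport:
    """Classification and misclassification percentages, per trial and averaged."""

    scores: dict[str, float]          # FQnS, SQnS, SPQnS, misFQnS, misSQnS, misSPQnS
    per_trial: pd.DataFrame = field(repr=False, default=None)

    def __getattr__(self, name):
        scores = object.__getattribute__(self, "scores")
        if name in scores:
            return scores[name]
        raise AttributeError(name)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {k: (None if v is None or not np.isfinite(v) else v) for k, v in self.scores.items()},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        df = self.per_trial.copy()
        summary = df.drop(columns=["trial_id"]).agg(["mean", "min", "max"])
        summary.insert(0, "trial_id", summary.index)
        pd.concat([df, summary], ignore_index=True).to_csv(path, index=False)


def overlap_counts(
    reference: tuple[int, int], candidate: tuple[int, int]
) -> tuple[int, int]:
    """Inclusive reference length and intersection length of two sample intervals."""
    r0, r1 = reference
    c0, c1 = candidate
    if r0 > r1 or c0 > c1:
        raise ValueError("interval onset after offset")
    ref_count = r1 - r0 + 1
    overlap = max(0, min(r1, c1) - max(r0, c0) + 1)
    return ref_count, overlap


def quantitative_scores(trials: list[LabeledTrial]) -> ScoreReport:
    """Sample-wise QnS and misQnS percentages averaged over trials."""
    if not trials:
        raise ValueError("at least one trial required")
    rows = []
    for trial in trials:
        ref, cand = trial.reference, trial.candidate
        row = {"trial_id": trial.trial_id}
        for cls, tag in _EVENT_CLASSES.items():
            in_ref = ref == cls
            n_ref = int(in_ref.sum())
            if n_ref == 0:
                row[tag] = np.nan
                row["mis" + tag] = np.nan
                logger.info(
                    "trial %s has no reference %s samples; excluded from %s",
                    trial.trial_id, cls, tag,
                )
                continue
            overlap = int((in_ref & (cand == cls)).sum())
            other = [c for c in _EVENT_CLASSES if c != cls]
            cross = int((in_ref & np.isin(cand, other)).sum())
            row[tag] = 100.0 * overlap / n_ref
            row["mis" + tag] = 100.0 * cross / n_ref
        rows.append(row)
    per_trial = pd.DataFrame(rows)
    scores = {
        col: float(per_trial[col].mean(skipna=True))
        for col in per_trial.columns
        if col != "trial_id"
    }
    return ScoreReport(scores=scores, per_trial=per_trial)


def event_detection_scores(
    reference: np.ndarray, candidate: np.ndarray, label: str,
    min_overlap: float = 0.5,
) -> dict[str, float]:
    """Event-level sensitivity and precision for one class.

    Two events match when their intersection covers at least ``min_overlap`` of
    the shorter of the two — the majority-of-the-shorter-event rule, which is
    robust to the boundary smearing that zero-phase filtering introduces (a
    detected saccade legitimately extends to the flanking velocity minima,
    beyond the instantaneous ground-truth transition).
    """
    from gazekit.io_preprocess import _runs

    ref_runs = _runs(np.asarray(reference, dtype=object) == label)
    cand_runs = _runs(np.asarray(candidate, dtype=object) == label)

    def _matched(runs_a, runs_b):
        hits = 0
        for s, e in runs_a:
            for s2, e2 in runs_b:
                inter = min(e, e2) - max(s, s2) + 1
                shorter = min(e - s + 1, e2 - s2 + 1)
                if inter >= min_overlap * shorter:
                    hits += 1
                    break
        return hits

    sens = _matched(ref_runs, cand_runs) / len(ref_runs) if ref_runs else np.nan
    prec = _matched(cand_runs, ref_runs) / len(cand_runs) if cand_runs else np.nan
    return {
        "sensitivity": sens,
        "precision": prec,
        "n_reference": len(ref_runs),
        "n_candidate": len(cand_runs),
    }
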