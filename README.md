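# gazekit

Ocular kinematics and gaze-event classification for monocular point-of-regard (POR)
data recorded in a **horizontal (transverse) stimulus plane** — the geometry of
robotic and virtual-reality workspaces where visual stimuli are presented among the
hands and stimulus depth varies across the display.

Remote video trackers report the POR as plane Cartesian coordinates and typically
convert to a scalar visual angle assuming constant viewing depth. In a transverse
workspace that assumption fails, and the fixed thresholds of commercial event
parsers (e.g. 0.3°, 30 °/s, 8000 °/s²) misclassify slow smooth pursuits as
fixations and misplace saccade boundaries. `gazekit` implements the geometric
alternative:

1. **Inverse kinematics.** The POR (x, y) is lifted into an eye-centred frame,
   `[x';y';z'] = [0;0;H] + R·[x;y;0]` (eye height H, head orientation R), converted
   to spherical coordinates (ρ, θ, ϕ), and differentiated with Savitzky–Golay
   filters. Angular speed is `v = √((θ̇ sin ϕ)² + ϕ̇²)`; ocular pitch and yaw are
   α = ϕ, γ = 90° − θ.
2. **Adaptive thresholds.** Local peaks of `v` are bimodal on the log scale (noise,
   microsaccades and pursuits vs saccades). A two-component lognormal mixture is
   fitted by maximum likelihood and the saccade velocity threshold is
   `v_thr = exp[((μ₂ − 2σ₂) + (μ₁ + 2σ₁))/2]` — participant- and task-specific by
   construction.
3. **Event classification.** Smooth pursuits first (position *and* velocity match
   to a moving target within a noise tolerance η, sub-saccadic kinematics, ≥40 ms),
   then saccades (supra-threshold velocity peak, confirming acceleration, ≥5 ms,
   delimited by flanking velocity minima), then post-saccadic fixations. Spatial
   tolerances use the foveal visual radius `FVR ≈ ρ·tan(δ/2)·cosec(ε)`, which grows
   with gaze distance and obliquity.
4. **Scoring.** Sample-wise quantitative scores (FQnS, SQnS, SPQnS) and
   misclassification indices between any reference and candidate labelling, plus
   event-level sensitivity/precision.

A seeded synthetic-session generator (`gazekit.synth`) produces ground-truth
labelled sessions — visual-search (fixation/saccade) and object-interception
(pursuit-rich) tasks with main-sequence saccades, physiological drift,
microsaccades, pursuit lag and gain noise, blinks and tracker artifacts — so every
stage is testable without recorded data.

## Worked example

Simulate a pursuit-rich session, classify it with a session-fitted threshold, and
score it against the generator's ground truth:

```bash
gazekit simulate --mode dynamic --seed 7 --out demo
gazekit thresholds --gaze demo/gaze.csv --out demo/thr
gazekit classify --gaze demo/gaze.csv --targets demo/targets.csv \
        --mode dynamic --out demo/cls
gazekit evaluate --reference demo/truth_events.csv --candidate demo/cls/events.csv \
        --gaze demo/gaze.csv --out demo/eval
```

which prints

```
simulated 32931 samples (65.9 s) -> demo
v_thr = 67.2 deg/s from 225 peaks -> demo/thr
events: {'smooth_pursuit': 191, 'saccade': 84, 'blink': 19, 'fixation': 1} -> demo/cls
{
  "FQnS": 0.10737774596214934,
  "misFQnS": 39.5821216052973,
  "SQnS": 90.7552620718118,
  "SPQnS": 86.96213981134514,
  "misSPQnS": 3.243313089546453
}
saccade events: sensitivity=0.83 precision=0.95
```

Reading the numbers: the mixture fit put this session's saccade velocity threshold
at 67 deg/s (a fixation/saccade-only session fits a markedly lower one — the task
dependence that motivates adaptive thresholds). The classifier recovered 87 % of
ground-truth pursuit samples (SPQnS) and 91 % of saccade samples (SQnS), with 3 %
of pursuit samples mislabelled. Dynamic-task fixations are mostly brief
post-saccadic holds that the strict fixation rules rarely confirm under noise, so
FQnS is near zero there and misFQnS is dominated by quiet gaze on the static
fixation circle being read as pursuit of a stationary target; fixation recovery is
instead measured on the static visual-search task (`--mode static`), where it is
~94 %. Event-level saccade sensitivity is capped near 0.83 because small catch-up
saccades (<4°) lose their acceleration signature in the 20 Hz filter — see
`docs/methods.md`.

The same stages are available as library functions (`gazekit.simulate_session`,
`gazekit.trace_kinematics`, `gazekit.fit_lognormal_mixture`,
`gazekit.classify_dynamic_task`, `gazekit.quantitative_scores`, …).

## Layout

```
src/gazekit/
  io_preprocess.py   gaze/stimulus I/O, blink & artifact repair, filtering, resampling
  kinematics.py      plane -> eye -> spherical transforms, derivatives, FVR
  thresholds.py      velocity peaks, lognormal-mixture EM, adaptive threshold
  classify.py        pursuit/saccade/fixation rules + fixed-threshold baseline
  evaluate.py        FQnS/SQnS/SPQnS, misclassification, event-level scores
  synth.py           ground-truth-labelled synthetic session generator
  cli.py             subcommand-per-stage command line (`gazekit ...`)
docs/methods.md      models, defaults, numerical choices, limitations
tests/               unit, property and acceptance suites
```
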