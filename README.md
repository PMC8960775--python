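# autrain

A headless, hardware-free implementation of an automated home-cage training
and psychoacoustic testing workflow for small primates working on a
touchscreen. The package contains everything such a system needs *except*
the hardware: the automated unsupervised training (AUT) engine that shapes a
naive subject into a two-alternative-choice (2AC) observer, the trial-level
logic of the 2AC/3AC audio-visual association and vocalization-detection
tasks, simulated subjects that stand in for animals, and the statistical and
psychometric pipeline used to evaluate performance and estimate hearing
thresholds.

It is aimed at researchers who want to prototype, stress-test, or analyze
automated operant-training protocols without a device or animals: every
input a live system would produce can be generated by the built-in simulated
subjects, and every analysis runs on plain CSV/JSON-lines session logs.

## What it implements

**Training schedule.** The AUT is a 49-position step table (one entry step
plus 48 dynamic steps) spanning four milestones: trigger size (6 × 6 cm
shrinking to 3 × 3 cm over steps 1–15), trigger position (5 mm lateral drift
per step over 16–30), sound and delayed target (two-touch trials from step
31; sound from step 36 ramping 32 → 72 dB SPL in 10 dB steps by step 40),
and a visual distractor (0.3 cm growing to 2.8 cm over steps 46–49).
Progression is performance-based: a sliding window of the 10 most recent
scored trials advances the subject one step at ≥ 8 correct and retreats one
step at ≤ 2 correct; reaching step 50 completes the schedule. Progress
persists as one JSON document per subject across sessions.

**Tasks.** One trial state machine covers shaping trials, the 2AC/3AC
audio-visual association (chance reward rates 1/2 and 1/3), generalization
variants with novel stimulus pairs, and a vocalization-detection task by the
method of constant stimuli (levels 0–80 dB SPL) with a level-dependent
reward scheme: levels of 15–45 dB SPL are rewarded regardless of choice,
silent trials only on the "absent" response, and levels ≥ 60 dB SPL only on
the "present" response.

**Analysis.** Hit-rate tables with the signal-detection sensitivity index
d′ = z(H) − z(FA) (1/(2N) correction for perfect rates), exact one-sided
binomial tests against chance with Bonferroni adjustment, Kruskal–Wallis
rank tests on reaction times, engagement summaries (trials/session,
zero-trial sessions, median normalized trial timestamp), learning curves on
a standardized percent-of-trials axis, and partial Pearson correlation.

**Psychometrics.** The psychometric function
ψ(x; m, w, λ, γ) = γ + (1 − λ − γ)·S(x; m, w), with S a cumulative normal,
m the threshold (level at S = 0.5), w the width (level difference between
S = 0.5 and S = 0.95 by default), γ the guess rate, λ the lapse rate.
Fitting maximizes the binomial likelihood of per-level counts; confidence
intervals come from the observed information or a parametric bootstrap.

## Worked example

Shape a learning subject through the full schedule, test it on the 2AC
association, and estimate a hearing threshold:

```python
from autrain import (AgentSpec, PsychometricParams, simulate_training,
                     simulate_session, two_choice_task, detection_task,
                     hit_rate_table, kruskal_wallis_ranks, to_frame,
                     fit_psychometric, bootstrap_ci)
from autrain.analysis import detection_level_counts, reaction_times_by_sound

learner = AgentSpec(policy="learning-curve", p_start=0.5,
                    p_asymptote=0.95, tau_trials=200.0)
result = simulate_training(learner, seed=1)
print(result.final_state.current_step, result.n_sessions, result.milestone_trials)
# 50 5 {'size': 238, 'position': 181, 'delay': 156, 'choice': 40}
```

The subject completed the schedule (step 50) in 5 sessions and 615 trials,
most of them spent on the early size and position milestones.

```python
subject = AgentSpec(policy="fixed-accuracy", p_correct=0.85, p_ignore=0.05,
                    rt_model={"voc": (0.1, 0.3), "sTr": (-0.3, 0.3)})
logs = to_frame(simulate_session(two_choice_task(), subject, 1000,
                                 seed=2, animal_id="m01"))
print(hit_rate_table(logs, family_size=26))
#  sound_id  n_scored  n_ignored  hit_rate  d_prime  p_value_adjusted
#       sTr       480         22     0.844     1.96          1.1e-54
#       voc       471         27     0.830     1.96          4.2e-49
rts = reaction_times_by_sound(logs)
print(kruskal_wallis_ranks(rts["voc"], rts["sTr"]))
# KruskalResult(H=314.73, df=1, p_value=2.04e-70)
```

Both stimuli are discriminated far above the 50% chance level (d′ ≈ 1.96),
and the per-sound reaction-time shift built into the agent is detected by
the rank test.

```python
observer = AgentSpec(policy="psychometric-observer",
                     psychometric=PsychometricParams(m=36.0, w=18.0,
                                                     lam=0.02, gamma=0.06))
det = to_frame(simulate_session(detection_task(), observer, 1400,
                                seed=3, animal_id="m01"))
counts = detection_level_counts(det)
fit = fit_psychometric(counts, seed=0)
boot = bootstrap_ci(counts, fit, n_boot=500, seed=0)
print(fit.params.m, boot.intervals["m"])
# 35.8  (33.9, 37.8)
```

The fitted hearing threshold, 35.8 dB SPL with a bootstrap 95% CI of
33.9–37.8, recovers the observer's generating threshold of 36 dB SPL.

The same workflows are available from the shell:

```bash
autrain simulate-aut --agent ideal --seed 1 --out run/
autrain simulate-task --task 3ac --agent random --n-trials 10000 --seed 1
autrain analyze run/aut_log.csv --out-prefix run/analysis
autrain fit-psychometric --input levels.csv --out fit.json --n-boot 500
autrain make-fixtures --out fixtures/ --seed 0
```

## Layout

- `src/autrain/schedule.py` — step table, sliding-window progression, persistence
- `src/autrain/tasks.py` — trial state machine, stimulus sampling, reward rules
- `src/autrain/agents.py` — simulated subjects and session/training simulation
- `src/autrain/analysis.py` — performance, engagement, and inferential statistics
- `src/autrain/psychometrics.py` — psychometric function, ML fit, bootstrap CIs
- `src/autrain/io.py`, `src/autrain/cli.py` — log formats, run config, CLI
- `docs/methods.md` — modeling and numerical details
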