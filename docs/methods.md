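# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what the simulated subjects do and do not capture.

## Shaping schedule and progression

The schedule is expanded deterministically from a small set of constants
(`ScheduleConfig`) into 49 positions: an entry step plus 48 dynamic steps.
Milestone boundaries are fixed (size 1–15, position 16–30, delay 31–45,
choice 46–49). Two ramps are stated only by their endpoints — trigger size
6 → 3 cm over steps 1–15 and distractor size 0.3 → 2.8 cm over steps 46–49 —
and are interpolated linearly; the lateral offset ramp is exactly 5 mm per
step, capped at the configured screen-edge offset (≥ 75 mm, the distance
needed to reach the edge in 15 steps); the sound-level ramp is exactly
10 dB per step from 32 dB SPL (step 36) to 72 dB SPL (step 40), constant
afterwards.

Progression uses a sliding window of the 10 most recent *scored* outcomes:
advance at ≥ 8 correct, retreat at ≤ 2 correct, one step per scored trial,
clamped to [entry, completion]. Three policies are deliberate design
choices where the protocol description is silent:

- **Incomplete windows never trigger a transition.** Until 10 scored trials
  accumulate after a step change, the subject stays, preventing spurious
  transitions from 1–2 lucky or unlucky trials.
- **The window is cleared on every step change**, so consecutive
  transitions each require fresh evidence; a single hot streak cannot
  cascade through several steps.
- **Ignored trials bypass the window entirely** — they carry no choice, so
  they are evidence of disengagement, not of ability.

Timeout duration is a single configurable value (default 5 s) rather than a
session-age-dependent mix. Progress is persisted after every session as one
JSON document per subject and reloaded on resume, so a training run is a
pure function of (agent, seed, schedule) regardless of how it is split into
sessions.

## Trial engine and reward rules

A trial runs trigger → (sound lead drawn uniformly from 1–1.5 s when sound
is enabled) → options → response window (7 s default) → reward, or a
gray-screen timeout after wrong touches, followed by an inter-trial
interval drawn uniformly from 0.8–2.5 s (the uniform choice on both
intervals is ours; only the ranges are given by the protocol). The step
table stores the nominal sound lead (the midpoint, 1.25 s); the per-trial
lead is always drawn from the configured range. Time is simulated through
an injectable clock so a 10,000-trial session runs in ~0.1 s; a wall-clock
mode exists for paced demonstrations.

Choice tasks reward the target touch and nothing else. Target side is drawn
independently and uniformly per trial (not balanced), and in shaping trials
the left/right placement during the position and delay milestones is an
independent uniform draw. The detection task's reward scheme is a fixed
three-branch rule over the constant-stimuli set {0, 15, 30, 45, 60, 70,
80} dB SPL: the 15–45 band is rewarded regardless of choice (these levels
sit near typical facility background noise, and unconditional reward there
prevents frustration-driven disengagement near threshold), 0 dB only on the
"absent" response, ≥ 60 dB only on the "present" response. A uniformly
random responder therefore earns rewards at (3·1 + 4·½)/7 = 5/7 of
detection trials, and at exactly 1/2 and 1/3 of 2AC and 3AC trials. Trials
at 0 dB SPL represent both silent trials and a vocalization at zero
amplitude; they are modeled as a single silent-trial type. In the choice
milestone (steps 46–49) the engine scores by the identity of the touched
visual, not by its size, even though the size asymmetry would let a
size-based strategy succeed.

## Simulated subjects

Agents are response policies, not cognitive models. They exist so that
every pipeline has inputs with known ground truth:

- `random` / `ideal` bracket chance and ceiling;
- `fixed-accuracy` holds P(correct) constant;
- `learning-curve` follows a saturating exponential
  p(t) = p∞ − (p∞ − p₀)·exp(−t/τ) with defaults p₀ = 0.5, p∞ = 0.9,
  τ = 200 trials — a canonical smooth improvement profile on the order of a
  few hundred trials per milestone, matching the scale at which window-based
  progression operates;
- `psychometric-observer` answers "present" with probability ψ(level), so a
  threshold fit has an exact generating value to recover.

Reaction times are log-normal with a per-sound location parameter (default
location −0.3, scale 0.35, i.e. median ≈ 0.74 s), giving rank-based RT
comparisons a true effect when two sounds are given different locations.
`p_ignore` inserts ignored trials upstream of choice, independent of the
stimulus. One seeded generator drives stimulus sampling and the agent, so
logs are byte-identical across runs with the same seed.

What the agents do **not** emulate: satiety and engagement dynamics within
a session, side biases, stimulus-specific strategies (e.g. exploiting the
distractor-size asymmetry), perseveration, or social interruption. Passing
tests therefore demonstrate that the machinery is correct and the
statistics behave nominally under known generating processes — not that
real subjects behave like the agents.

## Statistical conventions

- **Hit rate** is correct/scored; ignored trials are tabulated separately.
- **d′** uses the yes/no convention z(H) − z(FA). In a two-stimulus task
  each stimulus's hit rate serves as the other's correct-rejection rate, so
  FA = 1 − hit(other). Rates of exactly 0 or 1 are moved to 1/(2N) and
  1 − 1/(2N) before the quantile transform. No formula beyond "sensitivity
  index" is fixed by the protocol, so printed d′ values from live datasets
  are not treated as exact targets.
- **Binomial test**: exact one-sided upper tail P(X ≥ k | n, p_chance),
  p_chance = 1/2 (2AC) or 1/3 (3AC).
- **Bonferroni**: adjusted p = min(1, p·m) with the family size m an
  explicit argument (a 26-comparison family at α = 0.05 gives the corrected
  α ≈ 0.0019).
- **Kruskal–Wallis** is used for reaction-time comparisons even with two
  groups (df = 1), tie-corrected, chi-square tail.
- **Learning curves** index each subject's trials 1..N and map them to a
  shared percent-of-total-trials axis (ceil(i·B/N) for B bins); bin counts
  sum to N exactly.
- **Engagement** normalizes trial timestamps by the *scheduled* session
  duration (supplied per session, not inferred from the last trial) and
  reports the per-session median; zero-trial sessions are tallied per
  subject.
- **Partial Pearson correlation** residualizes both variables on the
  covariate with an intercept; the t-test uses n − 3 df and the Fisher CI
  uses SE = 1/√(n − 4).

## Psychometric fitting

ψ(x; m, w, λ, γ) = γ + (1 − λ − γ)·Φ(c·(x − m)/w). The default width
convention defines w as the level difference between S = 0.5 and S = 0.95,
hence c = Φ⁻¹(0.95) ≈ 1.645; the common 0.05–0.95 convention (c = 2Φ⁻¹(0.95))
is selectable because conventions differ between packages. m is always the
level at which the *core* sigmoid crosses 0.5.

The fit maximizes the binomial log-likelihood of per-level (n, k) counts
plus a weak Beta(1, 10) log-prior on λ and γ. The prior contributes only
9·log(1−λ) + 9·log(1−γ): it keeps the asymptotes identified when few trials
constrain them, while biasing estimates by far less than 10⁻³ at the trial
counts used here. Optimization is L-BFGS-B (ftol 10⁻¹², gtol 10⁻⁸) from a
deterministic 6-point start grid (threshold guesses crossed with two width
guesses) plus two seeded jittered starts; the best optimum wins. Bounds
default to m within one level-range of the data, w in (10⁻³, 4)·range, and
λ, γ in [0, 0.499]. Degenerate data (all responses identical) are flagged
non-converged with no estimate rather than returning a boundary artifact.
Fitting detection data uses the probability of the *present* response
versus level, so the false-alarm floor at 0 dB SPL is absorbed by γ.

Confidence intervals: the fit itself carries Wald 95% intervals from the
inverse observed information (central-difference Hessian at the optimum);
`bootstrap_ci` offers parametric-bootstrap percentile intervals (resample
counts from the fitted curve, refit warm-started at the original estimate),
flagged unreliable if more than 20% of refits fail. Wald and bootstrap
intervals agree closely at the trial counts used in the examples.

## Problem sizes and determinism

The test suite simulates at sizes chosen to make binomial sampling error
small relative to the tested margins: 10,000 trials for chance-level
checks (3 SE ≈ 1.5 percentage points), 1,400-trial detection sessions
(≈ 200 per level, matching a realistic multi-session yield) for threshold
recovery across 100 seeded replicates, 1,000 replicates of 100-trial
sessions for the size of the binomial test, and exhaustive enumeration
where the space is small (all 2¹⁰ outcome windows; all binomial tails for
n ≤ 20). Every stochastic path takes an explicit integer seed; fixture
bundles and CLI workflows are reproducible byte-for-byte.

## Known limitations

- Agents are stationary or smoothly improving; none reproduce abrupt
  strategy shifts, biases, or motivational structure of real subjects.
- The engagement summary requires externally supplied session durations;
  the CLI falls back to the last trial timestamp + 1 s when none exist.
- The Wald intervals rely on a quadratic likelihood approximation and can
  be optimistic when λ or γ sits on its boundary; prefer the bootstrap for
  reporting.
- The trial engine models timing only as far as the logs require (leads,
  latencies, timeouts, intervals); it does not render stimuli or model
  touch geometry, so trigger/target sizes influence difficulty only through
  the agents' accuracy parameters.
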