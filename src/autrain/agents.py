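"""Simulated subjects that stand in for animals.

Every task and analysis in the package is exercised end-to-end by driving
the trial engine with one of five response policies:

``random``
    touches uniformly among the displayed options — the chance baseline;
``ideal``
    always touches the target — the always-advance upper bound;
``fixed-accuracy``
    touches the target with a constant probability ``p_correct``;
``learning-curve``
    accuracy follows a saturating exponential
    p(t) = p_asymptote - (p_asymptote - p_start) * exp(-t / tau_trials);
``psychometric-observer``
    for detection trials: reports "present" with probability psi(level)
    under a given psychometric parameter set, so threshold fits have a known
    ground truth to recover.

Reaction times are log-normal with a per-sound location shift, giving the
rank-based reaction-time comparison a true effect to detect. An optional
``p_ignore`` makes the agent miss the response window at random, producing
ignored trials. All randomness flows from one seeded generator: identical
seeds give byte-identical logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .psychometrics import PsychometricParams, psi
from .schedule import (
    AUTStepParams,
    ConfigurationError,
    Milestone,
    ProgressionConfig,
    ProgressionState,
    apply_outcome,
    build_aut_schedule,
    load_state,
    save_state,
)
from .tasks import OUTSIDE, SimClock, TaskSpec, TrialRecord, TrialSpec, run_trial, two_choice_task

__all__ = [
    "AgentSpec",
    "Agent",
    "TrainingResult",
    "agent_respond",
    "make_agent",
    "simulate_session",
    "simulate_training",
]

POLICIES = ("random", "ideal", "fixed-accuracy", "learning-curve", "psychometric-observer")


@dataclass(frozen=True)
class AgentSpec:
    """Response policy of one simulated subject."""

    policy: str = "random"
    p_correct: Optional[float] = None
    p_start: float = 0.5
    p_asymptote: float = 0.9
    tau_trials: float = 200.0
    psychometric: Optional[PsychometricParams] = None
    p_ignore: float = 0.0
    # log-normal (location, scale) of reaction-time seconds, keyed by sound_id
    rt_model: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    rt_default: tuple[float, float] = (-0.3, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ConfigurationError(f"unknown policy {self.policy!r}; choose from {POLICIES}")
        if self.policy == "fixed-accuracy" and (
            self.p_correct is None or not 0 <= self.p_correct <= 1
        ):
            raise ConfigurationError("fixed-accuracy requires p_correct in [0, 1]")
        if self.policy == "learning-curve":
            if not (0 <= self.p_start <= 1 and 0 <= self.p_asymptote <= 1):
                raise ConfigurationError("learning-curve probabilities must lie in [0, 1]")
            if self.tau_trials <= 0:
                raise ConfigurationError("tau_trials must be positive")
        if self.policy == "psychometric-observer" and self.psychometric is None:
            raise ConfigurationError("psychometric-observer requires psychometric parameters")
        if not 0 <= self.p_ignore <= 1:
            raise ConfigurationError("p_ignore must lie in [0, 1]")


class Agent:
    """Stateful wrapper around an :class:`AgentSpec`: one subject, one rng."""

    def __init__(self, spec: AgentSpec, rng: Optional[np.random.Generator] = None) -> None:
        self.spec = spec
        self.rng = rng if rng is not None else np.random.default_rng(spec.seed)
        self.trials_seen = 0

    def _p_correct_now(self) -> float:
        s = self.spec
        if s.policy == "ideal":
            return 1.0
        if s.policy == "fixed-accuracy":
            return float(s.p_correct)
        if s.policy == "learning-curve":
            t = self.trials_seen
            return s.p_asymptote - (s.p_asymptote - s.p_start) * float(np.exp(-t / s.tau_trials))
        raise AssertionError(s.policy)

    def _latency(self, sound_id: str) -> float:
        mu, sigma = self.spec.rt_model.get(sound_id, self.spec.rt_default)
        return float(self.rng.lognormal(mu, sigma))

    def respond(self, trial: TrialSpec) -> tuple[Optional[str], Optional[float]]:
        """Return (touched visual or None, latency in s) for one trial."""
        s = self.spec
        self.trials_seen += 1
        if s.p_ignore > 0 and self.rng.random() < s.p_ignore:
            return None, None

        distractors = [v for v, _ in trial.distractor_visuals]
        # A trial with a single displayed option (trigger shaping) can still be
        # failed by touching the background.
        wrong_options = distractors if distractors else [OUTSIDE]

        if s.policy == "random":
            options = [trial.target_visual] + wrong_options
            choice = options[self.rng.integers(len(options))]
        elif s.policy == "psychometric-observer":
            level = trial.level_db if trial.level_db is not None else 0.0
            p_present = psi(s.psychometric, level)
            say_present = self.rng.random() < p_present
            if trial.sound_id == "silence":
                present_visual = distractors[0] if distractors else OUTSIDE
                choice = present_visual if say_present else trial.target_visual
            else:
                choice = trial.target_visual if say_present else wrong_options[
                    self.rng.integers(len(wrong_options))
                ]
        else:
            if self.rng.random() < self._p_correct_now():
                choice = trial.target_visual
            else:
                choice = wrong_options[self.rng.integers(len(wrong_options))]
        return choice, self._latency(trial.sound_id)


def make_agent(spec: AgentSpec, rng: Optional[np.random.Generator] = None) -> Agent:
    return Agent(spec, rng)


def agent_respond(agent: Agent, trial: TrialSpec) -> tuple[Optional[str], Optional[float]]:
    """Functional entry point mirroring :meth:`Agent.respond`."""
    return agent.respond(trial)


def simulate_session(
    task: TaskSpec,
    agent: AgentSpec | Agent,
    n_trials: int,
    seed: Optional[int] = None,
    session_id: str = "s000",
    animal_id: str = "sim",
    clock: Optional[SimClock] = None,
) -> list[TrialRecord]:
    """Run one complete session and return its trial records.

    One seeded generator drives both stimulus sampling and the agent, so the
    whole log is reproducible (byte-identical after serialization) for a
    fixed seed. Timestamps are monotone session-relative seconds.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isinstance(agent, AgentSpec):
        rng = np.random.default_rng(agent.seed if seed is None else seed)
        agent = Agent(agent, rng)
    else:
        rng = agent.rng if seed is None else np.random.default_rng(seed)
        agent.rng = rng
    clock = clock if clock is not None else SimClock()

    records = []
    for i in range(n_trials):
        records.append(
            run_trial(
                task,
                agent.respond,
                rng,
                clock=clock,
                trial_index=i,
                session_id=session_id,
                animal_id=animal_id,
            )
        )
    return records


@dataclass
class TrainingResult:
    """Outcome of driving one agent through the full shaping schedule."""

    final_state: ProgressionState
    records: list[TrialRecord]
    step_trajectory: np.ndarray  # step occupied at each scored trial
    milestone_trials: dict[str, int]
    n_sessions: int

    @property
    def completed(self) -> bool:
        return self.final_state.completed


def simulate_training(
    agent: AgentSpec,
    schedule: Optional[Sequence[AUTStepParams]] = None,
    progression_config: Optional[ProgressionConfig] = None,
    session_lengths: int | Sequence[int] = 150,
    max_sessions: int = 60,
    seed: int = 0,
    task: Optional[TaskSpec] = None,
    state_dir: Optional[str] = None,
    animal_id: str = "sim",
) -> TrainingResult:
    """Drive an agent through the shaping schedule across sessions.

    Progress is folded trial by trial into a :class:`ProgressionState`; when
    ``state_dir`` is given the state is persisted to JSON after every session
    and reloaded before the next, exactly as a live system resumes a subject
    across breaks. Training stops when the agent reaches the completion step
    or after ``max_sessions`` sessions.
    """
    if max_sessions < 1:
        raise ValueError("max_sessions must be >= 1")
    schedule = tuple(schedule) if schedule is not None else build_aut_schedule()
    config = progression_config or ProgressionConfig()
    task = task or two_choice_task()
    if isinstance(session_lengths, int):
        lengths: list[int] = [session_lengths] * max_sessions
    else:
        lengths = list(session_lengths)
        if len(lengths) < max_sessions:
            lengths = lengths + [lengths[-1]] * (max_sessions - len(lengths))

    rng = np.random.default_rng(seed)
    live = Agent(agent, rng)
    state = ProgressionState(animal_id=animal_id, current_step=config.entry_step)
    if state_dir is not None:
        try:
            state = load_state(animal_id, state_dir)
        except FileNotFoundError:
            pass

    records: list[TrialRecord] = []
    trajectory: list[int] = []
    n_sessions = 0
    for session in range(max_sessions):
        if state.completed:
            break
        n_sessions += 1
        clock = SimClock()
        for i in range(lengths[session]):
            if state.completed:
                break
            step_params = schedule[state.current_step - config.entry_step]
            rec = run_trial(
                task,
                live.respond,
                rng,
                step_params=step_params,
                clock=clock,
                trial_index=i,
                session_id=f"s{session:03d}",
                animal_id=animal_id,
            )
            records.append(rec)
            outcome = rec.correct  # None for ignored trials
            if outcome is not None:
                trajectory.append(state.current_step)
            state = apply_outcome(state, outcome, config)
        if state_dir is not None:
            save_state(state, state_dir)

    milestone_trials: dict[str, int] = {m.value: 0 for m in Milestone}
    for rec in records:
        if rec.step is not None:
            milestone_trials[schedule[rec.step - config.entry_step].milestone.value] += 1

    return TrainingResult(
        final_state=state,
        records=records,
        step_trajectory=np.asarray(trajectory, dtype=int),
        milestone_trials=milestone_trials,
        n_sessions=n_sessions,
    )
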