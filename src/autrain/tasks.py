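"""Trial-level task logic: stimulus sampling, adjudication, reward rules.

Covers four task families sharing one trial state machine:

* ``aut`` — schedule-driven shaping trials (trigger touch, later full 2AC);
* ``2ac`` / ``3ac`` — audio-visual association: a sound plays, then two or
  three visual options appear and the subject touches one;
* ``detection`` — method of constant stimuli: a vocalization is played at a
  level drawn from a fixed set (0 dB SPL = silent trial) and the subject
  reports presence/absence by touching the associated visual.

Phases of a trial: trigger touch -> (sound lead 1-1.5 s when sound enabled)
-> options shown -> response window -> reward or gray-screen timeout ->
inter-trial interval. Time is simulated through an injectable clock so whole
sessions run in microseconds; wall-clock pacing is an optional mode.

Reward in choice tasks is contingent on touching the target. The detection
task uses a mixed scheme designed to keep subjects engaged near threshold:
levels inside the free-reward band (15-45 dB SPL, around the facility's
background noise) are rewarded regardless of choice, silent trials (0 dB)
only on the absence response, and loud trials (>= 60 dB) only on the
presence response.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .schedule import AUTStepParams, ConfigurationError

__all__ = [
    "StimulusPair",
    "TaskSpec",
    "TrialSpec",
    "TrialRecord",
    "SimClock",
    "WallClock",
    "draw_trial",
    "adjudicate_response",
    "detection_reward",
    "run_trial",
    "two_choice_task",
    "three_choice_task",
    "detection_task",
    "generalization_task",
    "DETECTION_LEVELS_DB",
    "OUTSIDE",
    "IGNORED",
]

# Touch outside every displayed option (background touch); always scored wrong.
OUTSIDE = "outside"
# Sentinel stored in the `choice` column of ignored trials.
IGNORED = "ignored"

# Constant-stimuli level set for the detection task, in dB SPL.
DETECTION_LEVELS_DB = (0.0, 15.0, 30.0, 45.0, 60.0, 70.0, 80.0)
# Levels in [15, 45] dB SPL are rewarded regardless of choice.
FREE_REWARD_BAND_DB = (15.0, 45.0)
# At and above this level the reward is choice-contingent (presence response).
CHOICE_CONTINGENT_MIN_DB = 60.0

_SIDES = {2: ("left", "right"), 3: ("left", "right", "extra-position")}


@dataclass(frozen=True)
class StimulusPair:
    """One sound and the visual permanently associated with it.

    ``role`` distinguishes target-capable pairs (the sound can be the trial's
    cue) from distractor-only visuals (3AC fillers with no associated sound,
    never presented as target).
    """

    sound_id: str
    visual_id: str
    role: str = "target-capable"


@dataclass(frozen=True)
class TaskSpec:
    variant: str  # aut | 2ac | 3ac | detection
    pairs: tuple[StimulusPair, ...]
    n_choices: int = 2
    levels_db: tuple[float, ...] = ()
    reward_rule: str = "choice-contingent"  # or detection-scheme
    timeout_s: float = 5.0
    response_window_s: float = 7.0
    iti_range_s: tuple[float, float] = (0.8, 2.5)
    sound_lead_range_s: tuple[float, float] = (1.0, 1.5)

    def __post_init__(self) -> None:
        if self.n_choices not in (2, 3):
            raise ConfigurationError("n_choices must be 2 or 3")
        if not self.pairs:
            raise ConfigurationError("task needs at least one stimulus pair")
        sounds = [p.sound_id for p in self.pairs if p.role == "target-capable"]
        if len(set(sounds)) != len(sounds):
            raise ConfigurationError("each sound_id must map to exactly one visual")
        if self.variant == "detection" and not self.levels_db:
            raise ConfigurationError("detection task requires a nonempty level set")
        if len({p.visual_id for p in self.pairs}) < self.n_choices:
            raise ConfigurationError("not enough distinct visuals for n_choices")

    @property
    def targets(self) -> tuple[StimulusPair, ...]:
        return tuple(p for p in self.pairs if p.role == "target-capable")

    @property
    def distractor_only(self) -> tuple[StimulusPair, ...]:
        return tuple(p for p in self.pairs if p.role == "distractor-only")

    def visual_for(self, sound_id: str) -> str:
        for p in self.pairs:
            if p.sound_id == sound_id:
                return p.visual_id
        raise KeyError(sound_id)


@dataclass(frozen=True)
class TrialSpec:
    """Resolved stimulus layout of one trial before any response."""

    trial_index: int
    sound_id: str
    level_db: Optional[float]
    target_visual: str
    target_side: str
    distractor_visuals: tuple[tuple[str, str], ...]  # (visual_id, side)

    @property
    def displayed(self) -> tuple[str, ...]:
        return (self.target_visual,) + tuple(v for v, _ in self.distractor_visuals)


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial as written to the session log."""

    session_id: str
    animal_id: str
    task: str
    step: Optional[int]
    trial: int
    t_start_s: float
    sound_id: str
    level_db: Optional[float]
    target_visual: str
    target_side: str
    choice: str  # visual id, "outside", "error", or "ignored"
    correct: Optional[bool]
    rewarded: bool
    reaction_time_s: Optional[float]


class SimClock:
    """Simulated session clock; `now` is session-relative seconds."""

    def __init__(self, start: float = 0.0) -> None:
        self.now = float(start)

    def advance(self, dt: float) -> None:
        self.now += float(dt)


class WallClock(SimClock):
    """Clock that actually waits, for paced live demonstrations."""

    def advance(self, dt: float) -> None:
        time.sleep(dt)
        super().advance(dt)


def two_choice_task(**overrides) -> TaskSpec:
    """Audio-visual 2AC: conspecific call vs pure-tone train."""
    pairs = (StimulusPair("voc", "face"), StimulusPair("sTr", "pattern"))
    return TaskSpec(variant="2ac", pairs=pairs, n_choices=2, **overrides)


def three_choice_task(**overrides) -> TaskSpec:
    """3AC variant: same sound-visual pairs plus a soundless distractor visual."""
    pairs = (
        StimulusPair("voc", "face"),
        StimulusPair("sTr", "pattern"),
        StimulusPair("", "noise-image", role="distractor-only"),
    )
    return TaskSpec(variant="3ac", pairs=pairs, n_choices=3, **overrides)


def detection_task(levels_db: Sequence[float] = DETECTION_LEVELS_DB, **overrides) -> TaskSpec:
    """Vocalization-detection task by the method of constant stimuli.

    Presence is reported by touching the face, absence by the triangles;
    0 dB SPL trials are silent trials.
    """
    pairs = (StimulusPair("voc", "face"), StimulusPair("silence", "triangles"))
    return TaskSpec(
        variant="detection",
        pairs=pairs,
        n_choices=2,
        levels_db=tuple(float(x) for x in levels_db),
        reward_rule="detection-scheme",
        **overrides,
    )


def generalization_task(sound_a: str, visual_a: str, sound_b: str, visual_b: str, **overrides) -> TaskSpec:
    """A 2AC variant with novel stimuli (e.g. twitter vs sTr, noise vs twitter)."""
    pairs = (StimulusPair(sound_a, visual_a), StimulusPair(sound_b, visual_b))
    return TaskSpec(variant="2ac", pairs=pairs, n_choices=2, **overrides)


def draw_trial(task: TaskSpec, rng: np.random.Generator, trial_index: int = 0) -> TrialSpec:
    """Sample one trial layout uniformly from the task's stimulus sets.

    Sound (and level, for detection) and target side are drawn independently
    and uniformly; distractor visuals fill the remaining positions.
    """
    sides = _SIDES[task.n_choices]

    if task.variant == "detection":
        level = float(rng.choice(task.levels_db))
        # 0 dB SPL stands for both the silent trial and the vocalization at
        # zero amplitude; modeled as a single silent-trial type.
        if level == 0.0:
            sound_id = "silence"
        else:
            sound_id = next(p.sound_id for p in task.targets if p.sound_id != "silence")
        target_visual = task.visual_for(sound_id)
    else:
        pair = task.targets[rng.integers(len(task.targets))]
        sound_id, target_visual = pair.sound_id, pair.visual_id
        level = None

    target_side = sides[rng.integers(len(sides))]
    other_sides = [s for s in sides if s != target_side]

    # Remaining target-capable visuals first, then distractor-only fillers.
    pool = [p.visual_id for p in task.targets if p.visual_id != target_visual]
    pool += [p.visual_id for p in task.distractor_only]
    needed = task.n_choices - 1
    if len(pool) < needed:
        raise ConfigurationError("not enough distractor visuals to fill all positions")
    chosen = list(pool[:needed])
    rng.shuffle(other_sides)
    distractors = tuple(zip(chosen, other_sides))

    return TrialSpec(
        trial_index=trial_index,
        sound_id=sound_id,
        level_db=level,
        target_visual=target_visual,
        target_side=target_side,
        distractor_visuals=distractors,
    )


def draw_aut_trial(
    step: AUTStepParams, task: TaskSpec, rng: np.random.Generator, trial_index: int = 0
) -> TrialSpec:
    """Sample one shaping trial according to the current schedule position.

    Before sound onset (steps < 36) the scored touch is the trigger itself;
    its placement is central during the size milestone and drawn uniformly
    left/right afterwards. From step 46 a distractor (the other pair's
    visual) appears on the opposite side.
    """
    if step.sound_enabled:
        pair = task.targets[rng.integers(len(task.targets))]
        sound_id, target_visual = pair.sound_id, pair.visual_id
    else:
        sound_id, target_visual = "", "trigger"

    if step.trigger_offset_mm == 0 and not step.two_touch:
        target_side = "center"
        other = ""
    elif rng.integers(2) == 0:
        target_side, other = "left", "right"
    else:
        target_side, other = "right", "left"

    distractors: tuple[tuple[str, str], ...] = ()
    if step.distractor_enabled:
        alt = next(v for v in (p.visual_id for p in task.targets) if v != target_visual)
        distractors = ((alt, other),)

    return TrialSpec(
        trial_index=trial_index,
        sound_id=sound_id,
        level_db=step.sound_level_db if step.sound_enabled else None,
        target_visual=target_visual,
        target_side=target_side,
        distractor_visuals=distractors,
    )


def adjudicate_response(
    trial: TrialSpec,
    response: Optional[str],
    latency_s: Optional[float],
    response_window_s: float = 7.0,
) -> str:
    """Score a touch (or its absence) as correct / wrong / ignored.

    No touch, or a touch after the response window, is ignored. A background
    touch (``OUTSIDE``) is wrong. Any other touched visual must be one of the
    displayed options.
    """
    if response is None:
        return "ignored"
    if latency_s is None or latency_s < 0:
        raise ValueError("a response requires a non-negative latency")
    if latency_s > response_window_s:
        return "ignored"
    if response == trial.target_visual:
        return "correct"
    if response == OUTSIDE or response in {v for v, _ in trial.distractor_visuals}:
        return "wrong"
    raise ValueError(f"touched visual {response!r} is not displayed in this trial")


def detection_reward(
    level_db: float,
    choice: str,
    levels_db: Sequence[float] = DETECTION_LEVELS_DB,
    present_visual: str = "face",
    absent_visual: str = "triangles",
) -> bool:
    """Level-dependent reward scheme of the detection task.

    Levels inside the free-reward band are rewarded regardless of choice;
    silent trials only on the absence response; levels at or above the
    choice-contingent floor only on the presence response.
    """
    if level_db not in [float(x) for x in levels_db]:
        raise ValueError(f"level {level_db} dB SPL is not in the configured set")
    if choice not in (present_visual, absent_visual):
        raise ValueError(f"choice {choice!r} is not a detection response option")
    lo, hi = FREE_REWARD_BAND_DB
    if lo <= level_db <= hi:
        return True
    if level_db == 0.0:
        return choice == absent_visual
    if level_db >= CHOICE_CONTINGENT_MIN_DB:
        return choice == present_visual
    raise ValueError(f"level {level_db} dB SPL falls in no reward band")


Responder = Callable[[TrialSpec], tuple[Optional[str], Optional[float]]]


def run_trial(
    task: TaskSpec,
    responder: Responder,
    rng: np.random.Generator,
    step_params: Optional[AUTStepParams] = None,
    clock: Optional[SimClock] = None,
    trial_index: int = 0,
    session_id: str = "s000",
    animal_id: str = "sim",
) -> TrialRecord:
    """Execute one full trial and return its log record.

    The responder callback receives the trial layout and returns a touched
    visual (or None) with its latency. The clock is advanced through sound
    lead, response time, timeout after wrong responses, and the inter-trial
    interval drawn uniformly from ``iti_range_s``. Sequences are bit-identical
    for a fixed seed.
    """
    clock = clock if clock is not None else SimClock()

    if step_params is not None:
        trial = draw_aut_trial(step_params, task, rng, trial_index)
        sound_on = step_params.sound_enabled
        timeout_s = step_params.timeout_s
        response_window_s = step_params.response_window_s
        iti_range = step_params.iti_range_s
        step: Optional[int] = step_params.step_index
    else:
        trial = draw_trial(task, rng, trial_index)
        sound_on = task.variant != "aut"
        timeout_s = task.timeout_s
        response_window_s = task.response_window_s
        iti_range = task.iti_range_s
        step = None

    t_start = clock.now
    if sound_on:
        clock.advance(rng.uniform(*task.sound_lead_range_s))

    try:
        response, latency = responder(trial)
    except Exception:
        clock.advance(response_window_s)
        return TrialRecord(
            session_id, animal_id, task.variant, step, trial_index, t_start,
            trial.sound_id, trial.level_db, trial.target_visual, trial.target_side,
            choice="error", correct=None, rewarded=False, reaction_time_s=None,
        )

    outcome = adjudicate_response(trial, response, latency, response_window_s)

    if outcome == "ignored":
        clock.advance(response_window_s)
        choice, correct, rewarded, rt = IGNORED, None, False, None
    else:
        assert response is not None and latency is not None
        clock.advance(latency)
        choice, rt = response, latency
        correct = outcome == "correct"
        if task.reward_rule == "detection-scheme":
            if choice == OUTSIDE:
                rewarded = False
            else:
                rewarded = detection_reward(trial.level_db, choice, task.levels_db)
        else:
            rewarded = correct
        if outcome == "wrong":
            clock.advance(timeout_s)  # gray screen; touches ignored

    clock.advance(rng.uniform(*iti_range))

    return TrialRecord(
        session_id, animal_id, task.variant, step, trial_index, t_start,
        trial.sound_id, trial.level_db, trial.target_visual, trial.target_side,
        choice, correct, rewarded, rt,
    )
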