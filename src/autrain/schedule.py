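"""Automated unsupervised training (AUT) schedule and progression engine.

The AUT shapes a naive subject from touching a large central trigger to
performing a full two-alternative-choice (2AC) audio-visual trial. It is
organised as 49 schedule positions — one entry step plus 48 dynamic steps —
grouped into four milestones:

``size``
    steps 1-15: a central trigger shrinks from 6 x 6 cm to 3 x 3 cm.
``position``
    steps 16-30: the trigger drifts laterally by 5 mm per step until it
    reaches the screen edge.
``delay``
    steps 31-45: trials become two-touch (centre trigger, then peripheral
    target); from step 36 a sound precedes the visual target by 1-1.5 s,
    ramping from 32 dB SPL (step 36) to 72 dB SPL (step 40) in 10 dB steps.
``choice``
    steps 46-49: a visual distractor appears opposite the target, growing
    from 0.3 x 0.3 cm to 2.8 x 2.8 cm.

Reaching step 50 marks completion and hands the subject over to the
free-standing 2AC task. Progression is driven per scored trial by a sliding
window of the last 10 outcomes: >= 8 correct advances one step, <= 2 correct
retreats one step. Ignored trials (no response within the response window)
never enter the window. Progress persists across sessions via a small JSON
document per subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "Milestone",
    "Decision",
    "ScheduleConfig",
    "AUTStepParams",
    "ProgressionConfig",
    "ProgressionState",
    "ConfigurationError",
    "StateError",
    "build_aut_schedule",
    "window_decision",
    "apply_outcome",
    "write_step_table",
    "save_state",
    "load_state",
]

STEP_TABLE_COLUMNS = (
    "step",
    "milestone",
    "trigger_edge_cm",
    "trigger_offset_mm",
    "two_touch",
    "sound_enabled",
    "sound_level_db",
    "sound_lead_s",
    "distractor_enabled",
    "distractor_edge_cm",
    "timeout_s",
    "response_window_s",
)


class ConfigurationError(ValueError):
    """Raised when schedule or progression constants are inconsistent."""


class StateError(RuntimeError):
    """Raised when an operation is applied to an invalid progression state."""


class Milestone(str, Enum):
    SIZE = "size"
    POSITION = "position"
    DELAY = "delay"
    CHOICE = "choice"


class Decision(str, Enum):
    ADVANCE = "advance"
    RETREAT = "retreat"
    STAY = "stay"


# Milestone boundaries (inclusive step ranges).
_SIZE_LAST = 15
_POSITION_LAST = 30
_DELAY_LAST = 45
_LAST_STEP = 49
_SOUND_FIRST = 36
_SOUND_RAMP_LAST = 40
_DISTRACTOR_FIRST = 46


@dataclass(frozen=True)
class ScheduleConfig:
    """Constants from which the 49-position step table is expanded.

    ``screen_edge_offset_mm`` is the horizontal distance from screen centre
    to the peripheral stimulus position; the position milestone needs 15
    steps of ``offset_step_mm`` to reach it, so it must be at least 75 mm.
    """

    screen_edge_offset_mm: float = 75.0
    trigger_start_cm: float = 6.0
    trigger_final_cm: float = 3.0
    offset_step_mm: float = 5.0
    sound_start_db: float = 32.0
    sound_step_db: float = 10.0
    distractor_start_cm: float = 0.3
    distractor_final_cm: float = 2.8
    timeout_s: float = 5.0
    response_window_s: float = 7.0
    iti_range_s: tuple[float, float] = (0.8, 2.5)
    sound_lead_range_s: tuple[float, float] = (1.0, 1.5)

    def validate(self) -> None:
        if self.screen_edge_offset_mm < 75.0:
            raise ConfigurationError(
                "screen_edge_offset_mm must be >= 75 mm so the position "
                f"milestone can reach the screen edge (got {self.screen_edge_offset_mm})"
            )
        for name in ("timeout_s", "response_window_s", "offset_step_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 < self.trigger_final_cm < self.trigger_start_cm):
            raise ConfigurationError("trigger sizes must satisfy 0 < final < start")
        if not (0 < self.distractor_start_cm <= self.distractor_final_cm):
            raise ConfigurationError("distractor sizes must satisfy 0 < start <= final")
        lo, hi = self.iti_range_s
        if not (0 <= lo <= hi):
            raise ConfigurationError("iti_range_s must be an ordered non-negative pair")
        lo, hi = self.sound_lead_range_s
        if not (0 <= lo <= hi):
            raise ConfigurationError("sound_lead_range_s must be an ordered non-negative pair")


@dataclass(frozen=True)
class AUTStepParams:
    """Full stimulus/timing parameterisation of one AUT schedule position.

    ``sound_lead_s`` is the nominal sound-to-visual onset asynchrony (the
    midpoint of the configured jitter range); the trial engine draws the
    actual lead uniformly from that range on every trial.
    """

    step_index: int
    milestone: Milestone
    trigger_edge_cm: float
    trigger_offset_mm: float
    two_touch: bool
    sound_enabled: bool
    sound_level_db: Optional[float]
    sound_lead_s: Optional[float]
    distractor_enabled: bool
    distractor_edge_cm: Optional[float]
    timeout_s: float
    response_window_s: float
    iti_range_s: tuple[float, float]


def _milestone_of(step: int) -> Milestone:
    if step <= _SIZE_LAST:
        return Milestone.SIZE
    if step <= _POSITION_LAST:
        return Milestone.POSITION
    if step <= _DELAY_LAST:
        return Milestone.DELAY
    return Milestone.CHOICE


def build_aut_schedule(config: ScheduleConfig | None = None) -> tuple[AUTStepParams, ...]:
    """Expand the schedule constants into the ordered 49-entry step table.

    Deterministic for a fixed config. The trigger size over steps 1-15 and
    the distractor size over steps 46-49 interpolate linearly between their
    stated endpoints.
    """
    config = config or ScheduleConfig()
    config.validate()

    steps = []
    lead_nominal = sum(config.sound_lead_range_s) / 2.0
    for step in range(1, _LAST_STEP + 1):
        milestone = _milestone_of(step)

        if step <= _SIZE_LAST:
            frac = (step - 1) / (_SIZE_LAST - 1)
            edge = config.trigger_start_cm - frac * (config.trigger_start_cm - config.trigger_final_cm)
        else:
            edge = config.trigger_final_cm

        if step <= _SIZE_LAST:
            offset = 0.0
        else:
            offset = min(
                config.offset_step_mm * min(step - _SIZE_LAST, _POSITION_LAST - _SIZE_LAST),
                config.screen_edge_offset_mm,
            )

        sound_on = step >= _SOUND_FIRST
        if sound_on:
            ramp = min(step, _SOUND_RAMP_LAST) - _SOUND_FIRST
            level: Optional[float] = config.sound_start_db + ramp * config.sound_step_db
        else:
            level = None

        distractor_on = step >= _DISTRACTOR_FIRST
        if distractor_on:
            frac = (step - _DISTRACTOR_FIRST) / (_LAST_STEP - _DISTRACTOR_FIRST)
            dedge: Optional[float] = (
                config.distractor_start_cm
                + frac * (config.distractor_final_cm - config.distractor_start_cm)
            )
        else:
            dedge = None

        steps.append(
            AUTStepParams(
                step_index=step,
                milestone=milestone,
                trigger_edge_cm=round(edge, 6),
                trigger_offset_mm=round(offset, 6),
                two_touch=step > _POSITION_LAST,
                sound_enabled=sound_on,
                sound_level_db=level,
                sound_lead_s=lead_nominal if sound_on else None,
                distractor_enabled=distractor_on,
                distractor_edge_cm=round(dedge, 6) if dedge is not None else None,
                timeout_s=config.timeout_s,
                response_window_s=config.response_window_s,
                iti_range_s=config.iti_range_s,
            )
        )
    return tuple(steps)


def write_step_table(schedule: Sequence[AUTStepParams], path: str | Path) -> None:
    """Write the fully expanded step table as CSV (empty cells for absent values)."""
    lines = [",".join(STEP_TABLE_COLUMNS)]
    for p in schedule:
        row = [
            str(p.step_index),
            p.milestone.value,
            f"{p.trigger_edge_cm:g}",
            f"{p.trigger_offset_mm:g}",
            str(p.two_touch),
            str(p.sound_enabled),
            "" if p.sound_level_db is None else f"{p.sound_level_db:g}",
            "" if p.sound_lead_s is None else f"{p.sound_lead_s:g}",
            str(p.distractor_enabled),
            "" if p.distractor_edge_cm is None else f"{p.distractor_edge_cm:g}",
            f"{p.timeout_s:g}",
            f"{p.response_window_s:g}",
        ]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ProgressionConfig:
    """Sliding-window thresholds governing step transitions.

    Advance when the full window holds at least ``advance_min_correct``
    correct outcomes; retreat when it holds at most ``retreat_max_correct``.
    """

    window_len: int = 10
    advance_min_correct: int = 8
    retreat_max_correct: int = 2
    entry_step: int = 1
    completion_step: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.retreat_max_correct < self.advance_min_correct <= self.window_len):
            raise ConfigurationError(
                "need retreat_max_correct < advance_min_correct <= window_len"
            )
        if not (1 <= self.entry_step < self.completion_step):
            raise ConfigurationError("need 1 <= entry_step < completion_step")


@dataclass(frozen=True)
class ProgressionState:
    """A subject's current step plus its recent-outcome window.

    Immutable; :func:`apply_outcome` returns the successor state. The window
    holds scored outcomes only (most recent last) accumulated since the last
    step change.
    """

    animal_id: str
    current_step: int = 1
    outcome_window: tuple[bool, ...] = ()
    completed: bool = False

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "current_step": self.current_step,
            "outcome_window": [bool(o) for o in self.outcome_window],
            "completed": self.completed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProgressionState":
        return cls(
            animal_id=str(d["animal_id"]),
            current_step=int(d["current_step"]),
            outcome_window=tuple(bool(o) for o in d["outcome_window"]),
            completed=bool(d["completed"]),
        )


def window_decision(
    outcome_window: Iterable[bool], config: ProgressionConfig | None = None
) -> Decision:
    """Decide advance/retreat/stay from a window of scored outcomes.

    Incomplete windows (fewer than ``window_len`` outcomes) always stay.
    """
    config = config or ProgressionConfig()
    window = list(outcome_window)
    if len(window) < config.window_len:
        return Decision.STAY
    n_correct = sum(bool(o) for o in window[-config.window_len:])
    if n_correct >= config.advance_min_correct:
        return Decision.ADVANCE
    if n_correct <= config.retreat_max_correct:
        return Decision.RETREAT
    return Decision.STAY


def apply_outcome(
    state: ProgressionState,
    trial_correct: Optional[bool],
    config: ProgressionConfig | None = None,
) -> ProgressionState:
    """Fold one trial outcome into the progression state.

    ``trial_correct`` is True/False for scored trials and None for ignored
    trials, which leave the state untouched. The step changes by at most one
    per scored trial, clamped to [entry_step, completion_step]; on any step
    change the window is cleared so consecutive transitions require fresh
    evidence. Reaching ``completion_step`` marks the state completed.
    """
    config = config or ProgressionConfig()
    if state.completed:
        raise StateError(f"subject {state.animal_id!r} has already completed the schedule")
    if trial_correct is None:
        return state

    window = (state.outcome_window + (bool(trial_correct),))[-config.window_len:]
    decision = window_decision(window, config)
    step = state.current_step
    if decision is Decision.ADVANCE:
        step = min(step + 1, config.completion_step)
    elif decision is Decision.RETREAT:
        step = max(step - 1, config.entry_step)

    if step != state.current_step:
        window = ()
    return ProgressionState(
        animal_id=state.animal_id,
        current_step=step,
        outcome_window=window,
        completed=step >= config.completion_step,
    )


def save_state(state: ProgressionState, directory: str | Path) -> Path:
    """Persist a per-subject progression state as JSON; returns the file path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{state.animal_id}.json"
    path.write_text(json.dumps(state.to_dict(), indent=2) + "\n")
    return path


def load_state(animal_id: str, directory: str | Path) -> ProgressionState:
    path = Path(directory) / f"{animal_id}.json"
    if not path.exists():
        raise FileNotFoundError(f"no persisted state for subject {animal_id!r} in {directory}")
    return ProgressionState.from_dict(json.loads(path.read_text()))
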