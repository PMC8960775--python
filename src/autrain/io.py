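"""Session-log file formats and run configuration.

The canonical on-disk dialect is CSV (comma-separated, dot decimal, UTF-8,
mandatory header); an equivalent JSON-lines dialect is offered for
streaming. Both round-trip :class:`~autrain.tasks.TrialRecord` sequences
losslessly, with empty cells / nulls for absent values. Each log may carry a
small JSON metadata sidecar (subject, task, schedule version, seed, session
start).

Run configuration lives in one YAML document with nested sections
(``schedule``, ``progression``, ``tasks``, ``agents``); unknown keys are
rejected so typos fail loudly before any simulation starts.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .agents import AgentSpec
from .psychometrics import LevelCounts, PsychometricParams
from .schedule import ConfigurationError, ProgressionConfig, ScheduleConfig
from .tasks import (
    StimulusPair,
    TaskSpec,
    TrialRecord,
    detection_task,
    generalization_task,
    three_choice_task,
    two_choice_task,
)

__all__ = [
    "SESSION_LOG_COLUMNS",
    "read_session_log",
    "write_session_log",
    "to_frame",
    "from_frame",
    "read_level_counts",
    "write_level_counts",
    "RunConfig",
    "load_run_config",
    "task_from_config",
    "agent_from_config",
    "LogFormatError",
]

SESSION_LOG_COLUMNS = (
    "session_id",
    "animal_id",
    "task",
    "step",
    "trial",
    "t_start_s",
    "sound_id",
    "level_db",
    "target_visual",
    "target_side",
    "choice",
    "correct",
    "rewarded",
    "reaction_time_s",
)


class LogFormatError(ValueError):
    """Raised for malformed session-log files; messages name the line."""


def _record_to_row(rec: TrialRecord) -> dict[str, str]:
    def fmt(v: Any) -> str:
        if v is None:
            return ""
        if isinstance(v, bool):
            return str(v)
        if isinstance(v, float):
            return repr(v)
        return str(v)

    return {c: fmt(getattr(rec, _FIELD_BY_COLUMN[c])) for c in SESSION_LOG_COLUMNS}


_FIELD_BY_COLUMN = {c: c for c in SESSION_LOG_COLUMNS}


def _parse_row(row: Mapping[str, str], lineno: int) -> TrialRecord:
    def opt_float(v: str) -> Optional[float]:
        return None if v == "" else float(v)

    def opt_int(v: str) -> Optional[int]:
        return None if v == "" else int(v)

    def parse_bool(v: str) -> bool:
        if v in ("True", "true"):
            return True
        if v in ("False", "false"):
            return False
        raise ValueError(f"not a boolean: {v!r}")

    def opt_bool(v: str) -> Optional[bool]:
        return None if v == "" else parse_bool(v)

    try:
        return TrialRecord(
            session_id=str(row["session_id"]),
            animal_id=str(row["animal_id"]),
            task=str(row["task"]),
            step=opt_int(row["step"]),
            trial=int(row["trial"]),
            t_start_s=float(row["t_start_s"]),
            sound_id=str(row["sound_id"]),
            level_db=opt_float(row["level_db"]),
            target_visual=str(row["target_visual"]),
            target_side=str(row["target_side"]),
            choice=str(row["choice"]),
            correct=opt_bool(row["correct"]),
            rewarded=parse_bool(row["rewarded"]),
            reaction_time_s=opt_float(row["reaction_time_s"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise LogFormatError(f"malformed trial row at line {lineno}: {exc}") from exc


def write_session_log(
    records: Sequence[TrialRecord],
    path: str | Path,
    fmt: Optional[str] = None,
    meta: Optional[Mapping[str, Any]] = None,
) -> Path:
    """Write records as CSV (default) or JSON-lines; ``fmt`` in {csv, jsonl}.

    The format is inferred from the suffix when ``fmt`` is omitted. When
    ``meta`` is given, a ``<path>.meta.json`` sidecar is written alongside.
    """
    path = Path(path)
    fmt = fmt or ("jsonl" if path.suffix in (".jsonl", ".ndjson") else "csv")
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=SESSION_LOG_COLUMNS)
            writer.writeheader()
            for rec in records:
                writer.writerow(_record_to_row(rec))
    elif fmt == "jsonl":
        with path.open("w") as fh:
            for rec in records:
                fh.write(json.dumps(dataclasses.asdict(rec)) + "\n")
    else:
        raise ValueError(f"unknown log format {fmt!r}")
    if meta is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(dict(meta), indent=2) + "\n")
    return path


def read_session_log(path: str | Path, fmt: Optional[str] = None) -> list[TrialRecord]:
    """Losslessly parse a session log; malformed rows raise naming the line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("jsonl" if path.suffix in (".jsonl", ".ndjson") else "csv")
    records: list[TrialRecord] = []
    if fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise LogFormatError("empty file: missing header") from None
            if tuple(header) != SESSION_LOG_COLUMNS:
                raise LogFormatError(
                    f"unexpected header {header!r}; expected {list(SESSION_LOG_COLUMNS)}"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != len(SESSION_LOG_COLUMNS):
                    raise LogFormatError(
                        f"malformed trial row at line {lineno}: expected "
                        f"{len(SESSION_LOG_COLUMNS)} fields, got {len(row)}"
                    )
                records.append(_parse_row(dict(zip(SESSION_LOG_COLUMNS, row)), lineno))
    elif fmt == "jsonl":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise LogFormatError(f"malformed trial row at line {lineno}: {exc}") from exc
                row = {
                    c: "" if obj.get(c) is None else (str(obj[c]) if not isinstance(obj[c], float) else repr(obj[c]))
                    for c in SESSION_LOG_COLUMNS
                }
                records.append(_parse_row(row, lineno))
    else:
        raise ValueError(f"unknown log format {fmt!r}")
    return records


def to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Session records as the DataFrame dialect the analysis module consumes."""
    if not records:
        return pd.DataFrame(columns=SESSION_LOG_COLUMNS)
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return frame[list(SESSION_LOG_COLUMNS)]


def from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        d = row._asdict()
        records.append(
            TrialRecord(
                session_id=str(d["session_id"]),
                animal_id=str(d["animal_id"]),
                task=str(d["task"]),
                step=None if pd.isna(d["step"]) else int(d["step"]),
                trial=int(d["trial"]),
                t_start_s=float(d["t_start_s"]),
                sound_id=str(d["sound_id"]),
                level_db=None if pd.isna(d["level_db"]) else float(d["level_db"]),
                target_visual=str(d["target_visual"]),
                target_side=str(d["target_side"]),
                choice=str(d["choice"]),
                correct=None if pd.isna(d["correct"]) else bool(d["correct"]),
                rewarded=bool(d["rewarded"]),
                reaction_time_s=None if pd.isna(d["reaction_time_s"]) else float(d["reaction_time_s"]),
            )
        )
    return records


def read_level_counts(path: str | Path) -> LevelCounts:
    """Read a per-level counts CSV with header ``level_db,n,k``."""
    frame = pd.read_csv(path)
    expected = ["level_db", "n", "k"]
    if list(frame.columns) != expected:
        raise LogFormatError(f"unexpected header {list(frame.columns)}; expected {expected}")
    return LevelCounts(frame["level_db"].to_numpy(), frame["n"].to_numpy(), frame["k"].to_numpy())


def write_level_counts(counts: LevelCounts, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"level_db": counts.levels, "n": counts.n, "k": counts.k}).to_csv(
        path, index=False
    )
    return path


# --- run configuration -----------------------------------------------------

_TASK_BUILDERS = {
    "2ac": two_choice_task,
    "3ac": three_choice_task,
    "detection": detection_task,
}


def task_from_config(cfg: Mapping[str, Any]) -> TaskSpec:
    """Build a TaskSpec from a config mapping.

    Either ``variant`` selects a built-in task (2ac/3ac/detection, with
    optional timing overrides and ``levels_db`` for detection), or explicit
    ``pairs`` define a generalization variant with the same 2AC logic.
    """
    cfg = dict(cfg)
    variant = cfg.pop("variant", None)
    pairs = cfg.pop("pairs", None)
    if pairs is not None:
        built = tuple(
            StimulusPair(p["sound_id"], p["visual_id"], p.get("role", "target-capable"))
            for p in pairs
        )
        return TaskSpec(variant=variant or "2ac", pairs=built, **cfg)
    if variant not in _TASK_BUILDERS:
        raise ConfigurationError(f"unknown task variant {variant!r}")
    return _TASK_BUILDERS[variant](**cfg)


def agent_from_config(cfg: Mapping[str, Any]) -> AgentSpec:
    cfg = dict(cfg)
    psych = cfg.pop("psychometric", None)
    if psych is not None:
        cfg["psychometric"] = PsychometricParams(**psych)
    rt = cfg.pop("rt_model", None)
    if rt is not None:
        cfg["rt_model"] = {k: tuple(v) for k, v in rt.items()}
    try:
        return AgentSpec(**cfg)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    progression: ProgressionConfig = field(default_factory=ProgressionConfig)
    tasks: Mapping[str, TaskSpec] = field(default_factory=dict)
    agents: Mapping[str, AgentSpec] = field(default_factory=dict)
    output_dir: str = "."


_TOP_LEVEL_KEYS = {"seed", "schedule", "progression", "tasks", "agents", "output_dir"}


def _build_dataclass(cls, cfg: Mapping[str, Any], section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(cfg) - names
    if unknown:
        raise ConfigurationError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()
    }
    return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("run config must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown top-level keys: {sorted(unknown)}")
    schedule = _build_dataclass(ScheduleConfig, raw.get("schedule", {}), "schedule")
    schedule.validate()
    progression = _build_dataclass(ProgressionConfig, raw.get("progression", {}), "progression")
    tasks = {name: task_from_config(cfg) for name, cfg in (raw.get("tasks") or {}).items()}
    agents = {name: agent_from_config(cfg) for name, cfg in (raw.get("agents") or {}).items()}
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        schedule=schedule,
        progression=progression,
        tasks=tasks,
        agents=agents,
        output_dir=str(raw.get("output_dir", ".")),
    )
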