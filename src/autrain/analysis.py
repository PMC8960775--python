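"""Performance, engagement, and inferential statistics over session logs.

Works on the tabular session-log dialect produced by the trial engine (one
row per trial; see :mod:`autrain.io`). The central products are:

* a per-(subject, task, stimulus) performance table with hit rates, the
  signal-detection sensitivity index d', and one-sided binomial tests of
  performance against chance, Bonferroni-adjusted across the family of
  comparisons;
* rank-based reaction-time comparisons (Kruskal-Wallis by ranks);
* engagement summaries: trials per session, zero-trial sessions, and the
  median trial timestamp normalized by session duration;
* learning curves on a standardized percent-of-total-trials axis, so
  subjects with very different trial counts share one abscissa;
* partial Pearson correlation (engagement vs session number controlling for
  session duration).

d' uses the standard yes/no convention z(H) - z(FA), where the hit rate on
one stimulus plays the false-alarm role for the other, with the 1/(2N)
adjustment for perfect rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .psychometrics import LevelCounts

__all__ = [
    "hit_rate_table",
    "dprime",
    "binomial_vs_chance",
    "bonferroni_adjust",
    "bonferroni_alpha",
    "kruskal_wallis_ranks",
    "engagement_summary",
    "learning_curve_bins",
    "partial_pearson",
    "detection_level_counts",
    "reaction_times_by_sound",
    "EngagementSummary",
    "PartialCorrResult",
    "KruskalResult",
]

_CHANCE_BY_TASK = {"2ac": 0.5, "3ac": 1.0 / 3.0, "detection": 0.5, "aut": 0.5}


def _last_k_filter(logs: pd.DataFrame, last_k_sessions: Optional[int]) -> pd.DataFrame:
    if last_k_sessions is None:
        return logs
    keep = []
    for animal, g in logs.groupby("animal_id", sort=False):
        sessions = list(dict.fromkeys(g["session_id"]))  # order of appearance
        tail = set(sessions[-last_k_sessions:])
        keep.append(g[g["session_id"].isin(tail)])
    return pd.concat(keep) if keep else logs


def hit_rate_table(
    logs: pd.DataFrame,
    last_k_sessions: Optional[int] = None,
    p_chance: Optional[float] = None,
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """Per-stimulus performance over the selected session window.

    Rows are keyed by (animal_id, task, sound_id). Ignored trials are counted
    separately and excluded from the hit rate. ``p_chance`` defaults to the
    task's chance level (1/2 for 2AC, 1/3 for 3AC). d' is computed for
    two-stimulus groups, each stimulus's errors serving as the other's false
    alarms; groups with a different stimulus count get NaN. The binomial
    p-values are one-sided (upper tail) and Bonferroni-adjusted over
    ``family_size`` comparisons (default: the number of table rows).
    """
    if logs.empty:
        return pd.DataFrame(
            columns=[
                "animal_id", "task", "sound_id", "n_trials", "n_scored",
                "n_correct", "n_ignored", "hit_rate", "d_prime",
                "p_value_raw", "p_value_adjusted",
            ]
        )
    logs = _last_k_filter(logs, last_k_sessions)

    rows = []
    for (animal, task, sound), g in logs.groupby(["animal_id", "task", "sound_id"], sort=True):
        ignored = g["choice"].isin(["ignored", "error"])
        scored = g[~ignored]
        n_scored = len(scored)
        n_correct = int((scored["correct"] == True).sum())  # noqa: E712 — NaN-safe
        chance = p_chance if p_chance is not None else _CHANCE_BY_TASK.get(str(task), 0.5)
        rows.append(
            {
                "animal_id": animal,
                "task": task,
                "sound_id": sound,
                "n_trials": len(g),
                "n_scored": n_scored,
                "n_correct": n_correct,
                "n_ignored": int(ignored.sum()),
                "hit_rate": n_correct / n_scored if n_scored else np.nan,
                "d_prime": np.nan,
                "p_value_raw": binomial_vs_chance(n_correct, n_scored, chance)
                if n_scored
                else np.nan,
            }
        )
    table = pd.DataFrame(rows)

    # pairwise d': within each (animal, task), the other stimulus's errors are
    # this stimulus's false alarms
    for (animal, task), g in table.groupby(["animal_id", "task"], sort=False):
        if len(g) != 2 or g["n_scored"].min() == 0:
            continue
        i, j = g.index
        table.loc[i, "d_prime"] = dprime(
            table.loc[i, "hit_rate"], table.loc[j, "hit_rate"],
            int(table.loc[i, "n_scored"]), int(table.loc[j, "n_scored"]),
        )
        table.loc[j, "d_prime"] = dprime(
            table.loc[j, "hit_rate"], table.loc[i, "hit_rate"],
            int(table.loc[j, "n_scored"]), int(table.loc[i, "n_scored"]),
        )

    m = family_size if family_size is not None else len(table)
    table["p_value_adjusted"] = bonferroni_adjust(table["p_value_raw"].to_numpy(), m)
    return table


def dprime(
    hit_rate_a: float,
    hit_rate_b: float,
    n_a: int,
    n_b: int,
    correction: str = "2N",
) -> float:
    """Signal-detection sensitivity index z(H) - z(FA).

    ``hit_rate_a`` is the hit rate on A-trials; the false-alarm rate is taken
    as 1 - ``hit_rate_b``, i.e. the fraction of B-trials answered A. Rates of
    exactly 0 or 1 are replaced by 1/(2N) and 1 - 1/(2N) before the quantile
    transform so the index stays finite.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("trial counts must be >= 1")
    if not (0 <= hit_rate_a <= 1 and 0 <= hit_rate_b <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if correction not in ("2N", "none"):
        raise ValueError(f"unknown correction {correction!r}")

    def adjust(rate: float, n: int) -> float:
        if correction == "2N":
            lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
            return min(max(rate, lo), hi)
        return rate

    hit = adjust(hit_rate_a, n_a)
    fa = adjust(1.0 - hit_rate_b, n_b)
    return float(stats.norm.ppf(hit) - stats.norm.ppf(fa))


def binomial_vs_chance(k_correct: int, n_scored: int, p_chance: float = 0.5) -> float:
    """Exact one-sided upper-tail binomial p-value P(X >= k | n, p_chance)."""
    if n_scored < 1:
        raise ValueError("n_scored must be >= 1")
    if not 0 <= k_correct <= n_scored:
        raise ValueError("need 0 <= k_correct <= n_scored")
    if not 0 < p_chance < 1:
        raise ValueError("p_chance must lie in (0, 1)")
    return float(stats.binom.sf(k_correct - 1, n_scored, p_chance))


def bonferroni_adjust(p_values: Sequence[float], family_size: Optional[int] = None) -> np.ndarray:
    """Bonferroni-adjusted p-values min(1, p * m); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    m = family_size if family_size is not None else p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * m)


def bonferroni_alpha(alpha: float = 0.05, family_size: int = 1) -> float:
    """Corrected per-comparison alpha = alpha / m."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return alpha / family_size


@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p_value: float


def kruskal_wallis_ranks(*rt_groups: Sequence[float]) -> KruskalResult:
    """Kruskal-Wallis H test by ranks over two or more reaction-time groups.

    Tie-corrected H with chi-square tail probability on (groups - 1) degrees
    of freedom. Identical-valued groups give H = 0, p = 1.
    """
    if len(rt_groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in rt_groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # all observations identical: no rank variation at all
        return KruskalResult(H=0.0, df=df, p_value=1.0)
    H, p = stats.kruskal(*groups)
    return KruskalResult(H=float(H), df=df, p_value=float(p))


def reaction_times_by_sound(logs: pd.DataFrame) -> dict[str, np.ndarray]:
    """Scored-trial reaction times grouped by sound, for rank tests."""
    scored = logs[logs["reaction_time_s"].notna()]
    return {
        str(sound): g["reaction_time_s"].to_numpy(dtype=float)
        for sound, g in scored.groupby("sound_id", sort=True)
    }


@dataclass(frozen=True)
class EngagementSummary:
    per_session: pd.DataFrame
    per_animal: pd.DataFrame
    median_normalized_timestamp: float  # across sessions with trials


def engagement_summary(
    logs: pd.DataFrame,
    session_durations: Mapping[tuple[str, str], float] | pd.DataFrame,
) -> EngagementSummary:
    """Trials/session distribution and within-session timing of engagement.

    ``session_durations`` maps (animal_id, session_id) to the scheduled
    session duration in seconds (or a DataFrame with columns animal_id,
    session_id, duration_s) and must cover every session, including those
    without a single trial — these are tallied per subject. Trial timestamps
    are normalized by the session duration; each session contributes the
    median of its normalized timestamps.
    """
    if isinstance(session_durations, pd.DataFrame):
        durations = {
            (str(r.animal_id), str(r.session_id)): float(r.duration_s)
            for r in session_durations.itertuples()
        }
    else:
        durations = {k: float(v) for k, v in session_durations.items()}
    if any(d <= 0 for d in durations.values()):
        raise ValueError("session durations must be positive")

    per_session_rows = []
    grouped = {k: g for k, g in logs.groupby(["animal_id", "session_id"], sort=False)} if not logs.empty else {}
    for (animal, session), duration in durations.items():
        g = grouped.get((animal, session))
        if g is None:
            per_session_rows.append(
                {"animal_id": animal, "session_id": session, "n_trials": 0,
                 "duration_s": duration, "median_normalized_timestamp": np.nan}
            )
            continue
        t = g["t_start_s"].to_numpy(dtype=float)
        if np.any(t < 0) or np.any(t > duration):
            raise ValueError(
                f"timestamps of session {session!r} fall outside [0, duration]"
            )
        per_session_rows.append(
            {"animal_id": animal, "session_id": session, "n_trials": len(g),
             "duration_s": duration,
             "median_normalized_timestamp": float(np.median(t / duration))}
        )
    per_session = pd.DataFrame(per_session_rows)

    per_animal_rows = []
    for animal, g in per_session.groupby("animal_id", sort=True):
        n = g["n_trials"]
        per_animal_rows.append(
            {
                "animal_id": animal,
                "n_sessions": len(g),
                "median_trials_per_session": float(n.median()),
                "iqr_trials_per_session": float(n.quantile(0.75) - n.quantile(0.25)),
                "n_zero_trial_sessions": int((n == 0).sum()),
            }
        )
    per_animal = pd.DataFrame(per_animal_rows)

    with_trials = per_session["median_normalized_timestamp"].dropna()
    overall = float(with_trials.median()) if len(with_trials) else np.nan
    return EngagementSummary(per_session, per_animal, overall)


def learning_curve_bins(logs: pd.DataFrame, bin_percent: int = 5) -> pd.DataFrame:
    """Hit rate versus percent-of-total-trials, per subject.

    Each subject's trials, in log order, are indexed 1..N and mapped to the
    shared percentage axis; bin b covers ((b-1), b] * bin_percent percent.
    Bin trial counts sum to N exactly. Hit rates are over scored trials in
    the bin (NaN where a bin holds only ignored trials).
    """
    if bin_percent < 1 or 100 % bin_percent != 0:
        raise ValueError("bin_percent must divide 100")
    if logs.empty:
        return pd.DataFrame(columns=["animal_id", "bin", "pct_hi", "n_trials", "n_scored", "n_correct", "hit_rate"])

    n_bins = 100 // bin_percent
    out = []
    for animal, g in logs.groupby("animal_id", sort=True):
        N = len(g)
        idx = np.arange(1, N + 1)
        bins = np.ceil(idx * n_bins / N).astype(int)  # 1..n_bins
        scored = ~g["choice"].isin(["ignored", "error"]).to_numpy()
        correct = (g["correct"] == True).to_numpy()  # noqa: E712 — NaN-safe
        for b in range(1, n_bins + 1):
            mask = bins == b
            n_sc = int((mask & scored).sum())
            n_co = int((mask & scored & correct).sum())
            out.append(
                {
                    "animal_id": animal,
                    "bin": b,
                    "pct_hi": b * bin_percent,
                    "n_trials": int(mask.sum()),
                    "n_scored": n_sc,
                    "n_correct": n_co,
                    "hit_rate": n_co / n_sc if n_sc else np.nan,
                }
            )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    p_value: float
    ci95: tuple[float, float]
    n: int
    df: int


def partial_pearson(
    x: Sequence[float], y: Sequence[float], covariate: Sequence[float]
) -> PartialCorrResult:
    """Partial Pearson correlation of x and y controlling for one covariate.

    Both variables are residualized on the covariate (with intercept) by
    least squares; the Pearson correlation of the residuals is tested on
    n - 3 degrees of freedom, with a Fisher-transform 95% CI using
    SE = 1/sqrt(n - 4).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, covariate must be 1-d arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations for a partial correlation")
    for name, v in (("x", x), ("y", y), ("covariate", z)):
        if np.isclose(np.var(v), 0):
            raise ValueError(f"{name} has zero variance")

    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])

    df = n - 3
    r_clamped = min(max(r, -0.999999999), 0.999999999)
    t = r_clamped * np.sqrt(df / (1 - r_clamped**2))
    p = float(2 * stats.t.sf(abs(t), df))
    zr = np.arctanh(r_clamped)
    half = 1.959963984540054 / np.sqrt(n - 4)
    ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    return PartialCorrResult(r=r, p_value=p, ci95=ci, n=n, df=df)


def detection_level_counts(logs: pd.DataFrame, present_visual: str = "face") -> LevelCounts:
    """Aggregate detection logs into per-level (n, k) presence-response counts.

    Silent trials enter at level 0 dB SPL. k counts scored trials on which
    the presence response was chosen; ignored trials are dropped.
    """
    scored = logs[~logs["choice"].isin(["ignored", "error"])].copy()
    level = scored["level_db"].fillna(0.0).astype(float)
    present = (scored["choice"] == present_visual).astype(int)
    agg = (
        pd.DataFrame({"level_db": level, "present": present})
        .groupby("level_db", sort=True)
        .agg(n=("present", "size"), k=("present", "sum"))
        .reset_index()
    )
    return LevelCounts(
        agg["level_db"].to_numpy(), agg["n"].to_numpy(), agg["k"].to_numpy()
    )
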