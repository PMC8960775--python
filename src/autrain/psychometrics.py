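"""Psychometric function, maximum-likelihood fitting, and bootstrap CIs.

The response probability at stimulus level ``x`` is modeled as

    psi(x; m, w, lambda, gamma) = gamma + (1 - lambda - gamma) * S(x; m, w)

with ``S`` a cumulative-normal sigmoid, ``m`` the threshold (level at which
S = 0.5), ``w`` the width, ``gamma`` the guess rate (lower asymptote) and
``lambda`` the lapse rate (1 - upper asymptote). The default width
convention takes ``w`` as the level difference between S = 0.5 and S = 0.95,
so S(x) = Phi(z95 * (x - m) / w) with z95 the 95% standard-normal quantile;
the common 0.05-0.95 convention is selectable.

Fitting maximizes the binomial log-likelihood of per-level (n, k) counts,
stabilized by a weak Beta(1, 10) prior on the lapse and guess rates, from a
deterministic multi-start grid. Confidence intervals come from the observed
information (Wald) at the optimum; :func:`bootstrap_ci` offers parametric
bootstrap percentile intervals instead.

Hearing-threshold estimation by the method of constant stimuli fits the
probability of the presence response versus level; the false-alarm floor at
0 dB SPL is absorbed by ``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PsychometricParams",
    "LevelCounts",
    "PsychometricFit",
    "BootstrapCI",
    "psi",
    "threshold_level",
    "expected_counts",
    "fit_psychometric",
    "bootstrap_ci",
    "ParameterError",
]

_Z95 = float(stats.norm.ppf(0.95))
_PARAM_NAMES = ("m", "w", "lam", "gamma")


class ParameterError(ValueError):
    """Raised for invalid psychometric parameter values."""


@dataclass(frozen=True)
class PsychometricParams:
    m: float
    w: float
    lam: float = 0.0
    gamma: float = 0.0
    core: str = "cumulative-normal"

    def __post_init__(self) -> None:
        if not np.isfinite(self.m):
            raise ParameterError("threshold m must be finite")
        if not (self.w > 0):
            raise ParameterError("width w must be positive")
        if not (0 <= self.lam < 0.5 and 0 <= self.gamma < 0.5):
            raise ParameterError("lapse and guess rates must lie in [0, 0.5)")
        if self.lam + self.gamma >= 1:
            raise ParameterError("lapse + guess must be < 1")
        if self.core != "cumulative-normal":
            raise ParameterError(f"unsupported core {self.core!r}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.m, self.w, self.lam, self.gamma)


@dataclass(frozen=True)
class LevelCounts:
    """Per-level response counts: (level in dB SPL, n trials, k target responses)."""

    levels: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        n = np.asarray(self.n, dtype=int)
        k = np.asarray(self.k, dtype=int)
        if not (levels.shape == n.shape == k.shape) or levels.ndim != 1:
            raise ValueError("levels, n, k must be 1-d arrays of equal length")
        if np.any(n < 0) or np.any(k < 0) or np.any(k > n):
            raise ValueError("counts must satisfy 0 <= k <= n")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)

    @classmethod
    def from_records(cls, rows: Sequence[tuple[float, int, int]]) -> "LevelCounts":
        arr = np.asarray(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1].astype(int), arr[:, 2].astype(int))


@dataclass(frozen=True)
class PsychometricFit:
    params: Optional[PsychometricParams]
    ci95: Optional[Mapping[str, tuple[float, float]]]
    converged: bool
    log_likelihood: float


@dataclass(frozen=True)
class BootstrapCI:
    intervals: Mapping[str, tuple[float, float]]
    n_boot: int
    n_failed: int
    reliable: bool


def _scale(width_convention: str) -> float:
    if width_convention == "0.5-0.95":
        return _Z95
    if width_convention == "0.05-0.95":
        return 2.0 * _Z95
    raise ParameterError(f"unknown width convention {width_convention!r}")


def psi(
    params: PsychometricParams,
    x: float | np.ndarray,
    width_convention: str = "0.5-0.95",
) -> float | np.ndarray:
    """Response probability at level(s) ``x``; strictly increasing, bounded in (gamma, 1 - lambda)."""
    c = _scale(width_convention)
    core = stats.norm.cdf(c * (np.asarray(x, dtype=float) - params.m) / params.w)
    out = params.gamma + (1.0 - params.lam - params.gamma) * core
    return float(out) if np.isscalar(x) else out


def threshold_level(params: PsychometricParams) -> float:
    """Level at which psi crosses its half-way point gamma + (1-lam-gamma)/2 — equals m."""
    return params.m


def expected_counts(
    params: PsychometricParams,
    levels: Sequence[float],
    n_per_level: int,
    width_convention: str = "0.5-0.95",
) -> LevelCounts:
    """Noise-free expected counts k = round(n * psi(level)); handy oracle input."""
    levels = np.asarray(levels, dtype=float)
    p = psi(params, levels, width_convention)
    n = np.full(levels.shape, int(n_per_level))
    return LevelCounts(levels, n, np.rint(n * p).astype(int))


def _neg_log_posterior(
    theta: np.ndarray,
    free_idx: np.ndarray,
    base: np.ndarray,
    data: LevelCounts,
    c: float,
) -> float:
    full = base.copy()
    full[free_idx] = theta
    m, w, lam, gamma = full
    if w <= 0 or lam + gamma >= 1:
        return np.inf
    p = gamma + (1.0 - lam - gamma) * stats.norm.cdf(c * (data.levels - m) / w)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = float(np.sum(data.k * np.log(p) + (data.n - data.k) * np.log1p(-p)))
    # Weak Beta(1, 10) prior on lapse and guess keeps the asymptotes identified
    # when few trials land near them.
    prior = 9.0 * (np.log1p(-min(lam, 0.4999)) + np.log1p(-min(gamma, 0.4999)))
    return -(ll + prior)


def _binomial_ll(params: PsychometricParams, data: LevelCounts, c: float) -> float:
    p = np.clip(
        params.gamma
        + (1 - params.lam - params.gamma) * stats.norm.cdf(c * (data.levels - params.m) / params.w),
        1e-12,
        1 - 1e-12,
    )
    return float(np.sum(data.k * np.log(p) + (data.n - data.k) * np.log1p(-p)))


def _default_bounds(data: LevelCounts) -> dict[str, tuple[float, float]]:
    lo, hi = float(data.levels.min()), float(data.levels.max())
    span = max(hi - lo, 1.0)
    return {
        "m": (lo - span, hi + span),
        "w": (span * 1e-3, span * 4.0),
        "lam": (0.0, 0.499),
        "gamma": (0.0, 0.499),
    }


def _start_grid(data: LevelCounts, bounds: dict[str, tuple[float, float]]) -> list[np.ndarray]:
    lo, hi = float(data.levels.min()), float(data.levels.max())
    span = max(hi - lo, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = data.k / np.maximum(data.n, 1)
    # crude threshold guess: level whose proportion is nearest the mid-point
    mid_guess = float(data.levels[np.argmin(np.abs(prop - 0.5))])
    starts = []
    for m0 in (mid_guess, lo + 0.25 * span, lo + 0.75 * span):
        for w0 in (0.5 * span, span):
            starts.append(np.array([m0, w0, 0.02, 0.02]))
    return starts


def fit_psychometric(
    data: LevelCounts,
    fixed: Optional[Mapping[str, float]] = None,
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
    seed: int = 0,
    width_convention: str = "0.5-0.95",
    n_random_starts: int = 2,
    compute_ci: bool = True,
    init: Optional[PsychometricParams] = None,
) -> PsychometricFit:
    """Maximum-likelihood fit of (m, w, lambda, gamma) to per-level counts.

    Runs L-BFGS-B from a deterministic grid of starting points plus
    ``n_random_starts`` seeded jittered starts and keeps the best optimum;
    an explicit ``init`` replaces the grid with that single starting point.
    Parameters named in ``fixed`` are held at the given values. Data whose
    responses are all identical (k = 0 or k = n everywhere) cannot constrain
    the curve: the fit is flagged non-converged and carries no estimate.
    Wald 95% intervals come from the inverse observed information.
    """
    if len(np.unique(data.levels)) < 3:
        raise ValueError("need at least 3 distinct stimulus levels to fit")
    if np.all(data.k == 0) or np.all(data.k == data.n):
        return PsychometricFit(params=None, ci95=None, converged=False, log_likelihood=np.nan)

    fixed = dict(fixed or {})
    c = _scale(width_convention)
    bnds = _default_bounds(data)
    if bounds:
        bnds.update({k: tuple(v) for k, v in bounds.items()})

    free_names = [p for p in _PARAM_NAMES if p not in fixed]
    free_idx = np.array([_PARAM_NAMES.index(p) for p in free_names], dtype=int)
    base = np.array([fixed.get(p, np.nan) for p in _PARAM_NAMES], dtype=float)

    starts = [np.array(init.as_tuple())] if init is not None else _start_grid(data, bnds)
    rng = np.random.default_rng(seed)
    lo_hi = np.array([bnds[p] for p in _PARAM_NAMES])
    for _ in range(n_random_starts):
        jitter = rng.uniform(lo_hi[:, 0], np.minimum(lo_hi[:, 1], lo_hi[:, 0] + 2 * (lo_hi[:, 1] - lo_hi[:, 0]) * 0.5))
        starts.append(jitter)

    opt_bounds = [bnds[p] for p in free_names]
    best = None
    for s0 in starts:
        x0 = np.clip(s0[free_idx], [b[0] for b in opt_bounds], [b[1] for b in opt_bounds])
        res = optimize.minimize(
            _neg_log_posterior,
            x0,
            args=(free_idx, base, data, c),
            method="L-BFGS-B",
            bounds=opt_bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return PsychometricFit(params=None, ci95=None, converged=False, log_likelihood=np.nan)

    full = base.copy()
    full[free_idx] = best.x
    # keep the estimate strictly inside the open parameter space
    eps = 1e-9
    full[1] = max(full[1], eps)
    full[2] = min(max(full[2], 0.0), 0.5 - eps)
    full[3] = min(max(full[3], 0.0), 0.5 - eps)
    params = PsychometricParams(m=full[0], w=full[1], lam=full[2], gamma=full[3])

    if compute_ci:
        ci95 = _wald_ci(best.x, free_names, params, free_idx, base, data, c)
        for name, val in fixed.items():
            ci95[name] = (float(val), float(val))
    else:
        ci95 = None
    return PsychometricFit(
        params=params,
        ci95=ci95,
        converged=bool(best.success or np.isfinite(best.fun)),
        log_likelihood=_binomial_ll(params, data, c),
    )


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2 * f0 + f(x - ei)) / (h[i] ** 2)
            else:
                val = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def _wald_ci(
    x_opt: np.ndarray,
    free_names: list[str],
    params: PsychometricParams,
    free_idx: np.ndarray,
    base: np.ndarray,
    data: LevelCounts,
    c: float,
) -> dict[str, tuple[float, float]]:
    """Wald intervals from the observed information (finite-difference Hessian)."""
    est = {n: getattr(params, n) for n in _PARAM_NAMES}
    se = None
    try:
        hess = _numerical_hessian(
            lambda t: _neg_log_posterior(t, free_idx, base, data, c), np.asarray(x_opt, float)
        )
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.all(np.isfinite(diag)) and np.all(diag > 0):
            se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        se = None
    ci: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(free_names):
        if se is None or not np.isfinite(se[i]):
            ci[name] = (-np.inf, np.inf)
        else:
            half = 1.959963984540054 * float(se[i])
            ci[name] = (est[name] - half, est[name] + half)
    return ci


def bootstrap_ci(
    data: LevelCounts,
    fit: PsychometricFit,
    n_boot: int = 500,
    seed: int = 0,
    width_convention: str = "0.5-0.95",
    max_fail_frac: float = 0.2,
) -> BootstrapCI:
    """Parametric-bootstrap percentile 95% intervals for the fitted parameters.

    Counts are resampled per level from the fitted curve and refit; intervals
    are the 2.5-97.5 percentiles of the refitted parameters. Reproducible for
    a fixed seed. If more than ``max_fail_frac`` of the refits fail, the
    intervals are flagged unreliable.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not fit.converged or fit.params is None:
        raise ValueError("bootstrap requires a converged fit")

    rng = np.random.default_rng(seed)
    p_hat = np.asarray(psi(fit.params, data.levels, width_convention))
    draws: dict[str, list[float]] = {n: [] for n in _PARAM_NAMES}
    n_failed = 0
    for _ in range(n_boot):
        k_star = rng.binomial(data.n, p_hat)
        boot = LevelCounts(data.levels, data.n, k_star)
        try:
            refit = fit_psychometric(
                boot,
                seed=int(rng.integers(2**31 - 1)),
                width_convention=width_convention,
                n_random_starts=0,
                compute_ci=False,
                init=fit.params,
            )
        except ValueError:
            refit = PsychometricFit(None, None, False, np.nan)
        if not refit.converged or refit.params is None:
            n_failed += 1
            continue
        for name in _PARAM_NAMES:
            draws[name].append(getattr(refit.params, name))

    intervals = {}
    for name, vals in draws.items():
        if vals:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            intervals[name] = (float(lo), float(hi))
        else:
            intervals[name] = (np.nan, np.nan)
    return BootstrapCI(
        intervals=intervals,
        n_boot=n_boot,
        n_failed=n_failed,
        reliable=n_failed <= max_fail_frac * n_boot,
    )
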