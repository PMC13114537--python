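"""Exponentiated Rayleigh primitives and the cumulative-exposure step-stress law.

The exponentiated Rayleigh (ER, two-parameter Burr type X) distribution has

    F(t; alpha, beta) = (1 - exp(-beta t^2))^alpha,        t > 0,

with shape ``alpha > 0`` (dimensionless) and scale ``beta > 0`` (1/time^2).
The density is decreasing for ``alpha <= 1/2`` and unimodal for
``alpha > 1/2``; the hazard has an inverted-bathtub shape for ``alpha < 1/2``
and is increasing for ``alpha >= 1/2``.

A step-stress experiment raises the stress at fixed change times
``tau_1 < ... < tau_m``, giving ``m + 1`` stress levels.  Each level carries
its own scale ``beta_k`` (common shape ``alpha``), and the cumulative
exposure model (CEM) glues the per-level CDFs into one continuous lifetime
distribution: on level ``k`` the composed CDF is
``F_k(c_{k-1} + t - tau_{k-1})`` where the offsets ``c_k`` translate the
exposure accumulated at earlier levels into equivalent time at the current
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "ERParams",
    "StressSchedule",
    "CEMParams",
    "CEMOffsets",
    "er_cdf",
    "er_pdf",
    "er_logpdf",
    "er_hazard",
    "er_quantile",
    "er_mean",
    "cem_offsets",
    "cem_cdf",
    "cem_pdf",
    "cem_logpdf",
    "cem_sample",
]

_LN2 = np.log(2.0)


def log1mexp(x):
    """log(1 - exp(-x)) for x > 0, numerically stable on both tails.

    Uses log(-expm1(-x)) for x < ln 2 and log1p(-exp(-x)) otherwise.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        small = np.log(-np.expm1(-np.minimum(x, _LN2)))
        large = np.log1p(-np.exp(-np.maximum(x, _LN2)))
    return np.where(x < _LN2, small, large)


@dataclass(frozen=True)
class ERParams:
    """Shape/scale pair of a single-level exponentiated Rayleigh law."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"ER parameters must be positive, got alpha={self.alpha}, beta={self.beta}"
            )


@dataclass(frozen=True)
class StressSchedule:
    """Stress change times tau_1 < ... < tau_m (tau_0 = 0 implied).

    ``m`` change times define ``m + 1`` stress levels; an empty schedule is a
    single-level (constant-stress) experiment.
    """

    change_times: tuple

    def __init__(self, change_times=()):
        taus = tuple(float(t) for t in np.atleast_1d(np.asarray(change_times, dtype=float)))
        if len(taus) and taus[0] <= 0:
            raise ValueError("change times must be strictly positive")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("change times must be strictly increasing")
        object.__setattr__(self, "change_times", taus)

    @property
    def m(self) -> int:
        return len(self.change_times)

    @property
    def n_levels(self) -> int:
        return self.m + 1

    @property
    def taus(self) -> np.ndarray:
        """Change times prepended with tau_0 = 0 (length m + 1)."""
        return np.concatenate([[0.0], self.change_times])

    def level_of(self, t, *, right_limit: bool = False) -> np.ndarray:
        """0-based stress-level index of time(s) t.

        Levels are the half-open intervals (tau_{k-1}, tau_k]; a time equal to
        a change point belongs to the earlier level unless ``right_limit``.
        """
        side = "right" if right_limit else "left"
        return np.searchsorted(np.asarray(self.change_times), np.asarray(t, dtype=float), side=side)


@dataclass(frozen=True)
class CEMParams:
    """Common shape ``alpha`` plus one scale per stress level."""

    alpha: float
    betas: tuple

    def __init__(self, alpha, betas):
        betas = tuple(float(b) for b in np.atleast_1d(np.asarray(betas, dtype=float)))
        if not alpha > 0:
            raise ValueError(f"alpha must be positive, got {alpha}")
        if not all(b > 0 for b in betas):
            raise ValueError("all scale parameters must be positive")
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(self, "betas", betas)

    @property
    def n_levels(self) -> int:
        return len(self.betas)

    @property
    def is_ordered(self) -> bool:
        """Whether beta_1 <= ... <= beta_{m+1} (higher stress, shorter life)."""
        return all(a <= b * (1 + 1e-12) for a, b in zip(self.betas, self.betas[1:]))

    def level_params(self, k: int) -> ERParams:
        return ERParams(self.alpha, self.betas[k])

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "betas": list(self.betas)}

    @classmethod
    def from_dict(cls, d: dict) -> "CEMParams":
        return cls(d["alpha"], d["betas"])


@dataclass(frozen=True)
class CEMOffsets:
    """Exposure-translation offsets c_0 = 0, c_1, ..., c_m (one per level)."""

    c: tuple = field(default=(0.0,))

    def __post_init__(self):
        if self.c[0] != 0.0:
            raise ValueError("c_0 must be 0")
        if any(ck < 0 for ck in self.c):
            raise ValueError("offsets must be nonnegative")


def _check_nonneg(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times are outside the support")
    return t


def er_cdf(t, p: ERParams):
    """CDF (1 - e^{-beta t^2})^alpha of the ER law."""
    t = _check_nonneg(t)
    x = p.beta * t**2
    with np.errstate(divide="ignore"):
        out = np.exp(p.alpha * log1mexp(x))
    return np.where(x == 0.0, 0.0, out)[()]


def er_logpdf(t, p: ERParams):
    t = _check_nonneg(t)
    x = p.beta * t**2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(2 * p.alpha * p.beta) + np.log(t) - x + (p.alpha - 1.0) * log1mexp(x)
    return out[()]


def er_pdf(t, p: ERParams):
    """Density 2 alpha beta t e^{-beta t^2} (1 - e^{-beta t^2})^{alpha-1}.

    At t = 0 the limiting value is returned: 0 for alpha > 1/2, sqrt(beta)
    for alpha = 1/2, and +inf for alpha < 1/2.
    """
    t = _check_nonneg(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.exp(er_logpdf(t, p))
    if p.alpha > 0.5:
        origin = 0.0
    elif p.alpha == 0.5:
        origin = np.sqrt(p.beta)
    else:
        origin = np.inf
    return np.where(t == 0.0, origin, out)[()]


def er_hazard(t, p: ERParams):
    """Hazard pdf / (1 - cdf)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("the hazard is defined for t > 0")
    x = p.beta * t**2
    log_sf = np.log(-np.expm1(p.alpha * log1mexp(x)))
    return np.exp(er_logpdf(t, p) - log_sf)[()]


def er_quantile(u, p: ERParams):
    """Inverse CDF: t = sqrt(-ln(1 - u^{1/alpha}) / beta), 0 <= u < 1."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        # 1 - u^{1/alpha} via expm1 for accuracy near u = 1
        inner = -np.log(-np.expm1(np.log(u) / p.alpha))
    t = np.sqrt(inner / p.beta)
    return np.where(u == 0.0, 0.0, t)[()]


def er_mean(p: ERParams) -> float:
    """Expected lifetime via the survival integral int_0^inf (1 - F) dt."""

    def sf(t):
        return -np.expm1(p.alpha * log1mexp(p.beta * t**2))

    val, _ = integrate.quad(sf, 0.0, np.inf)
    return val


def cem_offsets(sched: StressSchedule, betas) -> CEMOffsets:
    """Exposure-translation offsets c_{k-1} = sum_{j<k} sqrt(beta_j/beta_k) (tau_j - tau_{j-1}).

    The offsets are the unique solution of the CEM continuity recursion
    ``F_k(c_{k-1}) = F_{k-1}(c_{k-2} + tau_{k-1} - tau_{k-2})``: for the ER
    law the CDF argument is ``beta t^2``, so matching exposure across a
    stress change equates ``beta_k c_{k-1}^2`` with the accumulated
    ``beta_{k-1} (.)^2``, giving square-root scale ratios (the linear ratios
    familiar from exponential-type step-stress models would leave the
    composed CDF discontinuous here).
    """
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    if len(betas) != sched.n_levels:
        raise ValueError(
            f"need {sched.n_levels} scale parameters for {sched.m} change times, got {len(betas)}"
        )
    dtau = np.diff(sched.taus)  # tau_k - tau_{k-1}, length m
    c = np.zeros(sched.n_levels)
    if sched.m:
        c[1:] = np.cumsum(np.sqrt(betas[:-1]) * dtau) / np.sqrt(betas[1:])
    return CEMOffsets(tuple(c))


def _effective_times(t, params: CEMParams, sched: StressSchedule, *, right_limit=False):
    """Per-time (level index, shifted argument c_{k-1} + t - tau_{k-1})."""
    t = np.asarray(t, dtype=float)
    levels = sched.level_of(t, right_limit=right_limit)
    c = np.asarray(cem_offsets(sched, params.betas).c)
    taus = sched.taus
    s = c[levels] + t - taus[levels]
    return levels, s


def cem_cdf(t, params: CEMParams, sched: StressSchedule):
    """Composed step-stress CDF F_k(c_{k-1} + t - tau_{k-1}) on (tau_{k-1}, tau_k]."""
    t = _check_nonneg(t)
    levels, s = _effective_times(t, params, sched)
    betas = np.asarray(params.betas)
    x = betas[levels] * s**2
    with np.errstate(divide="ignore"):
        out = np.exp(params.alpha * log1mexp(x))
    return np.where(x == 0.0, 0.0, out)[()]


def cem_logpdf(t, params: CEMParams, sched: StressSchedule):
    """Log density of the composed law; change points use the right branch."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("the density is defined for t > 0")
    levels, s = _effective_times(t, params, sched, right_limit=True)
    betas = np.asarray(params.betas)
    x = betas[levels] * s**2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            np.log(2 * params.alpha * betas[levels])
            + np.log(s)
            - x
            + (params.alpha - 1.0) * log1mexp(x)
        )
    return out[()]


def cem_pdf(t, params: CEMParams, sched: StressSchedule):
    return np.exp(cem_logpdf(t, params, sched))[()]


def cem_sample(n: int, params: CEMParams, sched: StressSchedule, rng):
    """Inverse-transform sample of n failure times from the composed law.

    Draws u ~ U(0,1), locates the stress level by comparing u with the CDF
    values p_k at the change points, and inverts the matching ER branch:
    t = tau_{k-1} + sqrt(-ln(1 - u^{1/alpha}) / beta_k) - c_{k-1}.  Draws of
    exactly 0 or 1 (probability-zero events) are redrawn.

    Parameters
    ----------
    rng : int or numpy.random.Generator
        Seed or generator; threaded explicitly for reproducibility.

    Returns
    -------
    times : ndarray
        Sorted failure times.
    counts : ndarray
        Failures per stress level (length m + 1).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if params.n_levels != sched.n_levels:
        raise ValueError("parameter/schedule level counts differ")
    rng = np.random.default_rng(rng)
    u = rng.uniform(size=n)
    bad = (u <= 0.0) | (u >= 1.0)
    while np.any(bad):  # pragma: no cover - probability ~0 redraw
        u[bad] = rng.uniform(size=bad.sum())
        bad = (u <= 0.0) | (u >= 1.0)

    betas = np.asarray(params.betas)
    taus = sched.taus
    c = np.asarray(cem_offsets(sched, betas).c)
    # p_k = F(tau_k) at each change point, the level boundaries in u-space
    p = np.exp(params.alpha * log1mexp(betas[:-1] * (c[:-1] + np.diff(taus)) ** 2)) if sched.m else np.array([])
    levels = np.searchsorted(p, u, side="left")
    inner = -np.log(-np.expm1(np.log(u) / params.alpha))
    times = taus[levels] + np.sqrt(inner / betas[levels]) - c[levels]
    counts = np.bincount(levels, minlength=sched.n_levels)
    return np.sort(times), counts
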