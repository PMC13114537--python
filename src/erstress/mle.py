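"""Order-restricted maximum likelihood and asymptotic confidence intervals.

The fitting algorithm works in the ratio parameterization: an unrestricted
pass maximizes the log-likelihood over (alpha, lambda_1..lambda_m,
beta_{m+1}) with no upper bound on the lambdas; any ratio landing above 1 is
then bound to the boundary (beta_k = beta_{k+1}) and the remaining free
parameters are re-maximized, iterating until every ratio satisfies
lambda_k <= 1.  Positivity is imposed by optimizing on the log scale.

Confidence intervals come from the observed Fisher information (negative
Hessian of the log-likelihood at the optimum, by Richardson-extrapolated
central differences, ridge-regularized if near-singular): Wald intervals on
the ratio coordinates, and delta-method intervals for the original scales
beta_k = (prod_{j>=k} lambda_j) beta_{m+1}.  Negative lower limits are
truncated to zero, as every parameter is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._numdiff import gradient, hessian
from .dataset import StepStressData
from .likelihood import ReparamPoint, from_reparam, loglik_reparam
from .distributions import CEMParams, cem_offsets

__all__ = [
    "FitResult",
    "IntervalSet",
    "fit_unrestricted_reparam",
    "fit_order_restricted",
    "observed_information",
    "delta_method_ci",
]

#: lambda* counts as a boundary violation when it exceeds 1 by more than this
BINDING_TOL = 1e-8
MAX_OUTER_ITER = 100


@dataclass
class FitResult:
    """Order-restricted fit: estimates, boundary bookkeeping, covariance."""

    reparam: ReparamPoint
    params: CEMParams
    loglik: float
    boundary_flags: np.ndarray  # per-lambda: True where bound at 1
    iterations: int
    converged: bool
    info: np.ndarray | None = field(default=None, repr=False)  # observed information
    cov: np.ndarray | None = field(default=None, repr=False)   # its (regularized) inverse


@dataclass(frozen=True)
class IntervalSet:
    """Per-parameter Wald intervals at a common confidence level."""

    level: float
    alpha: tuple
    betas: tuple          # (lower, upper) per beta_k
    lambdas: tuple = ()   # intervals for the ratio coordinates

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "alpha": list(self.alpha),
            "betas": [list(b) for b in self.betas],
            "lambdas": [list(l) for l in self.lambdas],
        }


def _unpack(x, m, free_mask, bound_value=1.0):
    full = np.empty(m + 2)
    full[~free_mask] = bound_value
    full[free_mask] = np.exp(x)
    return ReparamPoint(full[0], full[1:-1], full[-1])


def _initial_points(data: StepStressData, n_restarts: int = 4, seed: int = 0):
    """Deterministic starting points: a moment-style base plus jitters.

    Base: alpha = 1, every ratio 0.5, and beta_{m+1} from the last-level
    squared effective exposures (pooled 1/mean(t^2) when that level is
    empty).  Jitters perturb the log coordinates with fixed seeds to guard
    against flat or multimodal likelihoods.
    """
    m = data.schedule.m
    lam0 = np.full(m, 0.5)
    betas0 = np.concatenate([np.cumprod(lam0[::-1])[::-1], [1.0]])
    c = np.asarray(cem_offsets(data.schedule, betas0).c)
    last = data.levels == m
    if data.counts[-1] > 0:
        s_last = c[-1] + data.times[last] - data.schedule.taus[-1]
        b_last0 = data.counts[-1] / np.sum(s_last**2)
    else:
        b_last0 = 1.0 / np.mean(data.times**2)
    base = np.log(np.concatenate([[1.0], lam0, [b_last0]]))
    points = [base]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        points.append(base + rng.normal(scale=[1.5] + [0.7] * m + [1.0]))
    return points


def _maximize(data: StepStressData, free_mask: np.ndarray, starts) -> ReparamPoint:
    m = data.schedule.m

    def nll(x):
        v = loglik_reparam(_unpack(x, m, free_mask), data)
        return -v if np.isfinite(v) else 1e12

    best = None
    diagnostics = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # -inf excursions during line search
        for x0 in starts:
            res = optimize.minimize(
                nll, np.asarray(x0)[free_mask], method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
            )
            diagnostics.append(res.message)
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
    if best is None:
        raise RuntimeError(f"optimizer failed at every start: {diagnostics}")
    return _unpack(best.x, m, free_mask)


def fit_unrestricted_reparam(data: StepStressData, init=None, n_restarts: int = 4) -> ReparamPoint:
    """First-pass MLE of (alpha, lambda, beta_{m+1}) with lambdas unbounded above."""
    m = data.schedule.m
    free = np.ones(m + 2, dtype=bool)
    starts = [np.log(np.asarray(init, dtype=float))] if init is not None else _initial_points(
        data, n_restarts
    )
    return _maximize(data, free, starts)


def fit_order_restricted(
    data: StepStressData,
    n_restarts: int = 4,
    compute_cov: bool = True,
) -> FitResult:
    """Order-restricted MLE by iterated boundary binding.

    Repeats: maximize over the free coordinates; accept if every free ratio
    is <= 1; otherwise freeze all violators at exactly 1 and re-maximize.
    Bound ratios encode beta_k = beta_{k+1}; the returned scale estimates
    always satisfy beta_1 <= ... <= beta_{m+1}.
    """
    m = data.schedule.m
    free = np.ones(m + 2, dtype=bool)
    starts = _initial_points(data, n_restarts)
    rp = None
    converged = False
    iterations = 0
    for iterations in range(1, MAX_OUTER_ITER + 1):
        rp = _maximize(data, free, starts)
        lam = np.asarray(rp.lambdas)
        violators = (lam > 1.0 + BINDING_TOL) & free[1 : m + 1]
        if not violators.any():
            converged = True
            break
        free[1 : m + 1] &= ~violators
        # restart the reduced problem from the current iterate (clipped) + jitters
        clipped = np.concatenate([[rp.alpha], np.minimum(lam, 1.0), [rp.beta_last]])
        starts = [np.log(clipped)]
        rng = np.random.default_rng(iterations)
        starts += [starts[0] + rng.normal(scale=0.3, size=m + 2) for _ in range(n_restarts)]
    if not converged:
        warnings.warn("boundary-binding loop hit the iteration cap", stacklevel=2)
    lam = np.minimum(np.asarray(rp.lambdas), 1.0)  # clear sub-tolerance overshoot
    rp = ReparamPoint(rp.alpha, lam, rp.beta_last)
    result = FitResult(
        reparam=rp,
        params=from_reparam(rp),
        loglik=loglik_reparam(rp, data),
        boundary_flags=~free[1 : m + 1],
        iterations=iterations,
        converged=converged,
    )
    if compute_cov:
        result.info, result.cov = observed_information(rp, data)
    return result


def observed_information(rp_hat: ReparamPoint, data: StepStressData,
                         eig_tol: float = 1e-10, ridge: float = 1e-6):
    """Observed Fisher information at the fit and its regularized inverse.

    The information is the negative Hessian of the log-likelihood in the
    (alpha, lambda_1..lambda_m, beta_{m+1}) coordinates.  Near the boundary
    the matrix can be close to singular; if any eigenvalue falls below
    ``eig_tol`` a ridge ``ridge * I`` is added before inversion.
    """
    phi = rp_hat.to_vector()

    def f(v):
        return loglik_reparam(ReparamPoint.from_vector(v), data)

    info = -hessian(f, phi)
    eigvals = np.linalg.eigvalsh(info)
    regularized = info
    if np.min(eigvals) < eig_tol:
        regularized = info + ridge * np.eye(len(phi))
    cov = np.linalg.inv(regularized)
    return info, cov


def score_norm(rp: ReparamPoint, data: StepStressData) -> float:
    """Euclidean norm of the log-likelihood gradient (stationarity check)."""
    phi = rp.to_vector()

    def f(v):
        return loglik_reparam(ReparamPoint.from_vector(v), data)

    return float(np.linalg.norm(gradient(f, phi)))


def delta_method_ci(fit: FitResult, level: float = 0.95) -> IntervalSet:
    """Wald intervals for alpha, the ratios, and the original scales.

    The scales are beta_k = g_k(lambda, beta_{m+1}) = (prod_{j>=k} lambda_j)
    beta_{m+1}, so Var(beta_k) ~= (grad g_k)' V (grad g_k) with
    d g_k / d lambda_j = g_k / lambda_j for j >= k (0 below) and
    d g_k / d beta_{m+1} = prod_{j>=k} lambda_j.  Lower limits are truncated
    at zero for every parameter.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if fit.cov is None:
        raise ValueError("fit carries no covariance; refit with compute_cov=True")
    z = stats.norm.ppf(0.5 + level / 2.0)
    V = fit.cov
    rp = fit.reparam
    m = rp.m
    lam = np.asarray(rp.lambdas)
    betas = np.asarray(fit.params.betas)

    def interval(center, var):
        half = z * np.sqrt(max(var, 0.0))
        return (max(0.0, center - half), center + half)

    alpha_iv = interval(rp.alpha, V[0, 0])
    lam_ivs = tuple(interval(lam[k], V[k + 1, k + 1]) for k in range(m))
    beta_ivs = []
    for k in range(m + 1):
        grad = np.zeros(m + 2)
        for j in range(k, m):
            grad[j + 1] = betas[k] / lam[j]
        grad[m + 1] = np.prod(lam[k:]) if k < m else 1.0
        var = float(grad @ V @ grad)
        beta_ivs.append(interval(betas[k], var))
    return IntervalSet(level=level, alpha=alpha_iv, betas=tuple(beta_ivs), lambdas=lam_ivs)
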