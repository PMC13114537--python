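"""Log-likelihood of complete step-stress data in both parameterizations.

The order restriction beta_1 <= ... <= beta_{m+1} is awkward to impose
directly, so the model is reparameterized through the scale ratios

    lambda_k = beta_k / beta_{k+1} in (0, 1],        k = 1, ..., m,

leaving (alpha, lambda_1, ..., lambda_m, beta_{m+1}) with simple box
constraints.  ``lambda_k = 1`` encodes the boundary case beta_k = beta_{k+1}.
Both log-likelihood forms below are the same function of the data — no
Jacobian is involved, the map is a bijection of parameter space — and both
equal the sum of composed-density logs, which the test suite uses as an
independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import StepStressData
from .distributions import CEMParams, cem_offsets, log1mexp

__all__ = ["ReparamPoint", "to_reparam", "from_reparam", "loglik_original", "loglik_reparam"]


@dataclass(frozen=True)
class ReparamPoint:
    """(alpha, lambda_1..lambda_m, beta_{m+1}) coordinates."""

    alpha: float
    lambdas: tuple
    beta_last: float

    def __init__(self, alpha, lambdas, beta_last):
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(
            self, "lambdas", tuple(float(v) for v in np.atleast_1d(np.asarray(lambdas, dtype=float)))
        )
        object.__setattr__(self, "beta_last", float(beta_last))

    @property
    def m(self) -> int:
        return len(self.lambdas)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.alpha], self.lambdas, [self.beta_last]])

    @classmethod
    def from_vector(cls, phi) -> "ReparamPoint":
        phi = np.asarray(phi, dtype=float)
        return cls(phi[0], phi[1:-1], phi[-1])


def _suffix_products(lambdas: np.ndarray) -> np.ndarray:
    """r_k = prod_{j=k}^{m} lambda_j for k = 1..m, plus r_{m+1} = 1."""
    return np.concatenate([np.cumprod(lambdas[::-1])[::-1], [1.0]])


def to_reparam(params: CEMParams) -> ReparamPoint:
    betas = np.asarray(params.betas)
    if not params.is_ordered:
        raise ValueError("scale parameters must be nondecreasing to reparameterize")
    lambdas = betas[:-1] / betas[1:]
    return ReparamPoint(params.alpha, lambdas, betas[-1])


def from_reparam(rp: ReparamPoint) -> CEMParams:
    lambdas = np.asarray(rp.lambdas)
    betas = _suffix_products(lambdas) * rp.beta_last
    return CEMParams(rp.alpha, betas)


def _effective(data: StepStressData, c: np.ndarray):
    """Shifted arguments s_i = c_{k-1} + t_i - tau_{k-1} for every time."""
    taus = data.schedule.taus
    return c[data.levels] + data.times - taus[data.levels]


def loglik_original(params: CEMParams, data: StepStressData) -> float:
    """Log-likelihood in (alpha, beta_1, ..., beta_{m+1}) coordinates.

    n ln(2 alpha) + sum_k n_k ln beta_k + sum_i ln s_i - sum_i beta_k s_i^2
    + (alpha - 1) sum_i ln(1 - e^{-beta_k s_i^2}), with s_i the
    exposure-shifted time of observation i at its level k.
    """
    betas = np.asarray(params.betas, dtype=float)
    if params.n_levels != data.schedule.n_levels:
        raise ValueError("parameter/schedule level counts differ")
    c = np.asarray(cem_offsets(data.schedule, betas).c)
    s = _effective(data, c)
    x = betas[data.levels] * s**2
    return float(
        data.n * np.log(2 * params.alpha)
        + np.dot(data.counts, np.log(betas))
        + np.sum(np.log(s))
        - np.sum(x)
        + (params.alpha - 1.0) * np.sum(log1mexp(x))
    )


def loglik_reparam(rp: ReparamPoint, data: StepStressData) -> float:
    """Log-likelihood in (alpha, lambda_1..lambda_m, beta_{m+1}) coordinates.

    n ln(2 alpha) + sum_k nbar_k ln lambda_k + n ln beta_{m+1} + sum_i ln s_i
    - beta_{m+1} sum_k r_k sum_{i in k} s_i^2
    + (alpha - 1) sum_i ln(1 - e^{-r_k beta_{m+1} s_i^2}),
    where r_k = lambda_k ... lambda_m and the offsets c_{k-1} are built from
    the ratio products r_j / r_k.  lambda_k > 1 is admitted (the unrestricted
    first pass of the fitting algorithm lives above the boundary).
    """
    lam = np.asarray(rp.lambdas, dtype=float)
    if rp.m != data.schedule.m:
        raise ValueError("parameter/schedule level counts differ")
    if rp.alpha <= 0 or rp.beta_last <= 0 or np.any(lam <= 0):
        warnings.warn("nonpositive parameter in log-likelihood; returning -inf", stacklevel=2)
        return -np.inf
    r = _suffix_products(lam)  # length m + 1, r[-1] = 1
    dtau = np.diff(data.schedule.taus)
    # continuity offsets in ratio coordinates: sqrt(beta_j/beta_k) = sqrt(r_j/r_k)
    sq = np.sqrt(r)
    c = np.zeros(len(r))
    if len(dtau):
        c[1:] = np.cumsum(sq[:-1] * dtau) / sq[1:]
    s = _effective(data, c)
    x = r[data.levels] * rp.beta_last * s**2
    nbar = data.cum_counts[:-1]  # nbar_1 .. nbar_m
    return float(
        data.n * np.log(2 * rp.alpha)
        + (np.dot(nbar, np.log(lam)) if rp.m else 0.0)
        + data.n * np.log(rp.beta_last)
        + np.sum(np.log(s))
        - np.sum(x)
        + (rp.alpha - 1.0) * np.sum(log1mexp(x))
    )
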