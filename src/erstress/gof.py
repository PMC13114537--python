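"""Goodness-of-fit statistics and information criteria for fitted models.

Both tests compare the empirical CDF of the ordered failure times with the
fitted composed step-stress CDF, treating the fitted parameters as known:
the Kolmogorov-Smirnov distance uses the exact finite-sample null
distribution (appropriate at the small n these experiments produce), the
Cramer-von Mises statistic the asymptotic one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .dataset import StepStressData
from .distributions import CEMParams, StressSchedule, cem_cdf

__all__ = ["GofReport", "ks_statistic", "cvm_statistic", "information_criteria", "gof_report"]


@dataclass(frozen=True)
class GofReport:
    ks_stat: float
    ks_pvalue: float
    cvm_stat: float
    cvm_pvalue: float
    loglik: float
    n_params: int
    aic: float
    bic: float
    hqic: float
    caic: float

    def as_dict(self) -> dict:
        return asdict(self)


def _fitted_cdf_values(data: StepStressData, params: CEMParams) -> np.ndarray:
    return np.asarray(cem_cdf(data.times, params, data.schedule))


def ks_statistic(data: StepStressData, params: CEMParams,
                 sched: StressSchedule | None = None):
    """Kolmogorov-Smirnov distance and exact parameters-known p-value.

    D = max_i max(|i/n - F(t_{i:n})|, |F(t_{i:n}) - (i-1)/n|).
    """
    del sched  # carried by the dataset
    F = _fitted_cdf_values(data, params)
    n = data.n
    i = np.arange(1, n + 1)
    d = float(np.max(np.maximum(np.abs(i / n - F), np.abs(F - (i - 1) / n))))
    return d, float(stats.kstwo.sf(d, n))


def cvm_statistic(data: StepStressData, params: CEMParams,
                  sched: StressSchedule | None = None):
    """Cramer-von Mises statistic W^2 and asymptotic parameters-known p-value.

    W^2 = 1/(12n) + sum_i (F(t_{i:n}) - (2i-1)/(2n))^2.
    """
    del sched
    res = stats.cramervonmises(data.times, lambda t: cem_cdf(t, params, data.schedule))
    return float(res.statistic), float(res.pvalue)


def information_criteria(loglik: float, n_params: int, n: int) -> dict:
    """AIC, BIC, HQIC and CAIC from a log-likelihood at the optimum.

    AIC = -2l + 2p; BIC = -2l + p ln n; HQIC = -2l + 2p ln ln n;
    CAIC = -2l + p (ln n + 1).
    """
    if n < 3:
        raise ValueError("information criteria need n >= 3 (HQIC requires ln ln n > 0)")
    neg2 = -2.0 * loglik
    p = n_params
    return {
        "aic": neg2 + 2 * p,
        "bic": neg2 + p * np.log(n),
        "hqic": neg2 + 2 * p * np.log(np.log(n)),
        "caic": neg2 + p * (np.log(n) + 1.0),
    }


def gof_report(data: StepStressData, params: CEMParams, loglik: float,
               n_bound: int = 0) -> GofReport:
    """Full report for a fitted parameter set.

    ``n_bound`` counts active boundary constraints (beta_k = beta_{k+1});
    each reduces the free parameter count below the nominal m + 2.
    """
    ks, ks_p = ks_statistic(data, params)
    cvm, cvm_p = cvm_statistic(data, params)
    p = data.schedule.m + 2 - n_bound
    ic = information_criteria(loglik, p, data.n)
    return GofReport(
        ks_stat=ks, ks_pvalue=ks_p, cvm_stat=cvm, cvm_pvalue=cvm_p,
        loglik=loglik, n_params=p, **ic,
    )
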