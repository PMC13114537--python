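"""Monte-Carlo study harness: repeated generation, fitting, and summaries.

Each replicate draws a complete step-stress sample from the composed ER law
by inverse transform, fits it with the requested method (order-restricted
MLE with asymptotic intervals, or importance-sampling Bayes with credible
intervals), and records point estimates, interval endpoints and boundary
flags.  Summaries follow the usual simulation-study metrics: average
estimate (AE), mean squared error (MSE), average interval length (AL),
coverage probability (CP, in percent), and the percentage of replicates in
which adjacent scales were estimated equal (the order restriction binding).

Replicate r uses the seed stream spawn(base_seed, r), so studies are
reproducible and parallelizable; replicates whose fit fails are excluded
and counted, not redrawn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import PriorSpec, bayes_estimate, draw_posterior, hpd_interval, symmetric_interval
from .dataset import make_dataset
from .distributions import CEMParams, StressSchedule, cem_sample
from .mle import delta_method_ci, fit_order_restricted

__all__ = ["StudyConfig", "StudySummary", "run_study", "qq_standardized", "study_table"]


@dataclass(frozen=True)
class StudyConfig:
    """One cell of a simulation study."""

    alpha: float
    betas: tuple
    change_times: tuple
    n: int
    replications: int = 1000
    seed: int = 0
    method: str = "mle"          # 'mle' or 'bayes'
    level: float = 0.95
    interval: str = "symmetric"  # for bayes: 'symmetric' or 'hpd'
    n_draws: int = 10_000
    prior: PriorSpec | None = None
    n_restarts: int = 4

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("need at least one replication")
        if self.method not in ("mle", "bayes"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def true_params(self) -> CEMParams:
        return CEMParams(self.alpha, self.betas)

    @property
    def schedule(self) -> StressSchedule:
        return StressSchedule(self.change_times)


@dataclass
class StudySummary:
    """Aggregated metrics plus the raw replicate table for diagnostics."""

    config: StudyConfig
    replicates: pd.DataFrame   # one row per successful replicate
    n_failed: int
    param_names: tuple = field(init=False)

    def __post_init__(self):
        m1 = len(self.config.betas)
        self.param_names = ("alpha",) + tuple(f"beta{k + 1}" for k in range(m1))

    def _truth(self, name: str) -> float:
        return self.config.alpha if name == "alpha" else self.config.betas[int(name[4:]) - 1]

    def ae(self, name: str) -> float:
        return float(self.replicates[name].mean())

    def mse(self, name: str) -> float:
        return float(((self.replicates[name] - self._truth(name)) ** 2).mean())

    def average_length(self, name: str) -> float:
        return float((self.replicates[f"{name}_hi"] - self.replicates[f"{name}_lo"]).mean())

    def coverage(self, name: str) -> float:
        """Percentage of intervals containing the truth (zero-truncated
        lower bounds count as covering from 0)."""
        truth = self._truth(name)
        lo = np.maximum(0.0, self.replicates[f"{name}_lo"])
        covered = (lo <= truth) & (truth <= self.replicates[f"{name}_hi"])
        return float(100.0 * covered.mean())

    def equality_percent(self, k: int) -> float:
        """Percentage of replicates with beta_k = beta_{k+1} bound (1-based k)."""
        return float(100.0 * self.replicates[f"bound{k}"].mean())

    def mc_se(self, name: str, what: str = "ae") -> float:
        """Monte-Carlo standard error of the AE or MSE summary."""
        x = self.replicates[name].to_numpy()
        if what == "mse":
            x = (x - self._truth(name)) ** 2
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    def row(self) -> dict:
        cfg = self.config
        out = {
            "method": cfg.method, "alpha": cfg.alpha, "n": cfg.n,
            **{f"tau{j + 1}": t for j, t in enumerate(cfg.change_times)},
            "replications": len(self.replicates), "failed": self.n_failed,
        }
        for name in self.param_names:
            out[f"AE_{name}"] = self.ae(name)
            out[f"MSE_{name}"] = self.mse(name)
            out[f"AL_{name}"] = self.average_length(name)
            out[f"CP_{name}"] = self.coverage(name)
        for k in range(1, len(self.config.betas)):
            out[f"eq_beta{k}_beta{k + 1}"] = self.equality_percent(k)
        return out


def _fit_replicate_mle(data, cfg: StudyConfig) -> dict:
    fit = fit_order_restricted(data, n_restarts=cfg.n_restarts)
    ivs = delta_method_ci(fit, cfg.level)
    rec = {"alpha": fit.params.alpha, "alpha_lo": ivs.alpha[0], "alpha_hi": ivs.alpha[1]}
    for k, (b, iv) in enumerate(zip(fit.params.betas, ivs.betas), start=1):
        rec[f"beta{k}"], rec[f"beta{k}_lo"], rec[f"beta{k}_hi"] = b, iv[0], iv[1]
        rec[f"beta{k}_se"] = (iv[1] - iv[0]) / 2.0
    for k, flag in enumerate(fit.boundary_flags, start=1):
        rec[f"bound{k}"] = bool(flag)
    rec["loglik"] = fit.loglik
    return rec


def _fit_replicate_bayes(data, cfg: StudyConfig, rng) -> dict:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-ESS warnings are summarized instead
        post = draw_posterior(data, cfg.prior, cfg.n_draws, rng)
    pick = hpd_interval if cfg.interval == "hpd" else symmetric_interval
    rec = {}
    for name in ["alpha"] + [f"beta{k + 1}" for k in range(data.schedule.n_levels)]:
        rec[name] = bayes_estimate(post, name)
        rec[f"{name}_lo"], rec[f"{name}_hi"] = pick(post, name, cfg.level)
    for k in range(1, data.schedule.n_levels):
        rec[f"bound{k}"] = False  # the continuous posterior never binds exactly
    rec["ess"] = post.ess
    return rec


def run_study(config: StudyConfig) -> StudySummary:
    """Run all replications of one study cell and aggregate."""
    rows = []
    n_failed = 0
    for r in range(config.replications):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(r,)))
        times, _ = cem_sample(config.n, config.true_params, config.schedule, rng)
        data = make_dataset(times, config.schedule)
        try:
            if config.method == "mle":
                rec = _fit_replicate_mle(data, config)
            else:
                rec = _fit_replicate_bayes(data, config, rng)
        except Exception as exc:  # noqa: BLE001 - replicate-level failures are reported
            warnings.warn(f"replicate {r} failed: {exc}", stacklevel=2)
            n_failed += 1
            continue
        rec["replicate"] = r
        rows.append(rec)
    return StudySummary(config=config, replicates=pd.DataFrame(rows), n_failed=n_failed)


def qq_standardized(summary: StudySummary, param: str):
    """Normal QQ pairs of the standardized replicate estimates.

    Standardization is by the empirical mean and SD of the replicate
    estimates; returns (theoretical, sample) quantile arrays.
    """
    from scipy import stats

    est = summary.replicates[param].to_numpy()
    if len(est) < 10:
        raise ValueError("need at least 10 replicates for a QQ diagnostic")
    sd = est.std(ddof=1)
    if sd == 0:
        raise ValueError("constant estimates cannot be standardized")
    z = np.sort((est - est.mean()) / sd)
    probs = (np.arange(1, len(z) + 1) - 0.5) / len(z)
    return stats.norm.ppf(probs), z


def study_table(summaries) -> pd.DataFrame:
    """One row per study cell, in a fixed column order."""
    rows = [s.row() for s in summaries]
    return pd.DataFrame(rows)
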