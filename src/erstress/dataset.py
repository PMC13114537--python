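"""Step-stress dataset container, validation, file I/O, and the fish fixture.

A complete (uncensored) step-stress sample is the ordered failure times
``t_{1:n} < ... < t_{n:n}`` together with the stress schedule.  Each time is
assigned to the stress level whose half-open interval ``(tau_{k-1}, tau_k]``
contains it; the per-level counts ``n_k`` and cumulative counts ``nbar_j``
drive every likelihood computation downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import StressSchedule

__all__ = ["StepStressData", "make_dataset", "read_dataset", "write_dataset", "fish_data"]


@dataclass(frozen=True)
class StepStressData:
    """Ordered failure times plus schedule, with per-level bookkeeping."""

    times: np.ndarray
    schedule: StressSchedule
    counts: np.ndarray      # n_k, failures per level, length m + 1
    cum_counts: np.ndarray  # nbar_j = n_1 + ... + n_j
    levels: np.ndarray      # 0-based level index of each ordered time

    @property
    def n(self) -> int:
        return len(self.times)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StepStressData)
            and np.array_equal(self.times, other.times)
            and self.schedule == other.schedule
        )

    def __repr__(self) -> str:
        return (
            f"StepStressData(n={self.n}, levels={self.schedule.n_levels}, "
            f"counts={self.counts.tolist()})"
        )


def make_dataset(times, change_times=()) -> StepStressData:
    """Build a validated dataset from failure times and change times.

    Times are sorted; duplicates are kept in stable order with a warning;
    nonpositive times, or times exactly equal to a change point (ambiguous
    level membership), are rejected.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise ValueError("empty dataset")
    if np.any(times <= 0):
        raise ValueError("failure times must be strictly positive")
    sched = change_times if isinstance(change_times, StressSchedule) else StressSchedule(change_times)
    if np.isin(times, sched.change_times).any():
        raise ValueError(
            "a failure time coincides exactly with a stress change time; "
            "level membership is ambiguous"
        )
    times = np.sort(times, kind="stable")
    if np.any(np.diff(times) == 0):
        warnings.warn("duplicate failure times present; kept in stable order", stacklevel=2)
    levels = sched.level_of(times)
    counts = np.bincount(levels, minlength=sched.n_levels)
    return StepStressData(
        times=times,
        schedule=sched,
        counts=counts,
        cum_counts=np.cumsum(counts),
        levels=levels,
    )


def write_dataset(data: StepStressData, path) -> None:
    """Write times as CSV (one ``time`` column) plus a JSON schedule sidecar."""
    path = Path(path)
    pd.DataFrame({"time": data.times}).to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"change_times": list(data.schedule.change_times)}))


def read_dataset(path, change_times=None) -> StepStressData:
    """Read a dataset written by :func:`write_dataset`.

    ``change_times`` may be given explicitly (sequence or path to a JSON file
    with a ``change_times`` key); otherwise the ``.json`` sidecar next to the
    CSV is used.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if "time" not in df.columns:
        raise ValueError(f"{path}: expected a 'time' column, got {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: empty dataset")
    if change_times is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"missing change_times: no sidecar {sidecar}")
        change_times = sidecar
    if isinstance(change_times, (str, Path)):
        change_times = json.loads(Path(change_times).read_text())["change_times"]
    return make_dataset(df["time"].to_numpy(), change_times)


def fish_data() -> StepStressData:
    """The bundled fish swimming-endurance step-stress dataset.

    Fifteen fish swam against a current whose flow rate was raised at 110,
    130, 150 and 170 s (five stress levels); the failure time is the moment a
    fish could no longer hold its position.  Failure counts per level are
    (4, 6, 0, 3, 2).
    """
    root = resources.files("erstress") / "data"
    times = pd.read_csv(root / "fish.csv")["time"].to_numpy()
    taus = json.loads((root / "fish.json").read_text())["change_times"]
    return make_dataset(times, taus)
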