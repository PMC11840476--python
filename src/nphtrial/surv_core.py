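"""Counting-process backbone for two-arm survival data.

A trial is stored subject-wise (:class:`TrialDataset`), reduced once to the
risk-set / event-count representation at the observed unique event times
(:class:`CountingProcess`), from which every non-parametric quantity in this
package is computed: the Nelson-Aalen-Breslow survival estimator
``S(t) = exp(-sum dN/Y)``, the Kaplan-Meier product-limit estimator, the
hypergeometric event-count variances of the (weighted) log-rank statistics,
and the counting-process variance formulas of the RMST / milestone / median /
average-hazard-ratio estimands.

All times are in months from randomization (1 month = 365.25/12 days);
``recruit_time`` is calendar months from trial start.  Ties between an event
and a censoring at the same time are resolved with the usual risk-set
convention: the event happens first, so a subject censored at ``t`` is still
at risk for the events at ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 365.25 / 12.0

__all__ = [
    "DAYS_PER_MONTH",
    "NoEventsError",
    "UndefinedEstimateError",
    "TrialDataset",
    "CountingProcess",
    "StepSurvival",
    "build_counting_process",
    "nab_survival",
    "km_survival",
]


class NoEventsError(ValueError):
    """Raised when an operation requires at least one observed event."""


class UndefinedEstimateError(ValueError):
    """Raised when an estimand is not identified on the data at hand.

    Examples: the survival estimate never reaches 0.5 (median undefined), no
    subject at risk at a milestone time, no events before an RMST/AHR cutoff.
    """


def _as_array(x, dtype=float) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=dtype))


@dataclass
class TrialDataset:
    """Per-subject data of a two-arm randomized trial.

    Parameters
    ----------
    recruit_time
        Calendar time of randomization in months (>= 0).
    obs_time
        Observed time from randomization in months (> 0): event time if
        ``event`` is True, censoring time otherwise.
    event
        Event indicator (True = event observed, False = censored).
    arm
        0 = control, 1 = treatment.
    subgroup
        Optional biomarker labels (``"pos"`` / ``"neg"``).
    progression_time
        Optional observed progression time in months (NaN when progression
        was not observed before ``obs_time``).
    """

    recruit_time: np.ndarray
    obs_time: np.ndarray
    event: np.ndarray
    arm: np.ndarray
    subgroup: Optional[np.ndarray] = None
    progression_time: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.recruit_time = _as_array(self.recruit_time)
        self.obs_time = _as_array(self.obs_time)
        self.event = _as_array(self.event, dtype=bool)
        self.arm = _as_array(self.arm, dtype=int)
        n = len(self.obs_time)
        for name in ("recruit_time", "event", "arm"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has length != {n}")
        if self.subgroup is not None:
            self.subgroup = np.asarray(self.subgroup, dtype=object)
        if self.progression_time is not None:
            self.progression_time = _as_array(self.progression_time)
        if np.any(self.obs_time <= 0):
            raise ValueError("obs_time must be strictly positive")
        if np.any(self.recruit_time < 0):
            raise ValueError("recruit_time must be non-negative")
        bad = set(np.unique(self.arm)) - {0, 1}
        if bad:
            raise ValueError(f"arm must be coded 0 (control) / 1 (treatment); got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.obs_time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "recruit_time": self.recruit_time,
                "obs_time": self.obs_time,
                "event": self.event.astype(int),
                "arm": self.arm,
            }
        )
        if self.subgroup is not None:
            df["subgroup"] = self.subgroup
        if self.progression_time is not None:
            df["progression_time"] = self.progression_time
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrialDataset":
        return cls(
            recruit_time=df["recruit_time"].to_numpy(float),
            obs_time=df["obs_time"].to_numpy(float),
            event=df["event"].to_numpy(int).astype(bool),
            arm=df["arm"].to_numpy(int),
            subgroup=df["subgroup"].to_numpy(object) if "subgroup" in df else None,
            progression_time=(
                df["progression_time"].to_numpy(float) if "progression_time" in df else None
            ),
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "TrialDataset":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class CountingProcess:
    """Risk sets and event counts at the ordered unique event times.

    ``times`` are the pooled unique observed event times t1 < ... < tk.
    ``y0``/``y1`` are the numbers at risk per arm just before each time,
    ``d0``/``d1`` the event counts per arm at each time.
    """

    times: np.ndarray
    y0: np.ndarray
    y1: np.ndarray
    d0: np.ndarray
    d1: np.ndarray

    @property
    def k(self) -> int:
        return len(self.times)

    @property
    def y(self) -> np.ndarray:
        return self.y0 + self.y1

    @property
    def d(self) -> np.ndarray:
        return self.d0 + self.d1

    @property
    def e0(self) -> np.ndarray:
        """Expected control events per time under the null, d * Y0 / Y."""
        return self.d * self.y0 / self.y

    @property
    def v(self) -> np.ndarray:
        """Hypergeometric variance of dN0 per time, 0 where Y <= 1."""
        y, d, y0 = self.y, self.d, self.y0
        with np.errstate(divide="ignore", invalid="ignore"):
            out = d * (y0 / y) * (1.0 - y0 / y) * (y - d) / (y - 1.0)
        return np.where(y > 1, out, 0.0)

    def arm_counts(self, arm: Optional[int]) -> tuple[np.ndarray, np.ndarray]:
        """(at-risk, events) arrays for one arm, or pooled when arm is None."""
        if arm is None:
            return self.y, self.d
        if arm == 0:
            return self.y0, self.d0
        if arm == 1:
            return self.y1, self.d1
        raise ValueError(f"arm must be 0, 1 or None; got {arm!r}")

    def swap_arms(self) -> "CountingProcess":
        return CountingProcess(self.times, self.y1, self.y0, self.d1, self.d0)


def build_counting_process(data: TrialDataset) -> CountingProcess:
    """Reduce a dataset to its counting-process representation.

    Censored observations contribute to the at-risk counts only.  Raises
    :class:`NoEventsError` if the pooled sample contains no event.
    """
    if data.n_events == 0:
        raise NoEventsError("no events in the pooled sample")
    times = np.unique(data.obs_time[data.event])
    obs0 = data.obs_time[data.arm == 0]
    obs1 = data.obs_time[data.arm == 1]
    # Y_i(t_j) = #{obs >= t_j}; counting from sorted obs avoids an O(n*k) matrix.
    y0 = len(obs0) - np.searchsorted(np.sort(obs0), times, side="left")
    y1 = len(obs1) - np.searchsorted(np.sort(obs1), times, side="left")
    d0 = np.zeros(len(times))
    d1 = np.zeros(len(times))
    ev0 = data.obs_time[(data.arm == 0) & data.event]
    ev1 = data.obs_time[(data.arm == 1) & data.event]
    np.add.at(d0, np.searchsorted(times, ev0), 1.0)
    np.add.at(d1, np.searchsorted(times, ev1), 1.0)
    return CountingProcess(times, y0.astype(float), y1.astype(float), d0, d1)


@dataclass
class StepSurvival:
    """Right-continuous non-increasing step function with S(0) = 1.

    ``jump_times`` need not all be actual jumps; values are carried constant
    on [t_j, t_{j+1}).
    """

    jump_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.jump_times = _as_array(self.jump_times)
        self.values = _as_array(self.values)
        if len(self.jump_times) != len(self.values):
            raise ValueError("jump_times and values must have equal length")

    def value_at(self, t):
        """S(t), right-continuous."""
        idx = np.searchsorted(self.jump_times, t, side="right") - 1
        vals = np.concatenate([[1.0], self.values])
        return vals[np.asarray(idx) + 1] if np.ndim(t) else float(vals[idx + 1])

    def left_limit(self, t):
        """S(t-), the value just before t; 1 at or before the first jump."""
        idx = np.searchsorted(self.jump_times, t, side="left") - 1
        vals = np.concatenate([[1.0], self.values])
        return vals[np.asarray(idx) + 1] if np.ndim(t) else float(vals[idx + 1])

    def __call__(self, t):
        return self.value_at(t)


def _arm_increments(cp: CountingProcess, arm: Optional[int]) -> np.ndarray:
    """dN/Y per pooled event time for one arm (0 where the arm has no event)."""
    y, d = cp.arm_counts(arm)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(d > 0, d / y, 0.0)
    return inc


def nab_survival(cp: CountingProcess, arm: Optional[int] = None) -> StepSurvival:
    """Nelson-Aalen-Breslow estimator exp(-sum dN/Y) for one arm or pooled.

    Strictly positive everywhere; identically 1 when the arm has no events.
    """
    inc = _arm_increments(cp, arm)
    return StepSurvival(cp.times.copy(), np.exp(-np.cumsum(inc)))


def km_survival(cp: CountingProcess, arm: Optional[int] = None) -> StepSurvival:
    """Kaplan-Meier product-limit estimator prod(1 - dN/Y)."""
    inc = _arm_increments(cp, arm)
    return StepSurvival(cp.times.copy(), np.cumprod(1.0 - inc))
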