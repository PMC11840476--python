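"""Generative engine for the simulation scenarios.

Latent event times come from one of three arm-level hazard models:

* :class:`PiecewiseHazard` - piecewise-constant hazard (delayed-onset and
  crossing-hazards families; constant hazard as the one-piece special case);
* :class:`SubgroupMixture` - a biomarker-positive / negative mixture of
  piecewise-exponential subgroups with fixed prevalence;
* :class:`IllnessDeath` - the three-state progression model (pre-progression
  -> progression -> death, plus direct death) with constant transition
  intensities.

On top of the latent times the trial design is layered: uniform recruitment
over the recruitment window, independent exponential drop-out censoring whose
rate is solved to hit a target censoring proportion, and an event-driven
cutoff at the calendar time of the target-events-th event, which induces
administrative censoring.

``true_summaries`` evaluates the true estimands (median / RMST / milestone
differences, average hazard ratio) from the analytic survival and hazard
functions by closed form or adaptive quadrature; it is the reference the
operating-characteristics harness measures bias and coverage against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .surv_core import TrialDataset

__all__ = [
    "PiecewiseHazard",
    "SubgroupMixture",
    "IllnessDeath",
    "MultistateSpec",
    "ScenarioSpec",
    "CensoringSpec",
    "sample_piecewise",
    "sample_multistate",
    "tmax_horizon",
    "solve_censoring_rate",
    "simulate_trial",
    "true_summaries",
]

logger = logging.getLogger("nphtrial")

#: survival level defining the simulation horizon t_max (the 0.9999 event quantile)
_HORIZON_LEVEL = 1e-4


@dataclass(frozen=True)
class PiecewiseHazard:
    """Piecewise-constant hazard: rate ``rates[k]`` on [breakpoints[k], breakpoints[k+1])."""

    breakpoints: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in self.breakpoints))
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if len(self.breakpoints) != len(self.rates):
            raise ValueError("need one rate per breakpoint interval")
        if self.breakpoints[0] != 0.0:
            raise ValueError("breakpoints must start at 0")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be non-negative")

    @classmethod
    def exponential(cls, rate: float) -> "PiecewiseHazard":
        return cls((0.0,), (rate,))

    @property
    def _knot_cumhaz(self) -> np.ndarray:
        b = np.asarray(self.breakpoints)
        r = np.asarray(self.rates)
        return np.concatenate([[0.0], np.cumsum(r[:-1] * np.diff(b))])

    def hazard(self, t):
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        return np.asarray(self.rates)[idx]

    def cumhaz(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        b = np.asarray(self.breakpoints)
        r = np.asarray(self.rates)
        return self._knot_cumhaz[idx] + r[idx] * (t - b[idx])

    def survival(self, t):
        return np.exp(-self.cumhaz(t))

    def inverse_cumhaz(self, h):
        """Smallest t with Lambda(t) = h (exact on the piecewise-linear Lambda).

        A right-search on the knot cumulative hazards skips zero-rate
        intervals (over which Lambda is flat and the knot values coincide),
        so the located interval has positive rate whenever h is reachable.
        """
        h = np.asarray(h, dtype=float)
        knots = self._knot_cumhaz
        r = np.asarray(self.rates)
        b = np.asarray(self.breakpoints)
        idx = np.clip(np.searchsorted(knots, h, side="right") - 1, 0, len(r) - 1)
        if np.any((r[idx] == 0.0) & (h > knots[idx])):
            raise ValueError("cumulative hazard never reaches the requested level")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b[idx] + (h - knots[idx]) / r[idx]
        return np.where(h == knots[idx], b[idx], t) if np.ndim(h) else (
            b[idx] if h == knots[idx] else float(t)
        )

    def quantile(self, q: float) -> float:
        """Time at which survival equals q (event quantile 1-q)."""
        return float(self.inverse_cumhaz(-np.log(q)))

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    def sample(self, n: int, rng: np.random.Generator):
        return sample_piecewise(self, n, rng), None

    def to_dict(self) -> dict:
        return {"type": "piecewise", "breakpoints": list(self.breakpoints), "rates": list(self.rates)}


def sample_piecewise(haz: PiecewiseHazard, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-transform sampling on the piecewise-linear cumulative hazard."""
    if not any(r > 0 for r in haz.rates):
        raise ValueError("cannot sample from an all-zero hazard")
    if haz.rates[-1] == 0.0:
        raise ValueError("terminal hazard rate 0: survival is bounded away from 0")
    u = rng.uniform(size=n)
    return np.asarray(haz.inverse_cumhaz(-np.log(u)), dtype=float)


@dataclass(frozen=True)
class SubgroupMixture:
    """Biomarker mixture: positives with prevalence p, each stratum piecewise-exponential."""

    prevalence: float
    pos: PiecewiseHazard
    neg: PiecewiseHazard

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")

    def survival(self, t):
        return self.prevalence * self.pos.survival(t) + (1.0 - self.prevalence) * self.neg.survival(t)

    def hazard(self, t):
        dens = (
            self.prevalence * self.pos.hazard(t) * self.pos.survival(t)
            + (1.0 - self.prevalence) * self.neg.hazard(t) * self.neg.survival(t)
        )
        return dens / self.survival(t)

    def cumhaz(self, t):
        return -np.log(self.survival(t))

    def sample(self, n: int, rng: np.random.Generator):
        is_pos = rng.uniform(size=n) < self.prevalence
        times = np.empty(n)
        if is_pos.any():
            times[is_pos] = sample_piecewise(self.pos, int(is_pos.sum()), rng)
        if (~is_pos).any():
            times[~is_pos] = sample_piecewise(self.neg, int((~is_pos).sum()), rng)
        labels = np.where(is_pos, "pos", "neg").astype(object)
        return times, {"subgroup": labels}

    def to_dict(self) -> dict:
        return {
            "type": "subgroup_mixture",
            "prevalence": self.prevalence,
            "pos": self.pos.to_dict(),
            "neg": self.neg.to_dict(),
        }


@dataclass(frozen=True)
class IllnessDeath:
    """Illness-death model with constant transition intensities (per month).

    ``h_prog``: pre-progression -> progression; ``h_death_pre``:
    pre-progression -> death; ``h_death_post``: post-progression -> death.
    The induced overall-survival hazard is time-varying even though every
    transition intensity is constant.
    """

    h_prog: float
    h_death_pre: float
    h_death_post: float

    def __post_init__(self):
        if min(self.h_prog, self.h_death_pre, self.h_death_post) < 0:
            raise ValueError("transition intensities must be non-negative")

    @property
    def progression_proportion(self) -> float:
        """Expected share of subjects progressing before death."""
        tot = self.h_prog + self.h_death_pre
        return self.h_prog / tot if tot > 0 else 0.0

    def survival(self, t):
        a, b, c = self.h_prog, self.h_death_pre, self.h_death_post
        t = np.asarray(t, dtype=float)
        s_pre = np.exp(-(a + b) * t)
        if a == 0.0:
            return s_pre
        if abs(a + b - c) < 1e-12:
            return s_pre * (1.0 + a * t)
        return s_pre + a / (a + b - c) * (np.exp(-c * t) - s_pre)

    def density(self, t):
        return -self._dsurv(t)

    def _dsurv(self, t):
        a, b, c = self.h_prog, self.h_death_pre, self.h_death_post
        t = np.asarray(t, dtype=float)
        ds_pre = -(a + b) * np.exp(-(a + b) * t)
        if a == 0.0:
            return ds_pre
        if abs(a + b - c) < 1e-12:
            return ds_pre * (1.0 + a * t) + np.exp(-(a + b) * t) * a
        return ds_pre + a / (a + b - c) * (-c * np.exp(-c * t) - ds_pre)

    def hazard(self, t):
        return -self._dsurv(t) / self.survival(t)

    def cumhaz(self, t):
        return -np.log(self.survival(t))

    def sample(self, n: int, rng: np.random.Generator):
        os, prog = sample_multistate(self, n, rng)
        return os, {"progression_time": prog}

    def to_dict(self) -> dict:
        return {
            "type": "illness_death",
            "h_prog": self.h_prog,
            "h_death_pre": self.h_death_pre,
            "h_death_post": self.h_death_post,
        }


#: alias matching the domain vocabulary: the per-arm multistate intensity set
MultistateSpec = IllnessDeath

HazardModel = Union[PiecewiseHazard, SubgroupMixture, IllnessDeath]


def sample_multistate(
    ms: IllnessDeath, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (overall survival time, progression time or NaN) per subject.

    The exit from the pre-progression state is exponential with rate
    h_prog + h_death_pre; it is a progression with probability
    h_prog / (h_prog + h_death_pre), in which case a residual post-progression
    death time with rate h_death_post is added.
    """
    a, b, c = ms.h_prog, ms.h_death_pre, ms.h_death_post
    total = a + b
    if total <= 0:
        raise ValueError("no exit from the pre-progression state: all intensities 0")
    t_exit = rng.exponential(1.0 / total, size=n)
    progresses = rng.uniform(size=n) < (a / total)
    os = t_exit.copy()
    prog_time = np.full(n, np.nan)
    n_prog = int(progresses.sum())
    if n_prog:
        if c <= 0:
            raise ValueError("post-progression death intensity must be positive")
        os[progresses] = t_exit[progresses] + rng.exponential(1.0 / c, size=n_prog)
        prog_time[progresses] = t_exit[progresses]
    return os, prog_time


def _model_from_dict(d: dict) -> HazardModel:
    kind = d["type"]
    if kind == "piecewise":
        return PiecewiseHazard(tuple(d["breakpoints"]), tuple(d["rates"]))
    if kind == "subgroup_mixture":
        return SubgroupMixture(
            d["prevalence"], _model_from_dict(d["pos"]), _model_from_dict(d["neg"])
        )
    if kind == "illness_death":
        return IllnessDeath(d["h_prog"], d["h_death_pre"], d["h_death_post"])
    raise ValueError(f"unknown hazard model type {kind!r}")


def _horizon_one(model: HazardModel) -> float:
    """Time at which the model's survival reaches the horizon level."""
    if isinstance(model, PiecewiseHazard):
        return float(model.inverse_cumhaz(-np.log(_HORIZON_LEVEL)))
    hi = 1.0
    for _ in range(200):
        if model.survival(hi) < _HORIZON_LEVEL:
            break
        hi *= 2.0
    else:
        raise ValueError("survival stays above the horizon level; t_max undefined")
    return float(brentq(lambda t: model.survival(t) - _HORIZON_LEVEL, 0.0, hi, xtol=1e-10))


def tmax_horizon(haz0: HazardModel, haz1: HazardModel) -> float:
    """Larger of the two arms' 0.9999 event quantiles (survival = 1e-4)."""
    return max(_horizon_one(haz0), _horizon_one(haz1))


@dataclass(frozen=True)
class CensoringSpec:
    """Solved exponential drop-out model hitting a target censoring share.

    Before ``tmax`` and ignoring the administrative cutoff, the expected
    proportion of subjects censored before their event is
    p = 1/2 * Lc/(Lc + L0) + 1/2 * Lc/(Lc + L1), where Lc = lambda_c * tmax
    and L_i are the arms' cumulative event hazards at tmax.
    """

    p: float
    tmax: float
    rate: float
    cumhaz_censor: float
    cumhaz_event0: float
    cumhaz_event1: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.rate <= 0.0:
            return np.full(n, np.inf)
        return rng.exponential(1.0 / self.rate, size=n)


def solve_censoring_rate(haz0: HazardModel, haz1: HazardModel, p: float) -> CensoringSpec:
    """Solve the exponential censoring rate for a target proportion p in [0, 1)."""
    if not 0.0 <= p < 1.0:
        raise ValueError("censoring proportion must lie in [0, 1)")
    tmax = tmax_horizon(haz0, haz1)
    L0 = float(haz0.cumhaz(tmax))
    L1 = float(haz1.cumhaz(tmax))
    if p == 0.0:
        return CensoringSpec(0.0, tmax, 0.0, 0.0, L0, L1)

    def resid(lam_c: float) -> float:
        Lc = lam_c * tmax
        return 0.5 * Lc / (Lc + L0) + 0.5 * Lc / (Lc + L1) - p

    hi = 1.0
    while resid(hi) < 0.0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("no censoring rate solves the target proportion")
    rate = float(brentq(resid, 0.0, hi, xtol=1e-14, rtol=8.9e-16))
    assert abs(resid(rate)) < 1e-10
    return CensoringSpec(p, tmax, rate, rate * tmax, L0, L1)


@dataclass
class ScenarioSpec:
    """Complete generative description of one simulation scenario."""

    family: str
    control: HazardModel
    treatment: HazardModel
    n: int = 500
    recruitment_duration: float = 18.0
    target_events: int = 375
    censor_prop: float = 0.10
    name: str = ""

    def __post_init__(self):
        if self.target_events > self.n:
            raise ValueError("target_events cannot exceed the sample size")
        if not 0.0 <= self.censor_prop < 1.0:
            raise ValueError("censor_prop must lie in [0, 1)")

    def arm_model(self, arm: int) -> HazardModel:
        return self.control if arm == 0 else self.treatment

    def censoring(self) -> CensoringSpec:
        return solve_censoring_rate(self.control, self.treatment, self.censor_prop)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "name": self.name,
            "control": self.control.to_dict(),
            "treatment": self.treatment.to_dict(),
            "n": self.n,
            "recruitment_duration": self.recruitment_duration,
            "target_events": self.target_events,
            "censor_prop": self.censor_prop,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            family=d["family"],
            control=_model_from_dict(d["control"]),
            treatment=_model_from_dict(d["treatment"]),
            n=int(d.get("n", 500)),
            recruitment_duration=float(d.get("recruitment_duration", 18.0)),
            target_events=int(d.get("target_events", 375)),
            censor_prop=float(d.get("censor_prop", 0.10)),
            name=d.get("name", ""),
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate_trial(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    censoring: Optional[CensoringSpec] = None,
) -> TrialDataset:
    """Simulate one event-driven trial.

    Recruitment times are i.i.d. uniform on [0, recruitment_duration]
    (a constant recruitment rate conditioned on the fixed sample size);
    allocation is 1:1 by random permutation.  Each subject's latent event
    time competes with an independent exponential drop-out time on the
    patient time scale; the trial is cut at the calendar time at which the
    target number of events has occurred, administratively censoring times
    that extend beyond the cutoff.  If the target is never reached the full
    follow-up is returned with a warning.
    """
    n = spec.n
    if censoring is None:
        censoring = spec.censoring()
    recruit = rng.uniform(0.0, spec.recruitment_duration, size=n)
    arm = np.zeros(n, dtype=int)
    arm[rng.permutation(n)[: n // 2]] = 1
    latent = np.empty(n)
    extras: dict[str, np.ndarray] = {}
    for a in (0, 1):
        sel = arm == a
        times, extra = spec.arm_model(a).sample(int(sel.sum()), rng)
        latent[sel] = times
        if extra:
            for key, vals in extra.items():
                if key not in extras:
                    fill = np.nan if key == "progression_time" else None
                    extras[key] = np.full(n, fill, dtype=object if key == "subgroup" else float)
                extras[key][sel] = vals
    censor = censoring.sample(n, rng)
    patient_time = np.minimum(latent, censor)
    is_event = latent <= censor
    calendar_event = recruit[is_event] + latent[is_event]
    if is_event.sum() >= spec.target_events:
        cutoff = float(np.sort(calendar_event)[spec.target_events - 1])
    else:
        cutoff = np.inf
        warnings.warn(
            f"only {int(is_event.sum())} events observable; target "
            f"{spec.target_events} never reached - returning full follow-up",
            stacklevel=2,
        )
    keep = recruit < cutoff
    window = cutoff - recruit
    obs = np.minimum(patient_time, window)[keep]
    event = (is_event & (patient_time <= window))[keep]
    sub = extras.get("subgroup")
    prog = extras.get("progression_time")
    if prog is not None:
        prog = np.where(prog <= np.minimum(patient_time, window), prog, np.nan)[keep]
    return TrialDataset(
        recruit_time=recruit[keep],
        obs_time=obs,
        event=event,
        arm=arm[keep],
        subgroup=sub[keep] if sub is not None else None,
        progression_time=prog,
    )


def _true_median(model: HazardModel) -> float:
    if isinstance(model, PiecewiseHazard):
        return model.median
    hi = 1.0
    while model.survival(hi) > 0.5:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("survival never reaches 0.5")
    return float(brentq(lambda t: model.survival(t) - 0.5, 0.0, hi, xtol=1e-12))


def _quad(fn, lo: float, hi: float, model_breaks=()) -> float:
    pts = [b for b in model_breaks if lo < b < hi]
    val, _ = quad(fn, lo, hi, points=pts or None, epsabs=1e-10, limit=200)
    return float(val)


def _breaks(model: HazardModel) -> tuple[float, ...]:
    if isinstance(model, PiecewiseHazard):
        return model.breakpoints
    if isinstance(model, SubgroupMixture):
        return tuple(sorted(set(model.pos.breakpoints) | set(model.neg.breakpoints)))
    return ()


def true_summaries(
    spec: ScenarioSpec, cutoffs: tuple[float, ...] = (6.0, 12.0, 24.0)
) -> dict[str, float]:
    """True estimand values implied by the scenario's survival functions.

    Keys: ``median_0``, ``median_1``, ``median_diff``, and per cutoff L in
    ``cutoffs``: ``rmst_diff_L``, ``milestone_diff_L``, ``ahr_L``.
    """
    s0, s1 = spec.control, spec.treatment
    brk = tuple(sorted(set(_breaks(s0)) | set(_breaks(s1))))
    out: dict[str, float] = {}
    m0, m1 = _true_median(s0), _true_median(s1)
    out["median_0"], out["median_1"], out["median_diff"] = m0, m1, m1 - m0
    for L in cutoffs:
        rm0 = _quad(lambda t: float(s0.survival(t)), 0.0, L, brk)
        rm1 = _quad(lambda t: float(s1.survival(t)), 0.0, L, brk)
        out[f"rmst_diff_{L:g}"] = rm1 - rm0
        out[f"milestone_diff_{L:g}"] = float(s1.survival(L)) - float(s0.survival(L))
        num = _quad(
            lambda t: float(s0.survival(t)) * float(s1.survival(t)) * float(s1.hazard(t)),
            0.0, L, brk,
        )
        den = _quad(
            lambda t: float(s0.survival(t)) * float(s1.survival(t)) * float(s0.hazard(t)),
            0.0, L, brk,
        )
        out[f"ahr_{L:g}"] = num / den
    return out
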