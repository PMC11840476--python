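"""Schoenfeld-based effect targeting and per-family hazard calibration.

The study design fixes a control median (12 months), a number of events
(375), a one-sided level (2.5%) and a target power (80%).  Schoenfeld's
formula for the log-rank test under proportional hazards and 1:1 allocation,

    |log hr*| = 2 (z_{1-alpha} + z_{1-beta}) / sqrt(d),

turns that into a proportional-hazards reference effect hr* and thus a
target treatment median m1 = m0 / hr* (exponential control).  Every
non-proportional scenario family has one free hazard-ratio parameter, which
is root-solved so that the treatment arm's overall survival median equals
m1 - i.e. all families share the same between-arm median difference while
differing in the shape of the hazard-ratio function.

The calibrated ratios reproduce the canonical sequences: post-delay hazard
ratios 0.75 / 0.71 / 0.67 / 0.60 / 0.50 for delays of 0, 2, 4, 6, 8 months,
and post-crossing ratios 0.75 / 0.64 / 0.50 / 0.30 for crossings of
0, 2, 4, 6 months at a pre-crossing ratio of 1.5 (0.43 for a pre-crossing
ratio of 3 lasting 2 months); the target median difference is about 4.03
months, i.e. 123 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .scenario_sim import (
    IllnessDeath,
    PiecewiseHazard,
    ScenarioSpec,
    SubgroupMixture,
)
from .surv_core import DAYS_PER_MONTH

__all__ = [
    "CalibrationTarget",
    "schoenfeld_target",
    "calibrate_delay",
    "calibrate_crossing",
    "calibrate_subgroup",
    "calibrate_progression",
    "solve_control_multistate",
    "delayed_scenario",
    "crossing_scenario",
    "subgroup_scenario",
    "progression_scenario",
    "null_scenario",
]

_BRACKET = (1e-6, 10.0)
_XTOL = 1e-12


@dataclass(frozen=True)
class CalibrationTarget:
    """Design quantities plus the implied proportional-hazards reference effect."""

    control_median: float
    d_events: int
    alpha_one_sided: float
    power: float
    hr_star: float
    target_treatment_median: float

    @property
    def target_median_diff(self) -> float:
        """Months of median survival gained under the reference effect."""
        return self.target_treatment_median - self.control_median

    @property
    def target_median_diff_days(self) -> float:
        return self.target_median_diff * DAYS_PER_MONTH

    @property
    def control_rate(self) -> float:
        """Exponential control hazard per month."""
        return np.log(2.0) / self.control_median


def schoenfeld_target(
    control_median: float = 12.0,
    d: int = 375,
    alpha: float = 0.025,
    power: float = 0.80,
) -> CalibrationTarget:
    """Effect size giving the log-rank test the target power at d events."""
    if d <= 0:
        raise ValueError("number of events must be positive")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must lie in (0, 1)")
    log_hr = 2.0 * (norm.ppf(1.0 - alpha) + norm.ppf(power)) / np.sqrt(d)
    hr_star = float(np.exp(-log_hr))
    return CalibrationTarget(
        control_median=control_median,
        d_events=d,
        alpha_one_sided=alpha,
        power=power,
        hr_star=hr_star,
        target_treatment_median=control_median / hr_star,
    )


def _solve(fn, lo: float = _BRACKET[0], hi: float = _BRACKET[1]) -> float:
    if fn(lo) * fn(hi) > 0:
        raise ValueError("no calibrated hazard ratio in the search bracket")
    return float(brentq(fn, lo, hi, xtol=_XTOL))


def calibrate_delay(delay: float, target: CalibrationTarget) -> float:
    """Post-delay hazard ratio for the delayed-onset family.

    The treatment hazard equals the control hazard up to ``delay`` and
    HR * control rate afterwards; HR is solved so the treatment median is the
    target: lam0 * delay + HR * lam0 * (m1 - delay) = log 2.
    """
    m1 = target.target_treatment_median
    if not delay < m1:
        raise ValueError("delay must precede the target treatment median")
    lam0 = target.control_rate

    def resid(hr: float) -> float:
        return lam0 * delay + hr * lam0 * (m1 - delay) - np.log(2.0)

    return _solve(resid)


def calibrate_crossing(crossing: float, hr_pre: float, target: CalibrationTarget) -> float:
    """Post-crossing hazard ratio for the crossing-hazards family.

    Treatment hazard is hr_pre * control before ``crossing`` (hr_pre > 1:
    early harm) and HR * control afterwards, with HR solved from
    hr_pre * Lam0(crossing) + HR * (Lam0(m1) - Lam0(crossing)) = log 2.
    """
    m1 = target.target_treatment_median
    lam0 = target.control_rate
    if hr_pre * lam0 * crossing >= np.log(2.0):
        raise ValueError("treatment median is reached before the crossing time")

    def resid(hr: float) -> float:
        return hr_pre * lam0 * crossing + hr * lam0 * (m1 - crossing) - np.log(2.0)

    return _solve(resid)


def calibrate_subgroup(
    prevalence: float, hr_pos_vs_neg: float, target: CalibrationTarget
) -> float:
    """Hazard ratio vs control for the biomarker-negative stratum.

    Both strata are exponential under control; under treatment the positive
    stratum's hazard ratio is ``hr_pos_vs_neg`` times the negative stratum's.
    HR_neg is solved so the prevalence-weighted mixture survival passes
    through 0.5 at the target treatment median.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if hr_pos_vs_neg <= 0:
        raise ValueError("hr_pos_vs_neg must be positive")
    lam0m1 = target.control_rate * target.target_treatment_median

    def resid(hr_neg: float) -> float:
        return (
            prevalence * np.exp(-hr_pos_vs_neg * hr_neg * lam0m1)
            + (1.0 - prevalence) * np.exp(-hr_neg * lam0m1)
            - 0.5
        )

    return _solve(resid)


def solve_control_multistate(
    median: float = 12.0,
    prog_proportion: float = 0.2,
    post_multiplier: float = 2.0,
) -> IllnessDeath:
    """Control-arm intensities of the progression family.

    Pins three facts: the overall-survival median, the expected share of
    subjects progressing before death q = h_prog / (h_prog + h_death_pre),
    and the post/pre hazard multiplier m (h_death_post = m * h_death_pre).
    The remaining scale (h_death_pre) is root-solved on the analytic
    overall-survival function.
    """
    if not 0.0 <= prog_proportion < 1.0:
        raise ValueError("progression proportion must lie in [0, 1)")

    def build(b: float) -> IllnessDeath:
        a = prog_proportion / (1.0 - prog_proportion) * b
        return IllnessDeath(h_prog=a, h_death_pre=b, h_death_post=post_multiplier * b)

    def resid(b: float) -> float:
        return float(build(b).survival(median)) - 0.5

    b = _solve(resid, 1e-8, 10.0)
    return build(b)


def calibrate_progression(
    control_ms: IllnessDeath,
    trt_prog_proportion: float,
    target: CalibrationTarget,
) -> IllnessDeath:
    """Treatment-arm intensities of the progression family.

    A common hazard ratio HR scales the treatment arm's total pre-progression
    exit intensity; the split between progression and direct death honors the
    treatment progression proportion, and the post-progression intensity is
    shared with the control arm.  HR is root-solved so the treatment
    overall-survival median equals the target.
    """
    if not 0.0 <= trt_prog_proportion < 1.0:
        raise ValueError("progression proportion must lie in [0, 1)")
    total0 = control_ms.h_prog + control_ms.h_death_pre
    m1 = target.target_treatment_median

    def build(hr: float) -> IllnessDeath:
        total1 = hr * total0
        return IllnessDeath(
            h_prog=trt_prog_proportion * total1,
            h_death_pre=(1.0 - trt_prog_proportion) * total1,
            h_death_post=control_ms.h_death_post,
        )

    def resid(hr: float) -> float:
        return float(build(hr).survival(m1)) - 0.5

    return build(_solve(resid))


# ---------------------------------------------------------------------------
# scenario builders: calibrated ScenarioSpec per family
# ---------------------------------------------------------------------------


def _design_kwargs(design: dict) -> dict:
    allowed = {"n", "recruitment_duration", "target_events", "censor_prop"}
    bad = set(design) - allowed
    if bad:
        raise TypeError(f"unknown design options: {sorted(bad)}")
    return design


def null_scenario(
    target: CalibrationTarget | None = None, control=None, family: str = "null", **design
) -> ScenarioSpec:
    """Both arms drawn from the control model (type-I error setting)."""
    if control is None:
        target = target or schoenfeld_target()
        control = PiecewiseHazard.exponential(target.control_rate)
    return ScenarioSpec(
        family=family, control=control, treatment=control,
        name=f"{family}:null", **_design_kwargs(design),
    )


def delayed_scenario(
    delay: float, target: CalibrationTarget | None = None, **design
) -> ScenarioSpec:
    target = target or schoenfeld_target()
    lam0 = target.control_rate
    hr = calibrate_delay(delay, target)
    control = PiecewiseHazard.exponential(lam0)
    if delay == 0.0:
        treatment = PiecewiseHazard.exponential(hr * lam0)
    else:
        treatment = PiecewiseHazard((0.0, delay), (lam0, hr * lam0))
    return ScenarioSpec(
        family="delayed", control=control, treatment=treatment,
        name=f"delayed:{delay:g}", **_design_kwargs(design),
    )


def crossing_scenario(
    crossing: float, hr_pre: float = 1.5, target: CalibrationTarget | None = None, **design
) -> ScenarioSpec:
    target = target or schoenfeld_target()
    lam0 = target.control_rate
    hr = calibrate_crossing(crossing, hr_pre, target)
    control = PiecewiseHazard.exponential(lam0)
    if crossing == 0.0:
        treatment = PiecewiseHazard.exponential(hr * lam0)
    else:
        treatment = PiecewiseHazard((0.0, crossing), (hr_pre * lam0, hr * lam0))
    return ScenarioSpec(
        family="crossing", control=control, treatment=treatment,
        name=f"crossing:{crossing:g},{hr_pre:g}", **_design_kwargs(design),
    )


def subgroup_scenario(
    prevalence: float,
    hr_pos_vs_neg: float,
    target: CalibrationTarget | None = None,
    **design,
) -> ScenarioSpec:
    target = target or schoenfeld_target()
    lam0 = target.control_rate
    hr_neg = calibrate_subgroup(prevalence, hr_pos_vs_neg, target)
    control = SubgroupMixture(
        prevalence,
        PiecewiseHazard.exponential(lam0),
        PiecewiseHazard.exponential(lam0),
    )
    treatment = SubgroupMixture(
        prevalence,
        PiecewiseHazard.exponential(hr_pos_vs_neg * hr_neg * lam0),
        PiecewiseHazard.exponential(hr_neg * lam0),
    )
    return ScenarioSpec(
        family="subgroup", control=control, treatment=treatment,
        name=f"subgroup:{prevalence:g},{hr_pos_vs_neg:g}", **_design_kwargs(design),
    )


def progression_scenario(
    trt_prog_proportion: float = 0.1,
    ctrl_prog_proportion: float = 0.2,
    post_multiplier: float = 2.0,
    null: bool = False,
    target: CalibrationTarget | None = None,
    **design,
) -> ScenarioSpec:
    """Illness-death family; ``null=True`` gives equal arms (control model)."""
    target = target or schoenfeld_target()
    control = solve_control_multistate(
        median=target.control_median,
        prog_proportion=ctrl_prog_proportion,
        post_multiplier=post_multiplier,
    )
    if null:
        treatment = control
    else:
        treatment = calibrate_progression(control, trt_prog_proportion, target)
    return ScenarioSpec(
        family="progression", control=control, treatment=treatment,
        name=(
            f"progression:{trt_prog_proportion:g},{ctrl_prog_proportion:g},"
            f"{post_multiplier:g}{',null' if null else ''}"
        ),
        **_design_kwargs(design),
    )
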