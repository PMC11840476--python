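"""Replication engine for operating characteristics and method grading.

``run_replications`` simulates a scenario ``n_reps`` times, applies a set of
methods to every replicate, and aggregates one-sided rejection rates at
alpha, confidence-interval coverage of the true estimand values, and mean
bias, each with its binomial / empirical Monte-Carlo standard error.
Per-replication seeds are spawned from the master seed with numpy's
``SeedSequence(seed, spawn_key=(rep,))`` so that adding methods never
changes the simulated data of earlier replications.

Replicates on which an estimand is undefined (median not reached, no events
before a cutoff, ...) are counted and reported separately; they enter the
rejection denominator as non-rejections and are excluded from the coverage
and bias denominators.

``grade_tests`` / ``grade_estimates`` implement the coarse star grading of
power (relative to the log-rank test or the per-scenario best method),
coverage and bias used to summarize large scenario batteries.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import np_estimates, parametric
from .scenario_sim import ScenarioSpec, simulate_trial, true_summaries
from .surv_core import (
    CountingProcess,
    TrialDataset,
    UndefinedEstimateError,
    build_counting_process,
)
from .wlrt import DEFAULT_MAXCOMBO, WeightSpec, maxcombo, weighted_logrank

__all__ = [
    "Method",
    "parse_method",
    "parse_methods",
    "OperatingCharacteristics",
    "run_replications",
    "Grade",
    "grade_tests",
    "grade_estimates",
]

logger = logging.getLogger("nphtrial")


@dataclass(frozen=True)
class Method:
    """One analysis method: a name, a kind, and a runner.

    ``kind`` is ``"test"`` (p-value only) or ``"estimate"`` (p-value plus CI
    and point estimate graded against a true value).  ``estimand`` is the
    key of the corresponding entry of :func:`true_summaries` for estimates.
    """

    name: str
    kind: str
    run: Callable[[TrialDataset, CountingProcess], object]
    estimand: Optional[str] = None


def parse_method(text: str) -> Method:
    """Build a :class:`Method` from config shorthand.

    Tests: ``logrank``, ``fh:RHO,GAMMA``, ``modest:T``, ``maxcombo``.
    Estimates: ``rmst:L``, ``milestone:T``, ``ahr:L``, ``median``,
    ``weibull_median``, ``aft:weibull``, ``aft:lognormal``, ``cox``.
    """
    text = text.strip()
    kind, _, args = text.partition(":")
    if kind in ("logrank", "fh", "modest"):
        spec = WeightSpec.parse(text)
        return Method(spec.label, "test", lambda data, cp: weighted_logrank(cp, spec))
    if kind == "maxcombo":
        specs = DEFAULT_MAXCOMBO if not args else tuple(
            WeightSpec.parse(a) for a in args.split("+")
        )
        return Method("maxcombo", "test", lambda data, cp: maxcombo(cp, specs))
    if kind == "rmst":
        L = float(args)
        return Method(
            f"rmst:{L:g}", "estimate",
            lambda data, cp: np_estimates.rmst_difference(data, L, cp=cp),
            estimand=f"rmst_diff_{L:g}",
        )
    if kind == "milestone":
        t = float(args)
        return Method(
            f"milestone:{t:g}", "estimate",
            lambda data, cp: np_estimates.milestone_difference(data, t, cp=cp),
            estimand=f"milestone_diff_{t:g}",
        )
    if kind == "ahr":
        L = float(args)
        return Method(
            f"ahr:{L:g}", "estimate",
            lambda data, cp: np_estimates.average_hazard_ratio(data, L, cp=cp),
            estimand=f"ahr_{L:g}",
        )
    if kind == "median":
        return Method(
            "median", "estimate",
            lambda data, cp: np_estimates.median_difference(data, cp=cp),
            estimand="median_diff",
        )
    if kind == "weibull_median":
        return Method(
            "weibull_median", "estimate",
            lambda data, cp: parametric.weibull_median_difference(data),
            estimand="median_diff",
        )
    if kind == "aft":
        dist = args or "weibull"
        return Method(
            f"aft:{dist}", "test",
            lambda data, cp: parametric.aft_result(data, dist),
        )
    if kind == "cox":
        return Method("cox", "test", lambda data, cp: parametric.cox_hazard_ratio(data))
    raise ValueError(f"unknown method {text!r}")


def _split_method_string(text: str) -> list[str]:
    """Split a comma-separated method list, keeping ``fh:RHO,GAMMA`` intact.

    A bare-numeric token can only be the gamma of a preceding FH spec, so it
    is merged back: ``"logrank,fh:0,1,rmst:24"`` -> [logrank, fh:0,1, rmst:24].
    """
    tokens: list[str] = []
    for raw in text.split(","):
        raw = raw.strip()
        if not raw:
            continue
        try:
            float(raw)
            is_number = True
        except ValueError:
            is_number = False
        if is_number and tokens and tokens[-1].startswith("fh:"):
            tokens[-1] += f",{raw}"
        else:
            tokens.append(raw)
    return tokens


def parse_methods(texts: Union[str, Sequence[str]]) -> list[Method]:
    if isinstance(texts, str):
        texts = _split_method_string(texts)
    return [m if isinstance(m, Method) else parse_method(m) for m in texts]


@dataclass
class OperatingCharacteristics:
    """Aggregated per-method simulation results.

    ``table`` columns: method, metric (rejection_rate / coverage / mean_bias /
    undefined_rate), value, sse, n (denominator).  ``truths`` carries the true
    estimand values used for coverage and bias.
    """

    scenario: str
    n_reps: int
    seed: int
    alpha: float
    table: pd.DataFrame
    truths: dict[str, float] = field(default_factory=dict)

    def metric(self, method: str, metric: str) -> tuple[float, float]:
        row = self.table[(self.table.method == method) & (self.table.metric == metric)]
        if row.empty:
            raise KeyError(f"no {metric} recorded for method {method!r}")
        return float(row.value.iloc[0]), float(row.sse.iloc[0])

    def rejection_rate(self, method: str) -> tuple[float, float]:
        return self.metric(method, "rejection_rate")

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "scenario", self.scenario)
        out["n_reps"] = self.n_reps
        out["seed"] = self.seed
        out.to_csv(path, index=False)


def _rate_sse(r: float, n: int) -> float:
    return float(np.sqrt(r * (1.0 - r) / n)) if n > 0 else np.nan


def run_replications(
    spec: ScenarioSpec,
    methods: Union[str, Sequence[Union[str, Method]]],
    n_reps: int,
    seed: int,
    alpha: float = 0.025,
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics of several methods on one scenario."""
    methods = parse_methods(methods)
    if not methods:
        raise ValueError("need at least one method")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    t_start = time.perf_counter()
    censoring = spec.censoring()
    need_truth = any(m.kind == "estimate" for m in methods)
    truths = true_summaries(spec) if need_truth else {}
    reject = {m.name: 0 for m in methods}
    cover = {m.name: 0 for m in methods}
    bias_sum = {m.name: 0.0 for m in methods}
    bias_sq = {m.name: 0.0 for m in methods}
    defined = {m.name: 0 for m in methods}
    for rep in range(n_reps):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(rep,))))
        data = simulate_trial(spec, rng, censoring=censoring)
        cp = build_counting_process(data)
        for m in methods:
            try:
                res = m.run(data, cp)
            except (UndefinedEstimateError, parametric.FitError) as err:
                logger.debug("rep %d, %s undefined: %s", rep, m.name, err)
                continue
            defined[m.name] += 1
            if res.p_one_sided <= alpha:
                reject[m.name] += 1
            if m.kind == "estimate" and m.estimand is not None:
                truth = truths[m.estimand]
                if res.covers(truth):
                    cover[m.name] += 1
                err_ = res.estimate - truth
                bias_sum[m.name] += err_
                bias_sq[m.name] += err_ * err_
    rows = []
    for m in methods:
        nd = defined[m.name]
        r = reject[m.name] / n_reps  # undefined replicates count as non-rejections
        rows.append((m.name, "rejection_rate", r, _rate_sse(r, n_reps), n_reps))
        undef_rate = 1.0 - nd / n_reps
        rows.append((m.name, "undefined_rate", undef_rate, _rate_sse(undef_rate, n_reps), n_reps))
        if m.kind == "estimate" and nd > 0:
            c = cover[m.name] / nd
            rows.append((m.name, "coverage", c, _rate_sse(c, nd), nd))
            mean_bias = bias_sum[m.name] / nd
            var_bias = max(bias_sq[m.name] / nd - mean_bias**2, 0.0)
            rows.append((m.name, "mean_bias", mean_bias, float(np.sqrt(var_bias / nd)), nd))
    logger.info(
        "scenario %s: %d reps x %d methods in %.1fs",
        spec.name or spec.family, n_reps, len(methods), time.perf_counter() - t_start,
    )
    return OperatingCharacteristics(
        scenario=spec.name or spec.family,
        n_reps=n_reps,
        seed=seed,
        alpha=alpha,
        table=pd.DataFrame(rows, columns=["method", "metric", "value", "sse", "n"]),
        truths=truths,
    )


@dataclass(frozen=True)
class Grade:
    """One coarse performance grade: symbol in {*, +, ~, -} plus its basis."""

    method: str
    symbol: str
    basis: str


def grade_tests(
    oc: OperatingCharacteristics, reference: str = "logrank"
) -> list[Grade]:
    """Grade per-method power against the log-rank test or the best method.

    vs log-rank: ``*`` power more than 4 SSE above log-rank, ``+`` within
    +-4 SSE, ``~`` more than 4 SSE below, ``-`` more than 8 SSE below (the
    ``-`` band takes precedence inside the ``~`` region).
    vs best: ``*`` numerically best (ties share it), ``+`` within 4 SSE of
    the best, ``~`` 4-8 SSE below, ``-`` more than 8 SSE below.
    """
    methods = list(oc.table[oc.table.metric == "rejection_rate"].method)
    power = {m: oc.rejection_rate(m) for m in methods}
    grades = []
    if reference == "logrank":
        if "logrank" not in power:
            raise ValueError("log-rank reference requires the 'logrank' method")
        p_ref, _ = power["logrank"]
        for m in methods:
            p, sse = power[m]
            if p > p_ref + 4.0 * sse:
                sym = "*"
            elif p >= p_ref - 4.0 * sse:
                sym = "+"
            elif p >= p_ref - 8.0 * sse:
                sym = "~"
            else:
                sym = "-"
            grades.append(Grade(m, sym, "vs_logrank"))
    elif reference == "best":
        best = max(p for p, _ in power.values())
        for m in methods:
            p, sse = power[m]
            if p == best:
                sym = "*"
            elif p >= best - 4.0 * sse:
                sym = "+"
            elif p >= best - 8.0 * sse:
                sym = "~"
            else:
                sym = "-"
            grades.append(Grade(m, sym, "vs_best"))
    else:
        raise ValueError("reference must be 'logrank' or 'best'")
    return grades


def grade_estimates(
    oc: OperatingCharacteristics,
    control_params: Optional[dict[str, float]] = None,
    nominal: float = 0.95,
) -> list[Grade]:
    """Grade coverage and bias of the estimate methods.

    Coverage: ``*`` within +-2.3 SSE of nominal, ``-`` below, ``+`` above
    (conservative).  Bias: for the average hazard ratio, within +-0.05 is
    good (``+``), above +0.05 is conservative (``~``), below -0.05 is
    anti-conservative (``-``); for difference estimands (median / RMST /
    milestone), bias relative to the control-arm parameter within +-5
    percentage points is good, beyond that negative (conservative) is ``~``
    and positive (anti-conservative) is ``-``.
    """
    control_params = control_params or {}
    grades = []
    cov_tab = oc.table[oc.table.metric == "coverage"]
    for _, row in cov_tab.iterrows():
        lo = nominal - 2.3 * row.sse
        hi = nominal + 2.3 * row.sse
        sym = "*" if lo <= row.value <= hi else ("-" if row.value < lo else "+")
        grades.append(Grade(row.method, sym, "coverage"))
    bias_tab = oc.table[oc.table.metric == "mean_bias"]
    for _, row in bias_tab.iterrows():
        if row.method.startswith("ahr"):
            # benefit is a ratio < 1, so positive bias is conservative
            if abs(row.value) <= 0.05:
                sym = "+"
            else:
                sym = "~" if row.value > 0 else "-"
        else:
            ref = control_params.get(row.method)
            if ref is None:
                ref = abs(oc.truths.get("median_0", np.nan))
            rel = row.value / ref
            if abs(rel) <= 0.05:
                sym = "+"
            else:
                sym = "~" if rel < 0 else "-"
        grades.append(Grade(row.method, sym, "bias"))
    return grades
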