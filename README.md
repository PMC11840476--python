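# nphtrial

Analysis and simulation of randomized two-arm time-to-event trials under
**non-proportional hazards (NPH)**.

When the hazard functions of the two arms are not proportional — delayed
onset of a treatment effect, crossing hazards, biomarker subgroups with
different responses, hazards that change after disease progression — the
standard log-rank test loses power and the Cox hazard ratio loses its
interpretation. A wide menu of alternatives exists, each testing a different
null hypothesis and estimating a different summary of the survival contrast.
`nphtrial` implements that menu on one counting-process backbone, together
with the machinery needed to compare the methods fairly by simulation:
calibrated scenario generators, an event-driven trial simulator, and an
operating-characteristics harness. It is aimed at biostatisticians planning
or reviewing trials where NPH is anticipated.

## What is implemented

With `D` the set of ordered unique event times, `Y_i(t)` the number at risk
and `dN_i(t)` the events in arm `i` at `t`, and
`Ŝ(t) = exp(−Σ_{s≤t} dN(s)/Y(s))` the Nelson–Aalen–Breslow survival
estimator:

**Hypothesis tests** (one-sided, H₀: λ₀(t) ≤ λ₁(t)):

- weighted log-rank statistics
  `z = Σ w(t)(dN₀(t) − e₀(t)) / √(Σ w(t)² v(t))` with hypergeometric
  `e₀, v`; weights from the Fleming–Harrington family
  `w(t) = Ŝ⁻(t)^ρ (1−Ŝ⁻(t))^γ` (ρ=γ=0 is the plain log-rank test);
- the modestly weighted test, `w_j = 1/max(S̃(t_{j−1}), S̃(t*))` on the
  pooled Kaplan–Meier curve `S̃`, which keeps its level under the stronger
  null `S₀(t) ≥ S₁(t)`;
- MaxCombo: the maximum of several weighted z statistics with a
  multivariate-normal multiplicity adjustment from their estimated
  correlation `Σ w_a w_b v`.

**Estimands with Wald inference** (95% CI and one-sided p):

- RMST difference `μ₁−μ₀`, `μ_i = ∫₀ᴸ S_i`, with the counting-process
  double-sum variance;
- milestone survival difference `S₁(t)−S₀(t)`;
- median difference `τ₁−τ₀`, `τ = inf{t: Ŝ(t) ≤ ½}`, variance via a
  Gaussian-kernel hazard estimate at the median;
- average hazard ratio `θ = ∫₀ᴸ W dΛ₁ / ∫₀ᴸ W dΛ₀` with the concordance
  weight `W = S₀⁻S₁⁻`, inference on the log scale;
- Weibull / lognormal AFT acceleration factors, per-arm Weibull plug-in
  medians (delta method), and the Cox hazard ratio as comparator.

**Simulation machinery**: piecewise-exponential, biomarker-mixture and
illness-death (progression) arm models; uniform recruitment; an
event-driven cutoff at the target event count (administrative censoring);
an exponential drop-out rate solved to hit a target censoring share;
Schoenfeld-formula effect calibration so every scenario family shares one
true median-survival difference; and a replication harness reporting
type-I error, power, CI coverage and bias with Monte-Carlo standard errors
plus a coarse star grading of methods.

## Worked example

```python
import numpy as np
import nphtrial as nt

spec = nt.delayed_scenario(6.0)            # effect starts at 6 months, post-delay HR 0.60
data = nt.simulate_trial(spec, np.random.default_rng(2024))
cp = nt.build_counting_process(data)

print(nt.weighted_logrank(cp, nt.WeightSpec.unit()).p_one_sided)   # 0.0120
print(nt.weighted_logrank(cp, nt.WeightSpec.fh(0, 1)).p_one_sided) # 0.0011
print(nt.maxcombo(cp).p_one_sided)                                 # 0.0027
print(nt.rmst_difference(data, 24.0).estimate)                     # 1.22 months
print(nt.average_hazard_ratio(data, 24.0).estimate)                # 0.854
```

On this simulated trial (500 subjects, cut at 375 events) the late-weighted
FH(0,1) test is far more significant (p ≈ 0.001) than the plain log-rank
test (p ≈ 0.012) because the hazards only separate after month 6; MaxCombo
sits in between, paying its multiplicity premium for robustness. The
24-month RMST difference of 1.22 months and average hazard ratio of 0.85
are the interpretable — but less powerful — summaries of the same contrast
(their true values under this scenario are 1.56 months and 0.80, obtainable
from `nt.true_summaries(spec)`).

The scripts in `examples/` walk through each layer: `calibrate_scenarios.py`
(effect calibration), `analyze_trial.py` (the full battery on one trial),
`simulator_checks.py` (samplers vs closed forms), and
`operating_characteristics.py` (a desk-scale replication study with
grading). A thin CLI wraps the same layers:

```sh
nphtrial calibrate --family delayed --delay 6 --out scenario.yaml
nphtrial simulate --config scenario.yaml --reps 2500 --seed 42 \
    --methods "logrank,fh:0,1,maxcombo,rmst:24" --out results.csv
nphtrial analyze --data trial.csv --methods "logrank,ahr:24" --out estimates.csv
nphtrial grade --results results.csv --out grades.csv
```

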