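"""Likelihood-based comparators: AFT regression, per-arm Weibull medians, Cox PH.

The accelerated failure time model is log T = mu + theta * x + sigma * W with
x the treatment indicator; exp(theta) is the acceleration factor (> 1
favorable).  W is standard normal (lognormal model) or standard minimum
extreme value (Weibull model).  Fitting is by maximum likelihood with right
censoring via lifelines; standard errors are model-based (inverse Hessian).

The per-arm Weibull fit yields a plug-in median scale * log(2)^(1/shape)
whose variance follows by the delta method from the (shape, scale)
covariance.  The Cox model (Breslow ties, statsmodels) is provided purely as
a comparator; its Wald test is asymptotically equivalent to the log-rank
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .np_estimates import EstimateResult, _Z95, _difference_result
from .surv_core import TrialDataset, UndefinedEstimateError

__all__ = [
    "FitError",
    "AFTFit",
    "WeibullGroupFit",
    "fit_aft",
    "aft_result",
    "weibull_median_difference",
    "cox_hazard_ratio",
]


class FitError(RuntimeError):
    """Maximum-likelihood fit did not converge; carries optimizer context."""


@dataclass
class AFTFit:
    """Fitted AFT model on (mu, theta, log sigma) with model-based covariance."""

    distribution: str
    mu: float
    theta: float
    sigma: float
    cov: np.ndarray  # covariance of (mu, theta, log sigma)
    log_likelihood: float

    @property
    def se_theta(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    @property
    def acceleration_factor(self) -> float:
        return float(np.exp(self.theta))

    @property
    def p_one_sided(self) -> float:
        """Wald p for the benefit hypothesis; small when theta >> 0."""
        return float(norm.sf(self.theta / self.se_theta))

    @property
    def implied_hazard_ratio(self) -> float:
        """exp(-theta/sigma); equals the PH hazard ratio for the Weibull model."""
        return float(np.exp(-self.theta / self.sigma))


def _check_events(data: TrialDataset, minimum: int = 2) -> None:
    for arm in (0, 1):
        if np.sum(data.event & (data.arm == arm)) < minimum:
            raise UndefinedEstimateError(f"need >= {minimum} events in arm {arm}")


def fit_aft(data: TrialDataset, distribution: str = "weibull") -> AFTFit:
    """Fit a Weibull or lognormal AFT model with a treatment-arm covariate."""
    from lifelines import LogNormalAFTFitter, WeibullAFTFitter
    from lifelines.exceptions import ConvergenceError

    if distribution not in ("weibull", "lognormal"):
        raise ValueError(f"distribution must be 'weibull' or 'lognormal', got {distribution!r}")
    _check_events(data)
    df = data.to_dataframe()[["obs_time", "event", "arm"]].astype(float)
    fitter = WeibullAFTFitter() if distribution == "weibull" else LogNormalAFTFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="obs_time", event_col="event")
    except ConvergenceError as err:  # pragma: no cover - exercised only on pathological data
        raise FitError(f"{distribution} AFT fit did not converge: {err}") from err
    # lifelines parameterizes the location as X*beta and the ancillary
    # parameter on the log scale: for Weibull log(lambda) = mu + theta*x and
    # log(rho) = -log(sigma); for lognormal mu_ = mu + theta*x, log(sigma_).
    loc = "lambda_" if distribution == "weibull" else "mu_"
    anc = "rho_" if distribution == "weibull" else "sigma_"
    params = fitter.params_
    mu = float(params[(loc, "Intercept")])
    theta = float(params[(loc, "arm")])
    log_anc = float(params[(anc, "Intercept")])
    sigma = float(np.exp(-log_anc)) if distribution == "weibull" else float(np.exp(log_anc))
    order = [(loc, "Intercept"), (loc, "arm"), (anc, "Intercept")]
    cov = fitter.variance_matrix_.loc[order, order].to_numpy()
    if distribution == "weibull":  # log sigma = -log rho: flip the cross-covariances
        J = np.diag([1.0, 1.0, -1.0])
        cov = J @ cov @ J
    return AFTFit(
        distribution=distribution, mu=mu, theta=theta, sigma=sigma,
        cov=cov, log_likelihood=float(fitter.log_likelihood_),
    )


def aft_result(data: TrialDataset, distribution: str = "weibull") -> EstimateResult:
    """Acceleration factor exp(theta) with Wald CI, as a tidy result row."""
    fit = fit_aft(data, distribution)
    af = fit.acceleration_factor
    se = fit.se_theta
    return EstimateResult(
        name=f"aft_{distribution}", estimate=af, se=af * se,
        ci_low=float(np.exp(fit.theta - _Z95 * se)),
        ci_high=float(np.exp(fit.theta + _Z95 * se)),
        p_one_sided=fit.p_one_sided, log_se=se,
    )


@dataclass
class WeibullGroupFit:
    """Per-arm Weibull fit with the delta-method median variance."""

    shape: float
    scale: float
    cov_log: np.ndarray  # covariance of (log scale, log shape)

    @property
    def median(self) -> float:
        return float(self.scale * np.log(2.0) ** (1.0 / self.shape))

    @property
    def median_variance(self) -> float:
        # d median / d log scale = median;
        # d median / d log shape = -median * log(log 2) / shape
        grad = np.array([self.median, -self.median * np.log(np.log(2.0)) / self.shape])
        return float(grad @ self.cov_log @ grad)


def _fit_weibull_arm(data: TrialDataset, arm: int) -> WeibullGroupFit:
    from lifelines import WeibullFitter
    from lifelines.exceptions import ConvergenceError

    sel = data.arm == arm
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wf = WeibullFitter().fit(data.obs_time[sel], data.event[sel].astype(int))
    except ConvergenceError as err:  # pragma: no cover
        raise FitError(f"Weibull fit did not converge in arm {arm}: {err}") from err
    scale, shape = float(wf.lambda_), float(wf.rho_)
    cov_nat = wf.variance_matrix_.loc[["lambda_", "rho_"], ["lambda_", "rho_"]].to_numpy()
    J = np.diag([1.0 / scale, 1.0 / shape])
    return WeibullGroupFit(shape=shape, scale=scale, cov_log=J @ cov_nat @ J)


def weibull_median_difference(data: TrialDataset) -> EstimateResult:
    """Median difference from separate per-arm Weibull fits (delta-method se)."""
    _check_events(data)
    fit0 = _fit_weibull_arm(data, 0)
    fit1 = _fit_weibull_arm(data, 1)
    res = _difference_result(
        "weibull_median", fit0.median, fit0.median_variance,
        fit1.median, fit1.median_variance,
    )
    return res


def cox_hazard_ratio(data: TrialDataset) -> EstimateResult:
    """Cox partial-likelihood hazard ratio (Breslow ties), Wald inference.

    Benefit is HR < 1; one-sided p = P(Z < beta-hat / se).
    """
    import statsmodels.api as sm

    if data.n_events == 0:
        raise UndefinedEstimateError("no events: Cox model undefined")
    for arm in (0, 1):
        if np.sum(data.event & (data.arm == arm)) == 0:
            raise UndefinedEstimateError(
                f"no events in arm {arm}: monotone partial likelihood"
            )
    model = sm.PHReg(
        data.obs_time, data.arm.astype(float)[:, None],
        status=data.event.astype(int), ties="breslow",
    )
    fit = model.fit(disp=False)
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    return EstimateResult(
        name="cox", estimate=float(np.exp(beta)), se=float(np.exp(beta)) * se,
        ci_low=float(np.exp(beta - _Z95 * se)), ci_high=float(np.exp(beta + _Z95 * se)),
        p_one_sided=float(norm.cdf(beta / se)), log_se=se,
    )
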