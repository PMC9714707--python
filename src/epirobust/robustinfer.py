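"""Inference engines for the slope of a predictive regression.

Two routes to a t-test on beta in ``y_t = alpha + beta x_{t-1} + eps_t``:

* HAC: kernel (quadratic spectral) long-run variance of the regression
  scores with Andrews' AR(1) plug-in automatic bandwidth; p-values from the
  standard normal.
* Group t-statistic: split the sample into q consecutive blocks, estimate
  the slope within each block (with its own intercept), and t-test the q
  block estimates against Student-t with q-1 degrees of freedom.  The group
  test remains valid under heterogeneous group variances for two-sided
  levels up to 8.3%, and contains the Fama–MacBeth procedure as the special
  case of calendar-defined groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "RegressionData",
    "OLSFit",
    "HACResult",
    "GroupInference",
    "ols_fit",
    "qs_weight",
    "andrews_bandwidth",
    "hac_ttest",
    "partition_groups",
    "group_tstat_test",
    "group_tstat_from_estimates",
    "group_null_rejection_rate",
    "GROUP_LEVEL_BOUND",
]

#: Largest two-sided level at which the group t-test is valid under
#: arbitrary group-variance heterogeneity.
GROUP_LEVEL_BOUND = 0.083


@dataclass
class RegressionData:
    """Aligned response and scalar lagged regressor."""

    y: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y.shape != self.x.shape or self.y.ndim != 1:
            raise InvalidParameterError("y and x must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.x))):
            raise InvalidParameterError("y and x must be finite")

    @property
    def T(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class OLSFit:
    alpha: float
    beta: float
    residuals: np.ndarray


@dataclass(frozen=True)
class HACResult:
    beta: float
    se: float
    tstat: float
    pvalue: float
    bandwidth: float
    kernel: str = "qs"


@dataclass(frozen=True)
class GroupInference:
    q: int
    estimates: np.ndarray
    mean: float
    sd: float
    tstat: float
    pvalue: float
    level: float
    ci: tuple
    level_valid: bool
    degenerate: bool = False


def ols_fit(data: RegressionData) -> OLSFit:
    """Least-squares fit of y on (1, x)."""
    if data.T < 3:
        raise InsufficientDataError("need at least 3 observations")
    x, y = data.x, data.y
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateDesignError("regressor is constant")
    beta = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    alpha = float(y.mean() - beta * x.mean())
    resid = y - alpha - beta * x
    return OLSFit(alpha=alpha, beta=beta, residuals=resid)


def qs_weight(z):
    """Quadratic spectral kernel k(z); k(0) = 1 by continuity."""
    z = np.asarray(z, dtype=float)
    out = np.ones_like(z)
    nz = z != 0
    d = 6.0 * np.pi * z[nz] / 5.0
    out[nz] = 25.0 / (12.0 * np.pi**2 * z[nz] ** 2) * (np.sin(d) / d - np.cos(d))
    if out.ndim == 0:
        return float(out)
    return out


def _autocovariances(v: np.ndarray) -> np.ndarray:
    """Biased (divisor T) autocovariances of a demeaned copy of v, lags 0..T-1."""
    vc = v - v.mean()
    T = len(vc)
    return np.correlate(vc, vc, mode="full")[T - 1 :] / T


def andrews_bandwidth(v) -> float:
    """AR(1) plug-in automatic bandwidth for the QS kernel.

    rho_hat is the lag-1 autocorrelation of the score series; the bandwidth is
    S_T = 1.3221 * (alpha2 * T)^(1/5) with alpha2 = 4 rho^2 / (1 - rho)^4.
    """
    v = np.asarray(v, dtype=float)
    T = len(v)
    if T < 4:
        raise InvalidParameterError("need at least 4 observations")
    gamma = _autocovariances(v)
    if gamma[0] == 0:
        raise DegenerateDesignError("score series is constant")
    rho = float(gamma[1] / gamma[0])
    cap = 1.0 - 1e-6
    if abs(rho) >= cap:
        warnings.warn("plug-in AR(1) coefficient capped near unity", RuntimeWarning)
        rho = np.sign(rho) * cap
    alpha2 = 4.0 * rho**2 / (1.0 - rho) ** 4
    return float(1.3221 * (alpha2 * T) ** 0.2)


def hac_lrv(v: np.ndarray, bandwidth: float) -> float:
    """QS-kernel long-run variance of a score series at the given bandwidth."""
    gamma = _autocovariances(np.asarray(v, dtype=float))
    if bandwidth <= 0:
        return float(gamma[0])
    lags = np.arange(1, len(gamma))
    w = qs_weight(lags / bandwidth)
    return float(gamma[0] + 2.0 * np.sum(w * gamma[1:]))


def hac_ttest(data: RegressionData, bandwidth: float | None = None) -> HACResult:
    """HAC t-test on the slope with QS kernel and automatic bandwidth.

    Scores are v_t = (x_t - xbar) * resid_t; the slope variance is the
    sandwich T * LRV(v) / Sxx^2.
    """
    fit = ols_fit(data)
    x = data.x
    v = (x - x.mean()) * fit.residuals
    if bandwidth is None:
        bandwidth = andrews_bandwidth(v)
    lrv = hac_lrv(v, bandwidth)
    if lrv <= 0:
        raise DegenerateDesignError(
            f"non-positive long-run variance ({lrv:g}) at bandwidth {bandwidth:g}"
        )
    sxx = float(np.sum((x - x.mean()) ** 2))
    se = float(np.sqrt(data.T * lrv) / sxx)
    t = fit.beta / se
    p = float(2.0 * stats.norm.sf(abs(t)))
    return HACResult(beta=fit.beta, se=se, tstat=t, pvalue=p, bandwidth=bandwidth)


def partition_groups(T: int, q: int) -> list[tuple[int, int]]:
    """Consecutive-block partition: group j = {t : (j-1)T/q < t <= jT/q}.

    Returns 0-based half-open index ranges; group sizes differ by at most 1.
    Requires every group to be non-empty; the stricter T >= 3q sample-size
    requirement is enforced by the group t-test itself.
    """
    if q < 2:
        raise InvalidParameterError("q must be at least 2")
    if T < q:
        raise InsufficientDataError(f"T = {T} < q = {q}: empty groups")
    bounds = [int(np.floor(j * T / q)) for j in range(q + 1)]
    return [(bounds[j], bounds[j + 1]) for j in range(q)]


def group_tstat_from_estimates(estimates, level: float = 0.05) -> GroupInference:
    """Group t-statistic inference from precomputed group estimates.

    t_beta = sqrt(q) * mean / SD, compared with Student-t(q-1); the two-sided
    test is heterogeneity-robust only for levels up to 8.3%, recorded in
    ``level_valid``.
    """
    b = np.asarray(estimates, dtype=float)
    q = len(b)
    if q < 2:
        raise InvalidParameterError("need at least 2 group estimates")
    if not (0 < level < 1):
        raise InvalidParameterError("level must be in (0, 1)")
    mean = float(b.mean())
    sd = float(b.std(ddof=1))
    degenerate = False
    if sd == 0:
        degenerate = True
        if mean == 0:
            t, p = np.nan, np.nan
        else:
            t, p = np.sign(mean) * np.inf, 0.0
    else:
        t = float(np.sqrt(q) * mean / sd)
        p = float(2.0 * stats.t.sf(abs(t), df=q - 1))
    crit = stats.t.ppf(1.0 - level / 2.0, df=q - 1)
    half = crit * sd / np.sqrt(q)
    return GroupInference(
        q=q,
        estimates=b,
        mean=mean,
        sd=sd,
        tstat=t,
        pvalue=p,
        level=level,
        ci=(mean - half, mean + half),
        level_valid=level <= GROUP_LEVEL_BOUND,
        degenerate=degenerate,
    )


def group_tstat_test(data: RegressionData, q: int, level: float = 0.05) -> GroupInference:
    """Slope inference from q consecutive-block OLS estimates.

    Each block regression includes its own intercept.  A block with constant
    regressor raises a degenerate-design error naming the block.
    """
    if data.T < 3 * q:
        raise InsufficientDataError(f"T = {data.T} < 3q = {3 * q}")
    ranges = partition_groups(data.T, q)
    betas = np.empty(q)
    for j, (lo, hi) in enumerate(ranges):
        try:
            betas[j] = ols_fit(RegressionData(data.y[lo:hi], data.x[lo:hi])).beta
        except DegenerateDesignError as exc:
            raise DegenerateDesignError(f"group {j + 1} of {q}: {exc}") from exc
    return group_tstat_from_estimates(betas, level=level)


def group_null_rejection_rate(
    group_sds,
    n_reps: int = 10_000,
    level: float = 0.05,
    seed=None,
) -> float:
    """Empirical null rejection rate of the two-sided group t-test.

    Simulates ``n_reps`` draws of q independent zero-mean Gaussian group
    estimates with the given standard deviations and reports the fraction of
    replications where |t_beta| exceeds the Student-t(q-1) critical value at
    the given two-sided level.  Used to study the test's validity under
    group-variance heterogeneity.
    """
    sds = np.asarray(group_sds, dtype=float)
    q = len(sds)
    if q < 2:
        raise InvalidParameterError("need at least 2 groups")
    if np.any(sds <= 0):
        raise InvalidParameterError("group standard deviations must be positive")
    rng = np.random.default_rng(seed)
    b = rng.standard_normal((n_reps, q)) * sds
    mean = b.mean(axis=1)
    sd = b.std(axis=1, ddof=1)
    t = np.sqrt(q) * mean / sd
    crit = stats.t.ppf(1.0 - level / 2.0, df=q - 1)
    return float(np.mean(np.abs(t) > crit))
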