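"""Power-law tail-index estimation for positive daily changes.

Two estimators of the tail index zeta in ``P(X > x) ~ C x^(-zeta)``:

* the Hill estimator — the reciprocal mean log-excess of the k largest
  order statistics over the (k+1)-th, the MLE under an exact Pareto tail;
* the log-log rank-size regression with the small-sample bias-correcting
  shift of 1/2 in ranks, ``log(Rank - 1/2) = a - b log(Size)``, whose correct
  asymptotic standard error is ``sqrt(2/k) * zeta`` (not the OLS one).

Smaller zeta means heavier tails: the p-th moment is finite iff zeta > p, so
confidence intervals dipping below 2 (below 1) flag possibly infinite
variances (first moments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateSeriesError, InsufficientDataError, InvalidParameterError

__all__ = [
    "TailIndexEstimate",
    "TailCurve",
    "positive_changes",
    "hill_estimate",
    "rank_size_estimate",
    "tail_curve",
]

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class TailIndexEstimate:
    zeta: float
    se: float
    ci95: tuple
    k: int
    n: int
    method: str


@dataclass
class TailCurve:
    """Tail-index estimates over a grid of truncation levels k."""

    ks: np.ndarray
    fracs: np.ndarray
    estimates: list
    method: str

    @property
    def any_ci_low_below_2(self) -> bool:
        return bool(any(e.ci95[0] < 2.0 for e in self.estimates))

    @property
    def any_ci_low_below_1(self) -> bool:
        return bool(any(e.ci95[0] < 1.0 for e in self.estimates))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                "frac": self.fracs,
                "zeta": [e.zeta for e in self.estimates],
                "se": [e.se for e in self.estimates],
                "lo": [e.ci95[0] for e in self.estimates],
                "hi": [e.ci95[1] for e in self.estimates],
            }
        )


def positive_changes(x, min_count: int = 20) -> np.ndarray:
    """Strictly positive values of a series of daily changes, order preserved."""
    x = np.asarray(x, dtype=float)
    out = x[x > 0]
    if len(out) < min_count:
        raise InsufficientDataError(
            f"only {len(out)} positive values; need at least {min_count}"
        )
    return out


def hill_estimate(x, k: int) -> TailIndexEstimate:
    """Hill estimator from the k largest order statistics.

    zeta_hat = 1 / mean(log(X_(i) / X_(k+1)), i = 1..k), SE = zeta_hat/sqrt(k).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if k < 1 or k + 1 > n:
        raise InvalidParameterError("need 1 <= k <= n - 1")
    xs = np.sort(x)[::-1]
    threshold = xs[k]
    if threshold <= 0:
        raise InvalidParameterError("the (k+1)-th order statistic must be positive")
    mean_log = float(np.mean(np.log(xs[:k] / threshold)))
    if mean_log <= 0:
        raise DegenerateSeriesError("top-k values equal the threshold; Hill undefined")
    zeta = 1.0 / mean_log
    se = zeta / np.sqrt(k)
    return TailIndexEstimate(
        zeta=zeta, se=se, ci95=(zeta - Z95 * se, zeta + Z95 * se), k=k, n=n, method="hill"
    )


def rank_size_estimate(x, k: int, shift: float = 0.5) -> TailIndexEstimate:
    """Log-log rank-size regression with shifted ranks over the top k sizes.

    Fits ``log(r - shift) = a - b log(X_(r))`` for r = 1..k by least squares;
    the slope b estimates zeta.  The reported standard error is the
    asymptotically correct ``sqrt(2/k) * zeta_hat``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if k < 2 or k > n:
        raise InvalidParameterError("need 2 <= k <= n")
    ranks = np.arange(1, k + 1, dtype=float)
    if shift >= 1.0:
        raise InvalidParameterError("rank shift must keep Rank - shift positive")
    sizes = np.sort(x)[::-1][:k]
    if sizes[-1] <= 0:
        raise InvalidParameterError("top-k sizes must be strictly positive")
    log_size = np.log(sizes)
    if np.ptp(log_size) == 0:
        raise DegenerateSeriesError("all top-k sizes equal; rank-size design degenerate")
    log_rank = np.log(ranks - shift)
    # slope of log_rank on log_size; model log(Rank - shift) = a - b log(Size)
    b = -float(np.polyfit(log_size, log_rank, 1)[0])
    se = float(np.sqrt(2.0 / k) * b)
    return TailIndexEstimate(
        zeta=b, se=se, ci95=(b - Z95 * se, b + Z95 * se), k=k, n=n, method="rank_size"
    )


def tail_curve(
    x,
    method: str = "hill",
    fraction_range: tuple = (0.025, 0.15),
    n_grid: int = 20,
) -> TailCurve:
    """Evaluate the chosen estimator over an evenly spaced grid of k values.

    The grid spans ``fraction_range`` of the sample size (the conventional
    2.5–15% truncation window).  The curve records, for each k, the point
    estimate with its 95% interval; moment-finiteness diagnostics
    (any CI lower bound below 2 or below 1) are exposed as properties.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    lo, hi = fraction_range
    if not (0 < lo < hi <= 1):
        raise InvalidParameterError("fraction range must satisfy 0 < lo < hi <= 1")
    k_lo = int(np.floor(lo * n))
    k_hi = int(np.floor(hi * n))
    if method == "hill":
        k_hi = min(k_hi, n - 1)
    else:
        k_hi = min(k_hi, n)
    if k_lo < 2:
        raise InvalidParameterError(f"smallest grid k = {k_lo} < 2; sample too small")
    ks = np.unique(np.round(np.linspace(k_lo, k_hi, n_grid)).astype(int))
    if method == "hill":
        est = [hill_estimate(x, int(k)) for k in ks]
    elif method == "rank_size":
        est = [rank_size_estimate(x, int(k)) for k in ks]
    else:
        raise InvalidParameterError("method must be 'hill' or 'rank_size'")
    return TailCurve(ks=ks, fracs=ks / n, estimates=est, method=method)
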