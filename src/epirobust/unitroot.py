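"""GLS-detrended unit-root test battery with sieve wild-bootstrap p-values.

Implements the modified Phillips–Perron statistics (MZ_alpha, MSB, MZ_t), the
modified point-optimal statistic MP_t, and the GLS-detrended augmented
Dickey–Fuller t-ratio (ADF-GLS), with ADF lag length chosen by the modified
Akaike information criterion (MAIC).  All five statistics reject the unit
root for small values.

Because epidemic count series are heavy tailed and heteroskedastic, p-values
are computed by a sieve wild bootstrap: a sieve AR is fitted to the first
differences, the residuals are multiplied by i.i.d. Rademacher signs,
recoloured through the fitted AR, and re-cumulated with the unit root
imposed; the whole test battery is recomputed on each bootstrap path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .exceptions import DegenerateSeriesError, InvalidParameterError

__all__ = [
    "DetrendSpec",
    "MStatistics",
    "UnitRootReport",
    "gls_detrend",
    "select_lag_maic",
    "m_tests",
    "sieve_wild_bootstrap_p",
    "unit_root_report",
    "default_p_max",
]

STAT_NAMES = ("MZa", "MSB", "MZt", "MPt", "ADF")


@dataclass(frozen=True)
class DetrendSpec:
    """Deterministic component and GLS quasi-differencing constant.

    ``deterministic`` is ``"c"`` (constant) or ``"ct"`` (constant + linear
    trend).  ``cbar`` is the local-to-unity non-centrality used for GLS
    detrending; the conventional values are -7.0 (constant) and -13.5
    (trend), giving quasi-differencing parameter ``abar = 1 + cbar/T``.
    """

    deterministic: str = "c"
    cbar: float | None = None

    def __post_init__(self) -> None:
        if self.deterministic not in ("c", "ct"):
            raise InvalidParameterError("deterministic must be 'c' or 'ct'")
        if self.cbar is None:
            object.__setattr__(self, "cbar", -7.0 if self.deterministic == "c" else -13.5)
        if self.cbar >= 0:
            raise InvalidParameterError("cbar must be negative")

    def abar(self, T: int) -> float:
        return 1.0 + self.cbar / T

    def z_matrix(self, T: int) -> np.ndarray:
        t = np.arange(1, T + 1, dtype=float)
        if self.deterministic == "c":
            return np.ones((T, 1))
        return np.column_stack([np.ones(T), t])


@dataclass(frozen=True)
class MStatistics:
    """The five unit-root statistics plus the AR spectral variance."""

    MZa: float
    MSB: float
    MZt: float
    MPt: float
    ADF: float
    s2_ar: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in STAT_NAMES}


@dataclass
class UnitRootReport:
    """Full record of one unit-root analysis."""

    statistics: dict
    pvalues: dict
    lag: int
    s2_ar: float
    B: int
    seed: object
    spec: DetrendSpec
    T: int
    n_trimmed: int = 0

    def to_rows(self) -> list[dict]:
        return [
            {"statistic": k, "value": self.statistics[k], "pvalue": self.pvalues[k]}
            for k in STAT_NAMES
        ]


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def _quasi_diff(v: np.ndarray, abar: float) -> np.ndarray:
    out = np.empty(len(v))
    out[0] = v[0]
    out[1:] = v[1:] - abar * v[:-1]
    return out


def gls_detrend(y, spec: DetrendSpec = DetrendSpec()):
    """GLS (quasi-difference) detrending.

    Regresses the quasi-differenced series on the quasi-differenced
    deterministics and removes the fitted deterministic component from the
    original series.  Returns ``(ytilde, delta_hat)``.
    """
    y = np.asarray(y, dtype=float)
    T = len(y)
    if T < 5:
        raise InvalidParameterError("need at least 5 observations")
    if not np.all(np.isfinite(y)):
        raise InvalidParameterError("series must be finite")
    abar = spec.abar(T)
    z = spec.z_matrix(T)
    ya = _quasi_diff(y, abar)
    za = np.column_stack([_quasi_diff(z[:, j], abar) for j in range(z.shape[1])])
    delta, *_ = np.linalg.lstsq(za, ya, rcond=None)
    ytilde = y - z @ delta
    if np.allclose(ytilde, 0.0, atol=1e-12 * max(1.0, np.abs(y).max())):
        raise DegenerateSeriesError("series is deterministic; nothing left after detrending")
    return ytilde, delta


@dataclass(frozen=True)
class _ADFFit:
    coef: np.ndarray  # (b0, b1..bp)
    sigma2: float  # residual variance, dof-adjusted
    t_b0: float
    nobs: int


def _adf_regression(y: np.ndarray, p: int) -> _ADFFit:
    """ADF regression without deterministics on sample t = p+2..T.

    dy_t = b0 * y_{t-1} + sum_{j=1..p} b_j * dy_{t-j} + e_t
    """
    dy = np.diff(y)
    Y = dy[p:]
    n = len(Y)
    if n <= p + 1:
        raise InvalidParameterError("lag order too large for series length")
    X = np.empty((n, p + 1))
    X[:, 0] = y[p:-1]
    for j in range(1, p + 1):
        X[:, j] = dy[p - j : len(dy) - j]
    xtx = X.T @ X
    try:
        coef = np.linalg.solve(xtx, X.T @ Y)
        e0 = np.zeros(p + 1)
        e0[0] = 1.0
        xtx_inv00 = np.linalg.solve(xtx, e0)[0]
    except np.linalg.LinAlgError as exc:
        raise DegenerateSeriesError("singular ADF design") from exc
    resid = Y - X @ coef
    dof = n - (p + 1)
    sigma2 = float(resid @ resid) / dof
    if sigma2 <= 0 or not np.isfinite(sigma2):
        raise DegenerateSeriesError("non-positive residual variance in ADF regression")
    t_b0 = float(coef[0] / np.sqrt(sigma2 * xtx_inv00))
    return _ADFFit(coef=coef, sigma2=sigma2, t_b0=t_b0, nobs=n)


def default_p_max(T: int) -> int:
    """Schwert-style default maximum ADF lag."""
    return int(np.floor(12.0 * (T / 100.0) ** 0.25))


def select_lag_maic(y, spec: DetrendSpec = DetrendSpec(), p_max: int | None = None) -> int:
    """Choose the ADF lag by the modified AIC on a common estimation sample.

    The series is first OLS-detrended by the deterministics of ``spec``
    (standard ADF detrending); every candidate lag p in 0..p_max is then fit
    on the common sample t = p_max+2..T and

        MAIC(p) = ln(sigma2_p) + 2 (tau(p) + p) / (T - p_max),
        tau(p)  = b0_hat^2 * sum(y_{t-1}^2) / sigma2_p,

    with sigma2_p the residual variance on the common sample.  The smallest
    minimiser is returned.
    """
    y = np.asarray(y, dtype=float)
    T = len(y)
    if p_max is None:
        p_max = default_p_max(T)
    if p_max < 0 or p_max >= (T - 1) / 2:
        raise InvalidParameterError("p_max must satisfy 0 <= p_max < (T-1)/2")
    z = spec.z_matrix(T)
    delta, *_ = np.linalg.lstsq(z, y, rcond=None)
    yd = y - z @ delta
    dy = np.diff(yd)
    Y = dy[p_max:]
    n = len(Y)
    ylag = yd[p_max:-1]
    sum_ylag2 = float(ylag @ ylag)
    # all candidate designs are nested: columns [y_{t-1}, dy_{t-1}, ..., dy_{t-p_max}]
    X = np.empty((n, p_max + 1))
    X[:, 0] = ylag
    for j in range(1, p_max + 1):
        X[:, j] = dy[p_max - j : len(dy) - j]
    G = X.T @ X
    g = X.T @ Y
    yy = float(Y @ Y)
    best_p, best_val = 0, np.inf
    for p in range(p_max + 1):
        k = p + 1
        try:
            coef = np.linalg.solve(G[:k, :k], g[:k])
        except np.linalg.LinAlgError as exc:
            raise DegenerateSeriesError("singular MAIC design") from exc
        sigma2 = (yy - float(coef @ g[:k])) / n
        if sigma2 <= 0:
            raise DegenerateSeriesError("zero residual variance in MAIC regression")
        tau = coef[0] ** 2 * sum_ylag2 / sigma2
        val = np.log(sigma2) + 2.0 * (tau + p) / (T - p_max)
        if val < best_val - 1e-14:
            best_p, best_val = p, val
    return best_p


def m_tests(ytilde, p: int, spec: DetrendSpec = DetrendSpec()) -> MStatistics:
    """Compute the five unit-root statistics from a GLS-detrended series.

    The long-run (AR spectral, frequency-zero) variance is
    ``s2_ar = sigma2_p / (1 - sum_j b_j)**2`` from the lag-p ADF regression on
    the detrended series.
    """
    yt = np.asarray(ytilde, dtype=float)
    T = len(yt)
    kappa = float(yt[:-1] @ yt[:-1]) / T**2
    if kappa == 0:
        raise DegenerateSeriesError("zero sum of squares; degenerate series")
    fit = _adf_regression(yt, p)
    denom = 1.0 - float(fit.coef[1:].sum())
    s2_ar = fit.sigma2 / denom**2
    if s2_ar <= 0 or not np.isfinite(s2_ar):
        raise DegenerateSeriesError("non-positive AR spectral variance")
    yT2 = yt[-1] ** 2 / T
    mza = (yT2 - s2_ar) / (2.0 * kappa)
    msb = float(np.sqrt(kappa / s2_ar))
    mzt = mza * msb
    c = spec.cbar
    if spec.deterministic == "c":
        mpt = (c * c * kappa - c * yT2) / s2_ar
    else:
        mpt = (c * c * kappa + (1.0 - c) * yT2) / s2_ar
    return MStatistics(MZa=mza, MSB=msb, MZt=mzt, MPt=mpt, ADF=fit.t_b0, s2_ar=s2_ar)


def _sieve_fit(y: np.ndarray, p: int, spec: DetrendSpec):
    """Fit the sieve AR(p) to the first differences; return (psi, residuals).

    Under the unit-root null the first differences are stationary; a constant
    in the levels contributes nothing to the differences, a linear trend
    contributes a constant mean, so differences are demeaned only in the
    trend case.
    """
    u = np.diff(np.asarray(y, dtype=float))
    if spec.deterministic == "ct":
        u = u - u.mean()
    if p == 0:
        return np.empty(0), u
    Y = u[p:]
    X = np.column_stack([u[p - j : len(u) - j] for j in range(1, p + 1)])
    psi, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ psi
    return psi, resid


def sieve_wild_bootstrap_p(
    y,
    observed: dict,
    p: int,
    spec: DetrendSpec = DetrendSpec(),
    B: int = 999,
    seed=None,
    reselect_lag: bool = True,
    p_max: int | None = None,
) -> dict:
    """Sieve wild bootstrap p-values for all five statistics.

    Residuals of the sieve AR(p) fitted to the first differences are
    multiplied by i.i.d. Rademacher signs, recoloured through the fitted AR
    with zero initial conditions, and cumulated so the unit root is imposed;
    the statistics are recomputed on each bootstrap path with the same
    detrending spec.  With ``reselect_lag`` (the default) the MAIC lag choice
    is repeated on every bootstrap path, so the bootstrap distribution
    reflects the whole procedure including lag selection; otherwise the
    data-selected lag ``p`` is held fixed.  All statistics are left tailed,
    so ``p = (1 + #{stat* <= stat}) / (B + 1)``.
    """
    if B < 1:
        raise InvalidParameterError("B must be at least 1")
    psi, eps = _sieve_fit(np.asarray(y, dtype=float), p, spec)
    if not np.all(np.isfinite(eps)):
        raise InvalidParameterError("non-finite sieve residuals")
    rng = np.random.default_rng(seed)
    a_poly = np.concatenate([[1.0], -psi]) if len(psi) else np.array([1.0])
    counts = {k: 0 for k in STAT_NAMES}
    n = len(eps)
    for _ in range(B):
        w = rng.integers(0, 2, size=n) * 2 - 1
        eps_star = w * eps
        dy_star = lfilter([1.0], a_poly, eps_star)
        y_star = np.concatenate([[0.0], np.cumsum(dy_star)])
        p_star = select_lag_maic(y_star, spec, p_max) if reselect_lag else p
        yt_star, _ = gls_detrend(y_star, spec)
        st = m_tests(yt_star, p_star, spec).as_dict()
        for k in STAT_NAMES:
            if st[k] <= observed[k]:
                counts[k] += 1
    return {k: (1 + counts[k]) / (B + 1) for k in STAT_NAMES}


def trim_leading_nonpositive(y: np.ndarray) -> tuple[np.ndarray, int]:
    """Restrict to the sample starting at the first strictly positive value."""
    y = np.asarray(y, dtype=float)
    pos = np.nonzero(y > 0)[0]
    if len(pos) == 0:
        raise DegenerateSeriesError("series has no positive values")
    return y[pos[0] :], int(pos[0])


def unit_root_report(
    y,
    det: str = "c",
    cbar: float | None = None,
    p_max: int | None = None,
    B: int = 999,
    seed=None,
    trim_zeros: bool = True,
    lag: int | None = None,
    reselect_lag: bool = True,
) -> UnitRootReport:
    """Run the full battery on one series and return a consolidated report.

    With ``trim_zeros`` (the default) the analysis is restricted to the
    sample starting at the first strictly positive observation, matching the
    convention of analysing epidemic series only over their active period.
    The MAIC lag selection is repeated on every bootstrap path unless
    ``reselect_lag=False`` (or a user-fixed ``lag`` is given), in which case
    the lag is held fixed inside the bootstrap.
    """
    y = np.asarray(y, dtype=float)
    n_trimmed = 0
    if trim_zeros:
        y, n_trimmed = trim_leading_nonpositive(y)
    spec = DetrendSpec(det, cbar)
    if lag is None:
        lag = select_lag_maic(y, spec, p_max)
    else:
        reselect_lag = False
    ytilde, _ = gls_detrend(y, spec)
    stats = m_tests(ytilde, lag, spec)
    pvals = sieve_wild_bootstrap_p(
        y, stats.as_dict(), lag, spec, B=B, seed=seed,
        reselect_lag=reselect_lag, p_max=p_max,
    )
    return UnitRootReport(
        statistics=stats.as_dict(),
        pvalues=pvals,
        lag=lag,
        s2_ar=stats.s2_ar,
        B=B,
        seed=seed,
        spec=spec,
        T=len(y),
        n_trimmed=n_trimmed,
    )
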