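"""Unit-root battery: hand-derived oracles, identities, bootstrap behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epirobust import (
    DegenerateSeriesError,
    DetrendSpec,
    InvalidParameterError,
    gls_detrend,
    m_tests,
    select_lag_maic,
    sieve_wild_bootstrap_p,
    unit_root_report,
)
from epirobust.unitroot import STAT_NAMES, default_p_max

# ---------------------------------------------------------------------------
# independent straight-line oracles
# ---------------------------------------------------------------------------


def oracle_adf(y, p):
    """Plain-loop ADF regression without deterministics; returns (coef, sigma2, t_b0)."""
    y = np.asarray(y, dtype=float)
    T = len(y)
    rows_Y, rows_X = [], []
    for t in range(p + 2, T + 1):  # 1-based t
        dy_t = y[t - 1] - y[t - 2]
        row = [y[t - 2]]
        for j in range(1, p + 1):
            row.append(y[t - j - 1] - y[t - j - 2])
        rows_Y.append(dy_t)
        rows_X.append(row)
    X = np.array(rows_X)
    Y = np.array(rows_Y)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    sigma2 = resid @ resid / (len(Y) - (p + 1))
    cov00 = np.linalg.inv(X.T @ X)[0, 0]
    return coef, sigma2, coef[0] / np.sqrt(sigma2 * cov00)


def oracle_m_stats(ytilde, p, det="c", cbar=None):
    """Direct-formula evaluation of the five statistics."""
    yt = np.asarray(ytilde, dtype=float)
    T = len(yt)
    cbar = cbar if cbar is not None else (-7.0 if det == "c" else -13.5)
    kappa = sum(yt[t - 2] ** 2 for t in range(2, T + 1)) / T**2
    coef, sigma2, t_b0 = oracle_adf(yt, p)
    s2 = sigma2 / (1.0 - sum(coef[1:])) ** 2
    yT2 = yt[-1] ** 2 / T
    mza = (yT2 - s2) / (2 * kappa)
    msb = np.sqrt(kappa / s2)
    if det == "c":
        mpt = (cbar**2 * kappa - cbar * yT2) / s2
    else:
        mpt = (cbar**2 * kappa + (1 - cbar) * yT2) / s2
    return {"MZa": mza, "MSB": msb, "MZt": mza * msb, "MPt": mpt, "ADF": t_b0}


def oracle_maic(y, det="c", p_max=None):
    """Brute-force enumeration of the MAIC criterion over candidate lags."""
    y = np.asarray(y, dtype=float)
    T = len(y)
    if p_max is None:
        p_max = default_p_max(T)
    z = np.ones((T, 1)) if det == "c" else np.column_stack([np.ones(T), np.arange(1, T + 1)])
    yd = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    dy = np.diff(yd)
    vals = []
    for p in range(p_max + 1):
        rows_Y, rows_X = [], []
        for t in range(p_max + 2, T + 1):
            rows_Y.append(dy[t - 2])
            row = [yd[t - 2]]
            for j in range(1, p + 1):
                row.append(dy[t - j - 2])
            rows_X.append(row)
        X = np.array(rows_X)
        Y = np.array(rows_Y)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        n = len(Y)
        sigma2 = resid @ resid / n
        tau = coef[0] ** 2 * sum(r[0] ** 2 for r in rows_X) / sigma2
        vals.append(np.log(sigma2) + 2 * (tau + p) / (T - p_max))
    return int(np.argmin(vals))


# ---------------------------------------------------------------------------
# GLS detrending
# ---------------------------------------------------------------------------


class TestGLSDetrend:
    def test_hand_worked_constant_case(self):
        # quasi-differencing y = 1..5 at abar = 1 - 7/5 = -0.4 gives
        # delta = 26.2 / 8.84 by direct least squares on the quasi-differences
        y = np.array([1.0, 2, 3, 4, 5])
        yt, delta = gls_detrend(y, DetrendSpec("c"))
        assert delta[0] == pytest.approx(26.2 / 8.84, abs=1e-12)
        assert yt[0] == pytest.approx(1.0 - 26.2 / 8.84, abs=1e-12)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            gls_detrend(np.full(20, 3.0), DetrendSpec("c"))

    @given(c=st.floats(min_value=0.1, max_value=100.0))
    @settings(derandomize=True, max_examples=25)
    def test_linearity_in_scale(self, c):
        rng = np.random.default_rng(5)
        y = np.cumsum(rng.standard_normal(40))
        yt, d = gls_detrend(y)
        yts, ds = gls_detrend(c * y)
        np.testing.assert_allclose(yts, c * yt, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(ds, c * d, rtol=1e-9)

    def test_invalid_spec(self):
        with pytest.raises(InvalidParameterError):
            DetrendSpec("c", cbar=1.0)
        with pytest.raises(InvalidParameterError):
            DetrendSpec("quadratic")


# ---------------------------------------------------------------------------
# MAIC lag selection
# ---------------------------------------------------------------------------


class TestMAIC:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        y = np.cumsum(rng.standard_normal(200))
        assert select_lag_maic(y) == oracle_maic(y)

    def test_matches_oracle_on_short_series(self):
        rng = np.random.default_rng(10)
        y = np.cumsum(rng.standard_normal(50))
        assert select_lag_maic(y, p_max=4) == oracle_maic(y, p_max=4)

    def test_single_candidate(self):
        rng = np.random.default_rng(4)
        y = np.cumsum(rng.standard_normal(60))
        assert select_lag_maic(y, p_max=0) == 0

    def test_p_max_validation(self):
        with pytest.raises(InvalidParameterError):
            select_lag_maic(np.arange(20.0), p_max=10)


# ---------------------------------------------------------------------------
# M statistics
# ---------------------------------------------------------------------------


class TestMStatistics:
    @pytest.mark.parametrize("p", [0, 2])
    @pytest.mark.parametrize("det", ["c", "ct"])
    def test_matches_direct_formula_oracle(self, p, det):
        rng = np.random.default_rng(8)
        y = np.cumsum(rng.standard_normal(50))
        yt, _ = gls_detrend(y, DetrendSpec(det))
        got = m_tests(yt, p, DetrendSpec(det)).as_dict()
        want = oracle_m_stats(yt, p, det=det)
        for k in STAT_NAMES:
            assert got[k] == pytest.approx(want[k], abs=1e-10), k

    def test_mzt_identity(self):
        rng = np.random.default_rng(12)
        y = np.cumsum(rng.standard_normal(120))
        yt, _ = gls_detrend(y)
        s = m_tests(yt, 1)
        assert abs(s.MZt - s.MZa * s.MSB) < 1e-12

    @given(c=st.floats(min_value=0.01, max_value=1000.0))
    @settings(derandomize=True, max_examples=25)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(13)
        y = np.cumsum(rng.standard_normal(80))
        yt, _ = gls_detrend(y)
        a = m_tests(yt, 1).as_dict()
        b = m_tests(c * yt, 1).as_dict()
        for k in STAT_NAMES:
            assert a[k] == pytest.approx(b[k], rel=1e-8), k


# ---------------------------------------------------------------------------
# sieve wild bootstrap
# ---------------------------------------------------------------------------


class TestSieveWildBootstrap:
    def test_deterministic_given_seed_and_valid_range(self):
        rng = np.random.default_rng(21)
        y = np.cumsum(rng.standard_normal(100))
        spec = DetrendSpec("c")
        yt, _ = gls_detrend(y, spec)
        obs = m_tests(yt, 0, spec).as_dict()
        p1 = sieve_wild_bootstrap_p(y, obs, 0, spec, B=99, seed=5)
        p2 = sieve_wild_bootstrap_p(y, obs, 0, spec, B=99, seed=5)
        assert p1 == p2
        assert all(0 < v <= 1 for v in p1.values())

    def test_bootstrap_pvalues_scale_invariant(self):
        rng = np.random.default_rng(22)
        y = np.cumsum(rng.standard_normal(90))
        spec = DetrendSpec("c")

        def pv(series):
            yt, _ = gls_detrend(series, spec)
            obs = m_tests(yt, 0, spec).as_dict()
            return sieve_wild_bootstrap_p(series, obs, 0, spec, B=49, seed=3)

        assert pv(y) == pv(10.0 * y)

    def test_invalid_B(self):
        with pytest.raises(InvalidParameterError):
            sieve_wild_bootstrap_p(np.arange(30.0), {}, 0, B=0)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


class TestUnitRootReport:
    def test_report_internally_consistent_on_random_walk(self):
        rng = np.random.default_rng(30)
        y = np.cumsum(rng.standard_normal(150))
        rep = unit_root_report(y, B=99, seed=1, trim_zeros=False)
        assert abs(rep.statistics["MZt"] - rep.statistics["MZa"] * rep.statistics["MSB"]) < 1e-10
        assert all(0 < v <= 1 for v in rep.pvalues.values())
        assert rep.lag >= 0

    def test_power_against_stationary_ar1(self):
        # phi = 0.5, T = 300: the GLS-ADF bootstrap test should reject most of the time
        n_reps, hits = 10, 0
        root = np.random.SeedSequence(31)
        for child in root.spawn(n_reps):
            s1, s2 = child.spawn(2)
            rng = np.random.default_rng(s1)
            e = rng.standard_normal(300)
            y = np.empty(300)
            y[0] = e[0]
            for t in range(1, 300):
                y[t] = 0.5 * y[t - 1] + e[t]
            rep = unit_root_report(y, B=199, seed=s2, trim_zeros=False)
            hits += rep.pvalues["ADF"] < 0.05
        assert hits >= 8

    def test_zero_lead_in_trimmed(self):
        rng = np.random.default_rng(33)
        walk = np.abs(np.cumsum(rng.standard_normal(120))) + 1.0
        y = np.concatenate([np.zeros(15), walk])
        rep = unit_root_report(y, B=19, seed=0)
        assert rep.n_trimmed == 15
        assert rep.T == 120
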