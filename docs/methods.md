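# Methods

This note records the statistical procedures implemented in `epirobust`, the
modelling choices behind the synthetic data generators, and the numerical
conventions adopted where several defensible options exist.

## The setting

The package analyses three kinds of daily series: cumulative epidemic counts
I_t (with first differences ΔI_t, the daily counts, and second differences
Δ²I_t, the daily changes), stock-index closing prices, and annualized
central-bank rates. All estimation is restricted to the sample starting at the
first strictly positive cumulative count — the active period of the series.

Three empirical features drive every design decision:

1. daily counts ΔI_t behave like integrated (unit-root) processes;
2. daily changes Δ²I_t are heavy tailed, with power-law tail indices ζ low
   enough (often below 2, sometimes near or below 1) that variances and
   possibly first moments are infinite;
3. daily index returns are heavy tailed and strongly heteroskedastic.

## Unit-root battery

GLS detrending quasi-differences the series at ᾱ = 1 + c̄/T before removing
the deterministics, with c̄ = −7 (constant) or −13.5 (constant + trend).
From the detrended series ỹ the package computes κ = T⁻² Σ ỹ²ₜ₋₁ and an
autoregressive spectral variance s²_AR = σ̂²_p/(1 − Σ b̂_j)² from a lag-p ADF
regression, and forms MZ_α = (T⁻¹ỹ²_T − s²_AR)/(2κ), MSB = (κ/s²_AR)^½,
MZ_t = MZ_α·MSB, MP_t (with the constant- and trend-case forms), and the
ADF-GLS t-ratio. All five reject the unit root for small values.

**Lag selection.** The ADF lag is chosen by the modified AIC,
MAIC(p) = ln σ̂²_p + 2(τ(p)+p)/(T−p_max) with τ(p) = b̂₀² Σ ỹ²ₜ₋₁/σ̂²_p, on
the common sample t = p_max+2..T, with p_max = ⌊12(T/100)^¼⌋ by default.
Conventions left open by the construction: the criterion is evaluated on the
OLS-detrended series (standard ADF detrending); σ̂²_p uses the common-sample
observation count as divisor; ties go to the smallest lag. In `m_tests` the
residual variance is degrees-of-freedom adjusted; all statistics are
scale invariant, so these divisor choices cannot change rejections, only the
MAIC trade-off.

**Sieve wild bootstrap.** P-values come from a bootstrap designed for heavy
tails and heteroskedasticity: fit a sieve AR(p) to the first differences
(demeaned only in the trend case, since a linear trend in levels is a constant
in differences), multiply the residuals by i.i.d. Rademacher signs, recolour
through the fitted AR with zero initial conditions, cumulate so the unit root
is imposed, and recompute the whole battery on each path;
p = (1 + #{stat* ≤ stat})/(B+1), with B = 999 by default.

**Lag re-selection inside the bootstrap.** The MAIC choice is repeated on
every bootstrap path by default. Holding the data-selected lag fixed looks
cheaper and more stable, but lag selection is part of the procedure whose
null distribution the bootstrap must mimic: in calibration experiments on
Gaussian random walks (T = 150, B = 199, 500 replications) the fixed-lag
variant rejected at only 2.2–2.8% at the nominal 5% level — conditional on
MAIC spuriously picking p > 0 (about 29% of samples at this T) it essentially
never rejected — while re-selection restores empirical size to 3–5.5% across
seeds. The fixed-lag variant remains available (`reselect_lag=False`).

## Tail-index estimation

Both estimators operate on the strictly positive values of the daily changes
(at least 20 required). The Hill estimator over the k largest order
statistics is the MLE under an exact Pareto tail; its standard error is taken
as ζ̂/√k, the standard asymptotic form. The log-log rank-size regression uses
the small-sample bias-correcting shift of ½ in ranks and reports the
asymptotically correct standard error √(2/k)·ζ̂ rather than the (badly
misleading) OLS standard error. Confidence intervals are normal-approximation
95% bands; the curve over a k-grid (2.5–15% of the sample by default) exposes
the moment diagnostics a practitioner reads off such plots — whether any CI
lower bound falls below 2 (infinite variance possible) or below 1 (infinite
mean possible). Ties among order statistics are kept in stable order; the
threshold convention is the (k+1)-th order statistic.

## Predictive-regression inference

The regression is R_t = α + β X_{t−1} + ε_t with R_t the daily excess return
(log return in %, minus the annualized rate over a 252-day count; both
conventions are configurable) and X the chosen transform of the counts:
levels (ΔI or Δ²I) or differences of logarithms of the daily counts.

**HAC.** The slope's sandwich variance uses the long-run variance of the
scores v_t = (x_t − x̄)ε̂_t, estimated with the quadratic spectral kernel and
Andrews' AR(1) plug-in bandwidth S_T = 1.3221(α̂(2)T)^{1/5},
α̂(2) = 4ρ̂²/(1−ρ̂)⁴, with ρ̂ the lag-1 autocorrelation of the scores (no
prewhitening; unit weight). Autocovariances use divisor T. P-values come from
the standard normal.

**Group t-statistic.** The sample is split into q consecutive blocks
(group j = {t : (j−1)T/q < t ≤ jT/q}; sizes differ by at most one), β is
estimated per block with a per-block intercept, and
t_β = √q·β̄/s_β̂ is referred to Student-t(q−1). The test requires no variance
estimation and is valid under independent, possibly wildly heteroskedastic
Gaussian (or mixed-Gaussian) group estimates — but only for two-sided levels
up to 8.3%, which the result object records (`level_valid`). With calendar
blocks it reproduces Fama–MacBeth inference exactly. T ≥ 3q is required so
each block regression has minimal degrees of freedom.

## Synthetic data: what it emulates and what it does not

The count generator draws a latent walk L_t = L_{t−1} + drift + scale·ξ_t and
reports ΔI_t = round(max(L_t, 0)) after a 10-day all-zero lead-in; a raw mode
returns the un-truncated walk for estimator tests, because truncation and
rounding destroy exact distributional statements about the increments.
Defaults: ξ_t Student-t with 1.5 degrees of freedom — tail index 1.5, the
centre of the heavy-tail range observed for daily-count changes — with
drift 5, scale 10 and initial level 50, which keeps zero-pinned stretches to
roughly 7% of days (real series have quiet stretches but are mostly active).
Return errors default to GARCH(1,1) with ω = 0.01, a = 0.15, b = 0.84
(unconditional daily volatility 1%, persistence 0.99): daily index returns in
a crisis window are strongly heteroskedastic with an elevated ARCH component,
and an i.i.d. error law would miss exactly the feature that breaks normal
critical values. Reproducibility: one root seed; composite generators spawn
documented child streams (infections walk, deaths walk, return errors).

The generator does **not** emulate epidemic mechanics (no SIR-type dynamics,
no waves by construction, no day-of-week reporting artifacts, no negative
data-correction entries), and the deaths series is an independent walk at
1/20 scale rather than a lagged function of infections. Tests passing on
these inputs therefore certify the statistical machinery under the assumed
persistence/heavy-tail/heteroskedasticity structure, not the fidelity of any
epidemiological model.

## The null-calibration contrast

With β = 0, the study driver exhibits the methodological point the package
exists to make. For the *stationary but extremely heavy-tailed* daily-change
regressor, HAC t-tests with normal critical values over-reject grossly
(12–29% at the 5% level in our experiments, worsening as the tail index
drops toward 1) while the group t-test stays near or below nominal. For the
*persistent* daily-count regressor, exogeneity of the errors protects the HAC
t-statistic's null distribution (conditional-on-regressor normality), so HAC
sits near nominal there — but the group test becomes conservative under the
wildly heterogeneous block variances a near-integrated regressor induces, so
HAC still flags significance materially more often. In both regimes the group
test never over-rejects; that one-sided safety under heterogeneity, costing
some power, is its design trade-off.

## Numerical conventions and edge cases

* Bootstrap p-values use the (1+#)/(B+1) convention, so they are never zero.
* A constant series (nothing left after detrending), a zero spectral
  variance, a constant regressor (globally or within a group — the error
  names the group), fewer than 20 positive changes, or an empty
  returns/counts overlap raise typed errors; the study driver records a
  row's error and continues with the remaining rows.
* All group estimates equal: t_β is flagged infinite (p = 0) when the mean is
  non-zero, degenerate when it is zero.
* The Andrews plug-in caps |ρ̂| at 1 − 10⁻⁶ with a warning; a zero bandwidth
  reduces the long-run variance to the heteroskedasticity-only (White) form.
* Significance stars use strict inequalities: *** p < 1%, ** p < 5%,
  * p < 10%; p = 0.05 earns a single star.
* Calendar alignment pairs each trading day with the count transform on the
  most recent calendar day strictly before it (Monday uses Sunday), drops
  rows whose transform is undefined (log of a non-positive count,
  observations consumed by differencing) and audits every drop by reason;
  used + dropped = available always holds. Rates are forward-filled onto
  trading days.

## Problem sizes used in the test suite

Monte Carlo checks run at: 10,000 replications per configuration for the
group-test validity grid; 500 Gaussian random walks (T = 150, B = 199) for
bootstrap size and 200 AR(1) paths (φ = 0.8, T = 300) for power; 200
replications for the Hill and rank-size sampling laws (n = 5000/4000);
200 synthetic studies per regressor regime (about 600 aligned observations
each) for the null-calibration contrast. The full suite completes in well
under two minutes on one CPU.
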