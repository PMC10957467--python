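# Methods notes

## Model

The estimand is the deviation of a group-level smoking outcome from its own
pre-intervention trajectory after a policy event adopted by each country in
a different calendar year. Realigning every country to event time
`t = year − T0` makes the event simultaneous by construction; group series
are sums of member counts at each `t` (ratios of sums, never means of
ratios), and outcomes are logs of those sums, so all effects are relative.

Five nested segmented specifications are fit by OLS on a window of
`pre_window = 10` years before and `post_window = 10` years after the
event (21 points): a pre-trend polynomial in the time index `T` of degree
1, 2 or 3, a level shift `β4·X`, and post-trend terms `β5·X·I`
(+ `β6·X·I²`), with `X` the post indicator and `I` years since the event.
Key assumptions: the counterfactual is the continuation of the fitted
polynomial; the event is the only discontinuity at `t = 0`; errors may be
serially correlated and heteroskedastic but the mean model is correct.

Inference uses the Newey–West (Bartlett-kernel) HAC covariance. The
truncation lag defaults to `floor(4·(n/100)^(2/9))` — 2 at n = 21 — the
common automatic rule; it is a tuning constant, not an estimate, and is
overridable. Coefficient point estimates never depend on it.

Specification choice minimizes `AIC = n·log(RSS/n) + 2k`, equivalent to
the Gaussian likelihood AIC up to a constant, so comparisons are internally
consistent. Ties break toward the smaller model id (fewer parameters).
`aic_window="pre"` scores candidates on pre-period residuals only, which
reads the selection rule as "best pre-intervention fit"; the default scores
the full window. Both are exposed because either reading is defensible; the
pre-window variant roughly halves the dispersion of the 10-year cumulative
effect in simulation, because it rarely rewards post-period curvature terms
that extrapolate badly.

## Reported quantities

All three summaries are linear in the coefficients, so delta-method CIs on
the HAC covariance are exact:

* average pre-trend: mean over pre rows of `β1 + 2β2·T + 3β3·T²`, ×100;
* average trend change: mean over `I = 0..h` of `β5 + 2β6·I`, ×100
  (the grid starts at 0 because `t = 0` is coded post, see below);
* cumulative effect at horizon `h = 10`: `100·(β4 + β5·h + β6·h²)`.

Percent means 100×log-points throughout, matching the convention of
reading log-model coefficients as relative changes; the exact
transformation `(e^Δ−1)·100` is what the counterfactual module uses when
converting to counts, and the two agree to first order.

The event year `t = 0` is assigned to the post period (`X = 1, I = 0`).
With ten post years this puts `I = 10` on the last observed year, so the
10-year cumulative effect is evaluated inside the window, not beyond it.
The alternative coding is available (`t0_is_post=False`).

Counterfactual counts are `exp` of the pre-trend part evaluated over
`t = 0..h`. "Averted" defaults to the stock difference at the horizon
(`at_horizon`), which makes the percent-of-projected figure equal to
`-(e^Δ−1)·100` of the same fit's cumulative effect — an identity the test
suite enforces; a `cumulative_person_years` mode sums the yearly gaps
instead, since "fewer smokers over a decade" can be read either way.
The tax what-if (`scenario_reassign`) applies a donor group's relative
reduction to a target group's projected path; it assumes transportability
of the relative effect and nothing more.

## Bootstrap

After realignment the country is the only exchangeable unit, so CIs come
from resampling member countries with replacement (100 replications by
default, seeded, fully deterministic) and rerunning aggregation → fit →
statistic. Percentile intervals are the default. With ~100 replicates the
2.5% tails rest on two or three order statistics, and when a few large
members dominate the aggregate the percentile interval is measurably
narrow; `interval="normal"` therefore uses the replicate standard deviation
with a t critical value whose degrees of freedom are the Kish effective
number of countries (computed from smoker-count weights) minus one. In the
package's own coverage studies (50-country groups, log-normal size spread
with ln-sd 1.0) the percentile interval covers a true −15% cumulative
effect about 88–90% of the time and the Kish-t interval about 92%; with
mild size spread (ln-sd 0.3) both are at the nominal 95%. Temporal
dependence is the fit's concern (HAC), not the bootstrap's; no block
bootstrap is attempted.

The delta-method HAC interval on a single 21-point aggregate fit badly
understates cohort-to-cohort variability (~58% coverage in the same study)
and is reported for within-fit inference only.

## Synthetic data

`simulate_country` draws log young-smoker counts as a polynomial secular
trend in event time plus a level/slope/quadratic break at the country's
ratification year, with stationary AR(1) Gaussian noise on the log scale
(multiplicative counts, matching the log outcome model); population grows
smoothly, and the 45–59 band carries an ever-smoker pool whose quit ratio
drifts after the event. Ratification years are sampled over 2004–2010 with
median 2005. Scenario defaults sit in the observed ranges: baseline
prevalence 8–25%, secular decline ≈ 2%/yr, country sizes log-normal
(ln-sd 1.0), noise sd 0.02 with lag-1 correlation 0.5, and effect profiles
of a few percent per year, with the world preset accumulating to −15% at
ten years and the tax-split preset giving high-tax-change countries roughly
double effects.

Ground truth for a group is defined by applying the same effect formulas to
the noiseless aggregate curves; when members share break parameters this
equals the closed-form `100·(β4 + β5h + β6h²)` to machine precision (an
enforced invariant). The generator does not emulate survey-smoothing
artifacts, reporting gaps, migration, or correlated shocks across countries
— so passing recovery tests demonstrates the estimator machinery, not
robustness to those real-data features.

The recovery and null-control studies (200 cohorts of 50 countries each)
fit the generating specification when measuring parameter recovery:
specification search is a separate concern with its own adequacy study,
and mixing the two would measure mostly the extrapolation variance of
occasionally selected cubic models (per-cohort sd 8–14 pp against ~1 pp
under the generating class — the same order as the very wide CIs such
models produce on real aggregates).

## Degenerate inputs and numerical choices

Zero aggregate counts are errors, not `−∞` logs. Incomplete event-time
windows raise with the missing years named; no imputation is performed.
Rank-deficient designs (e.g. constant event time) raise rather than
pseudo-inverting. `RSS = 0` is floored at 1e-300 inside the AIC log.
Bootstrap replicates that fail are tolerated up to 20% and then reported
as a diagnostic error with the first failure messages.

## Limitations

Group aggregation hides country heterogeneity; one large member can
dominate a group (the motivation for both the separate-China convention
and the Kish-df interval). The counterfactual inherits all fragility of
polynomial extrapolation — cubic pre-trends in particular produce very
wide, honest CIs. Sex-stratified analysis and any mapping from averted
smokers to deaths are out of scope.
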