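# Methods

## Model

Each randomized trial contributes a 2×2 table. The effect measure is the
log odds ratio y_i with large-sample within-study variance
ν_i = 1/a + 1/b + 1/c + 1/d. If any cell is zero, 0.5 is added to all four
cells of that study (the dominant convention for inverse-variance odds
ratios; the increment is configurable). Studies with zero events in both
arms, or all events in both arms, carry no information about the odds
ratio and are excluded — flagged, never raised as errors.

The random-effects model takes y_i ~ N(θ_i, ν_i), θ_i ~ N(θ, τ²). Pooling
uses inverse-variance weights 1/ν_i (common-effect) or 1/(ν_i + τ̂²)
(random-effects); heterogeneity is tested with Cochran's Q against a
χ²_{k−1}, flagged at the 0.10 level by default (0.05 available) because
the test is underpowered at small k.

## τ² estimators

Six estimators are implemented directly (they are the object of study, so
none is delegated to an external package; R's metafor serves as an
independent cross-check in the tests):

- **DL** — method of moments: max(0, (Q − (k−1))/C), C = Σw − Σw²/Σw.
- **HS** — max(0, (Q − k)/Σw).
- **SJ** — two-step: crude τ̂₀² = Σ(y_i − ȳ)²/k (unweighted mean,
  divisor k per the original definition; k−1 selectable), then a weighted
  re-estimate with weights 1/(ν_i/τ̂₀² + 1).
- **PM** — the root of the generalized Q equation
  Σ(y_i − μ̂(τ²))²/(ν_i + τ²) = k − 1, solved by Brent's method on a
  bracket obtained by doubling from Var(y); the statistic is strictly
  decreasing in τ², so the bracket is guaranteed. Truncated to 0 when
  Q ≤ k − 1.
- **ML / REML** — maximizers of the profile (restricted) normal
  log-likelihood, found by the standard fixed-point update
  τ² ← Σw²[(y−μ̂)² − ν]/Σw² (+1/Σw for REML) with relative tolerance
  1e−10, at most 100 iterations, truncation at zero, and a bisection
  fallback on the score function when the iteration stalls.
  Non-convergence is reported via `converged=False` with the last
  iterate.

All estimates are invariant to shifting every y_i and equivariant under
rescaling (y, ν) → (cy, c²ν).

## Sequential boundaries

The spending function is the O'Brien–Fleming-type rule
α*(t) = 2(1 − Φ(z_{1−α/2}/√t)), interpreted as the *total two-sided*
error spent by information fraction t; it reaches α at t = 1, so a single
look at full information recovers the fixed-sample critical value
1.959964. (An alternative convention applies one-sided spending at α/2
per side and yields slightly different tables; the symmetric total-spend
form is used throughout and is what the package's recursion, Monte-Carlo
checks and tests agree on.)

Boundaries solve "first-exit probability at look j = spend increment"
under the Brownian null on the score scale, by the classical recursion:
the sub-density of non-crossed paths is propagated between looks by
convolution with the Gaussian increment kernel on a 512-point trapezoid
grid per look (convergence against 4,096 points is asserted in the
tests), and each boundary is found by Brent root-finding. When the
increment underflows, the boundary is capped at |z| = 8 and flagged.
Information fractions below 0.01 are floored; fractions above 1 are
clipped to 1, with all remaining α spent at the first such look and later
looks sharing its boundary.

## The pipeline

For one estimator: estimate τ̂² on the full data, pool both models, form
D² = (ν̂_R − ν_F)/ν̂_R, AF = 1/(1 − D²), and the RIS. Two RIS scales are
provided: the default participant-scale two-proportion formula
4(z_{1−α/2}+z_{1−β})² p̄(1−p̄)/(p_C−p_I)², anchored at the observed pooled
control event rate (or a user value) and an assumed relative risk
reduction (default 20%, α = 0.05, β = 0.20), with the adjusted size
rounded up to whole participants; and the literal information-units form
4(z_{1−α/2}+z_{1−β})² ν̂_random/μ², kept unrounded. The participant scale
is the default because it is the scale on which accumulated sample size
is naturally compared to the RIS.

The cumulative z-curve adds one look per study in accumulation order
(order_key, ties by study id then input position), re-estimating τ² on
every prefix — the cumulative-meta-analysis convention; a fix-at-final-τ̂²
mode exists for sensitivity. A single-study prefix uses τ̂² = 0. The
verdict is *conclusive_crossed* if |z_j| meets the boundary at any look,
*ris_reached_not_crossed* if the accumulated participants reach the
adjusted RIS without a crossing, else *inconclusive*.

The reported "minimum boundary" is the most extreme signed boundary on
the side of the observed effect among non-capped looks (capped looks are
numerical artifacts of underflowed spend and would make the summary a
constant ±8); if every look is capped the cap is reported.

## Sensitivity sweep

`sweep_estimators` runs the pipeline once per estimator and summarizes
each column with min, max and the QCV, (Q3−Q1)/(Q3+Q1) in percent.
Quartiles use linear interpolation between order statistics by default
(the inclusive-median/Tukey-hinge rule is selectable, since printed QCVs
in the literature rarely state the convention); QCV is computed on
magnitudes for signed quantities, and defined as 0 when Q1 = Q3
(including the all-zero case). Per-estimator failures are recorded in
the report row rather than aborting the sweep.

## Synthetic data

The generator draws θ_i ~ N(θ, τ²), a control rate p_C,i fixed or uniform
on a range, converts θ_i to an intervention rate on the odds scale, and
draws binomial counts with per-arm sizes uniform on [n_min, n_max]. Four
presets mirror the shape of a typical Cochrane case study — small (k = 7)
and large (k = 48) homogeneous meta-analyses, and small (k = 9) and large
(k = 62) heterogeneous ones (τ² = 0.15) — with a moderate protective
effect (θ = −0.4) and control rates on (0.05, 0.30). The generator
emulates the statistical structure the estimators assume; it does not
emulate publication bias, small-study effects, time trends, or
non-normal random effects, so passing tests speak to the correctness of
the machinery, not to robustness against those features of real data.

### Error-rate study

`simulate_error_rates` plans k equal trials whose cumulative size spans
the full RIS implied by the configuration, computes the boundaries once
for that schedule, and measures the proportion of replicates whose
cumulative z-curve crosses (a) the spending boundaries or (b) a fixed
±1.96 at every look. By default the curve uses the common-effect
z-statistic, which isolates the behaviour of the sequential procedure
itself; DL re-estimation at every look is available and is slightly
conservative when the truth is homogeneous. The calibrated scenarios in
the test suite use a control rate of 0.2 with an assumed relative risk
reduction of 0.10, so that per-study event counts are large enough for
the normal approximation of the log odds ratio, with ten looks for the
level checks and seven (the scale of a small meta-analysis) for power.
O'Brien–Fleming monitoring concentrates its spending near full
information, so the attained power at exactly the RIS sits slightly
below the nominal 1 − β — the usual, small sequential-design cost.

## Numerical notes and limitations

- The 95% CI and thresholds use the normal quantile 1.959964 throughout.
- PM roots are found to xtol 1e−12; the generalized-Q identity is
  verified to 1e−8 in tests.
- Boundary accuracy at the default grid is a few 1e−4 in z; Monte-Carlo
  Brownian checks at 2–4 × 10⁵ paths agree with the cumulative spend at
  every look within three binomial standard errors.
- Mantel–Haenszel and Peto pooling, risk-ratio/risk-difference measures,
  continuous outcomes, and futility (β-spending) boundaries are out of
  scope. Boundary monotonicity across estimators holds look-by-look
  below the RIS; at looks clipped to t = 1 the ordering can invert,
  because a schedule with more early spending leaves a smaller final
  increment and hence a higher final boundary.
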