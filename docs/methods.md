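# Methods

## Setting

The analysis model is a regression of an outcome on a set of covariates of
which one, `x_p = a1 / a2`, is a ratio of two partially observed, strictly
positive components. Remaining covariates split into incomplete (`z`) and
complete (`w`); outcomes (continuous `y`, or a survival time/event pair)
are required to be fully observed. A ratio can be missing for three
reasons — numerator missing, denominator missing, both missing — and the
data model enforces that the ratio is flagged missing whenever either
component is, and that observed ratios equal the component quotient to
relative tolerance 1e-10 (a supplied ratio column is cross-checked, never
silently recomputed; observed zero denominators are rejected at load).

## Imputation engine

All strategies except M5-PMM share one engine: a multivariate-normal
regression of the modelled incomplete variables `V` on the complete
regressors `u = (1, f(y), w)`,

    V_i | u_i ~ MVN(Θ'u_i, Σ),

sampled by data augmentation. The I-step draws each row's missing `V`
coordinates from the exact Gaussian conditional given the row's observed
`V` coordinates and `u` (rows are grouped by missingness pattern, so each
iteration costs a handful of small dense factorisations). The P-step draws
`Σ` from its inverse-Wishart full conditional (Bartlett construction) and
`Θ` from its matrix-normal full conditional.

Choices the engine's upstream software tradition leaves open, fixed here:

* **Prior.** Jeffreys-type noninformative, `p(Θ, Σ) ∝ |Σ|^-(|V|+1)/2`,
  giving `Σ | data ~ IW(n − |u|, S)` with `S` the residual cross-product
  at the per-iteration least-squares `Θ̂`. This matches the default of the
  commercial MI implementations this engine mirrors.
* **Starting values.** The EM maximiser of the observed-data likelihood
  (relative log-likelihood tolerance 1e-8, cap 500 iterations), not a
  complete-case fit: it shortens the effective burn-in.
* **Schedule.** Burn-in 1000 iterations, then one completed dataset every
  10th iteration until M are stored (defaults `m=5, burn_in=1000,
  thin=10`, all configurable). Ten iterations may under-separate
  imputations when the missing fraction is very large; raise `thin` if
  between-imputation autocorrelation matters for your use.
* **Numerical safeguards.** Any Cholesky that fails is retried once with a
  1e-10 diagonal jitter; a draw that is still not SPD is an error, not a
  silent truncation.
* **Randomness.** One seeded `numpy` Generator per engine call;
  reproductions are bit-identical given the seed. Sub-streams elsewhere
  derive from `SeedSequence.spawn`, so simulation replicates are
  independent and order-insensitive.

### Outcome encoding

For a continuous outcome `f(y) = y`. For a survival outcome `f(y)` is the
pair (event indicator, Nelson–Aalen cumulative hazard at the subject's own
time), entered as two separate regressors. Nelson–Aalen ties: all events
at a time contribute jointly (`d_s ≥ 2`) and a subject censored exactly at
an event time is counted in that risk set (the conventional
events-before-censorings rule; the engine's provenance does not dictate a
rule, so this one is this package's choice).

### Strategies and passive derivation

`build_strategy` fixes the modelled-variable order as `(z, …)` followed by
the ratio/components for reproducible sweeps. M6 creates `ln a1, ln a2`
columns on the fly and requires observed components to be positive.
`apply_passive` rederives the ratio only in rows where it was missing;
observed cells are never touched. For M5 an imputed denominator of exactly
zero (a probability-zero event) triggers one fresh I-step redraw for the
affected rows and then a hard error — deliberately *not* a truncation,
because extreme-but-finite denominators are the phenomenon of interest.
Rows with one observed component need no special casing: the I-step's
conditional draws use whatever is observed.

The compatibility labels (M1 compatible; M2–M4 semi-compatible; M5/M6
incompatible) are reported as fixed metadata of each strategy; the package
does not re-derive them symbolically. A diagnostic
(`ratio_identity_violations`) reports how often active strategies' draws
violate `x_p = a1/a2`, which they do on essentially every imputed row —
that is a property of those models, not a bug.

### Predictive mean matching (M5-PMM)

Chained equations over `(a1, a2, z)`, ten cycles, k = 10 donors, initial
fill by random draws from each variable's observed values. For each target
the regression parameters are drawn from their noninformative-prior
posterior *before* predictions are formed (proper MI); matching uses the
drawn-parameter predictions for both donors and recipients — whether the
original procedure matched on ML or drawn predictions is not documented,
and this choice is the package's. Distance ties at the k-th donor admit
all tied candidates, removing row-order dependence. The imputation count
`m` lives in `PMMSettings` alongside `k_donors` and `cycles`.

## Analysis fits and pooling

OLS (via statsmodels, classical SEs) for continuous outcomes; Cox partial
likelihood maximised by Newton–Raphson with **Breslow** tie handling and
observed-information SEs for survival outcomes. Breslow is used because it
is the default of the software family this engine mirrors, and ties are
measure-zero in the simulation; lifelines (Efron ties) serves as an
independent cross-check on tie-free data in the tests. Rank deficiency is
reported with the offending columns; diverging coefficients (monotone
likelihood) raise an advisory error.

Rubin's rules report FMI as `λ = (1 + 1/M)B/T` rather than the
ν-adjusted variant `(λ + 2/(ν+3))·…` — the two differ only at small M and
the simpler definition is the one most software prints. Intervals use the
t distribution with Barnard–Rubin degrees of freedom, computed from the
complete-data residual df for linear fits and treating Cox df as infinite.

## Simulation design

The generator emulates two cohort regimes through one parametric family:
`(ln a1, ln a2)` bivariate normal with means (4, 0.97), SDs (0.21, 0.11)
and correlation 0.22 — the "aurum-like", CV(a2) ≈ 0.11 regime of a
weight/height² style ratio. The "epic-like" regime (an HDL-style
denominator) is a **reconstruction**: only the printed coefficient of
variation (0.3) is known, so `log_sd_a2 = √ln(1.09)` makes CV(a2) = 0.3
exactly while every other log-scale parameter keeps its aurum value.
Location parameters are immaterial here (the design is scale-equivariant:
rescaling `a2` rescales `x_p` and the outcome noise together, leaving the
slope's bias and coverage unchanged), so the reconstruction risk is
confined to the unprinted log-SD of the numerator and the log-correlation;
at pilot scale the reconstruction reproduces the published bias table
within Monte Carlo error.

The outcome is `y ~ N(2·x_p, σ²)` with `σ²` chosen from the *analytic*
lognormal variance of `x_p` (not each replicate's sample variance) to hit
the target R² — a population-level target keeps the slope's sampling
distribution identical across replicates. The intercept is zero; only the
slope's properties are evaluated.

Missingness: independent per-component response indicators from
`logit P(R=1) = γ0 + γ1 y`. MCAR fixes `γ1 = 0`, `γ0 = logit(0.75)`
(43.75% of ratios missing). MAR calibrates `|γ1|` so that the *expected*
ROC AUC of `y` against `R` is 0.65 — evaluated by O(N) cumulative-sum
integration over a fixed-seed sample of 10⁶ outcome draws, with `γ0`
re-solved for the 0.75 marginal at every trial `γ1`, both to tolerance
1e-3 — once per scenario, not per replicate. Two details the design's
provenance leaves open:

* **Sign of `γ1`.** The AUC target is sign-symmetric, but the ratio is
  right-skewed so the two signs behave differently downstream. The
  negative sign (high-outcome subjects likelier to be missing) is the
  default: it places missingness in the heavy right tail of `x_p`, where
  imputation misspecification has the most leverage, and it is the only
  sign consistent with the published benchmark results this package's
  acceptance tests target (complete-case bias ≈ −0.17 and the M5/M6 MAR
  biases). `calibrate_mar(..., gamma1_sign=+1)` gives the milder variant.
* **MAR missing fraction.** With these calibrated parameters the expected
  missing-ratio fraction is 42.7% (1 − E[p(y)²]), confirmed by direct
  simulation. The benchmark literature quotes "42%"; the 0.7-point gap is
  attributable to unreported calibration details upstream and is left
  visible (the corresponding acceptance check fails at printed precision
  and is intentionally not loosened).

`run_scenario` seeds every replicate from a spawned `SeedSequence`, counts
and excludes rare per-replicate failures (aborting if they exceed 1% of
replicates), and reports Monte Carlo SEs with every metric
(bias: empSE/√reps; empSE: empSE/√(2(reps−1)); coverage: binomial).

## What a green test does and does not establish

The synthetic world is exactly lognormal with a linear outcome model and
logistic one-variable missingness. Green benchmarks establish that the
engine, strategies and pooling reproduce the known operating
characteristics *in that world* — they do not certify behaviour under
model misspecification beyond it (non-lognormal components, outcome-model
nonlinearity, MNAR missingness), nor for the case-study cohorts the
simulation's presets merely emulate. Known limitations: no categorical
incomplete covariates (latent-normal extensions are out of scope), no
monotone-pattern shortcut, no time-varying covariates or left truncation
in the Cox fit, and compatibility classes are asserted, not derived.
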