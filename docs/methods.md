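# Methods

## Model

`spellmsm` analyses a continuous-time five-state process over follow-up time
(years since inclusion, which is mid-year of the year a person turns 23;
calendar dates are never materialised). The states, in the canonical index
order used for every vector and matrix in the package, are

    0 work   1 unemployment   2 education (tertiary)   3 sick_leave   4 disability

Disability is absorbing. The four transient states communicate freely
(12 ordered pairs) and disability is entered only from unemployment and sick
leave, giving **14 allowed transitions**. Direct work→disability or
education→disability jumps observed in data are treated as administrative
artefacts: the trajectory is censored at the jump time rather than rerouted
through an invented intermediate state, and every such edit is logged.

### Precedence resolution

Registry spells overlap; the resolved state at any instant is the active
spell type of highest precedence,

    disability > sick_leave > unemployment > work > education,

except that a work spell with annual income below the 2G threshold (G being
the social-insurance base amount; the threshold is a tunable
`income_threshold_G`, default 2.0) ranks *just below* education, so
part-time-working students resolve to education. Emigration and
paternal-leave spells outrank everything and produce recorded observation
gaps. Intervals are half-open `[start, stop)`; a transition occurs at the
stop of the origin interval; zero-length fragments produced by resolution
are dropped before merging adjacent same-state intervals. Interior time
covered by no spell is treated like a gap (the person is temporarily out of
observation); leading and trailing uncovered time moves the entry and censor
times inward.

A gap censors the current at-risk period. On return the person re-enters,
left-truncated, in the state observed at the return time — the spell data
decide the re-entry state, including the tie when several spells start
simultaneously at the gap end (precedence applies there as anywhere else).
Re-entry directly into disability after a gap is accepted, because the
pre-gap origin of that transition is unobserved.

### Exclusion pipeline

Five steps, applied in a fixed order so the counts are order-dependent:
pre-start emigrants; persons who never started upper secondary education
before age 21; missing conscript data; missing parental education/income;
invalid follow-up (first resolved state is disability, or never observed in
a model state — e.g. only ever on paternal leave). The `FlowReport` records
`(step, n_removed, n_remaining)` and the final count always equals
`n_initial − Σ n_removed`.

## Estimators

### Nelson-Aalen

For transition h→j, `dÂ(u) = (Σ event weights at u) / (Σ weights at risk at
u)`, with the risk set `{i : entry_i < u ≤ exit_i}` respecting left
truncation. Variance increments are `Σ w² events / (risk weight)²`,
reducing to the classical `d/n²` at unit weights. Multiplying all weights by
a positive constant changes nothing.

### Cox proportional hazards

One model per transition (cause-specific hazard), maximising the weighted
partial likelihood with **Breslow handling of ties** — chosen because it is
the tie convention consistent with the Breslow baseline that the product
integral consumes. Optimisation is Newton-Raphson with step-halving;
convergence requires relative log-partial-likelihood change < 1e-9 *and*
score max-norm < 1e-6, within 50 iterations. Coefficients exceeding 20 in
absolute value flag monotone likelihood (separation); non-convergence raises
an error carrying the last iterate. Continuous covariates (the district
unemployment rate) are centered at the weighted estimation-sample mean so
the Breslow baseline `dÂ₀(u) = d_u / Σ_{at risk} w e^{β'z}` refers to an
interpretable pattern; predictions undo the centering, and a pattern that
leaves a centered covariate unspecified sits at the centering value. With
β = 0 the Breslow baseline reproduces the Nelson-Aalen estimate bit-for-bit
because both run through the same risk-set arithmetic.

The robust (sandwich) covariance aggregates score residuals **per person**,
not per row, since one person contributes many counting-process rows; it is
used for the weighted univariate models, where the model-based variance is
not valid.

### Product integral

Transition-specific hazards are merged into a matrix path after rounding
jump times to 1e-9 years (a canonical rounding that makes grid unions
float-safe; query times in `product_integral` and curve evaluation are
rounded the same way). Off-diagonal increments are the hazard increments,
diagonals minus the row sums; every `I + dÂ(u)` must be a stochastic matrix
and a row-sum increment above 1 raises an error naming the origin state and
jump time. For covariate-conditional curves on sparse late risk sets such a
violation can legitimately occur at small sample sizes; the pipeline then
truncates the conditional path just before the first invalid jump and logs
the cut (the strict error remains the default behaviour). The finite matrix
product satisfies Chapman-Kolmogorov exactly (to floating-point), and in a
two-state path it reduces exactly to Kaplan-Meier survival.

### Initial distributions and curves

`P(X(0)=k)` is estimated empirically ((weighted) starting-state proportions,
disability excluded) or model-based via multinomial logistic regression of
the starting state on the design matrix, evaluated at a covariate pattern —
the default for covariate-conditional curves. Curves are step functions;
requested times between jumps take the value at the last jump. Contrasts
(completion − non-completion differences, ratios, and the ratio of weighted
to unadjusted difference curves) are formed on the union grid with
step-constant interpolation; ratios with zero denominator are flagged
undefined (NaN), never fabricated. Pointwise percentile bootstrap bands over
person-level resamples are available; replicates with an empty exposure arm
are skipped and counted.

### IPTW

The exposure model is a logistic regression of completion on the 23 encoded
baseline covariates (exposure excluded), fitted by IRLS (statsmodels GLM,
deviance tolerance 1e-10, max 100 iterations); constant columns are dropped
from the design as uninformative. Weights default to **unstabilized**
`1/p̂` (exposed) and `1/(1−p̂)` (unexposed) — the plain
inverse-probability-of-treatment form — with stabilization and symmetric
percentile truncation available as opt-in flags; fitted probabilities at 0
or 1 raise a positivity error naming suspect columns. Balance is reported as
standardized mean differences per design column, dividing weighted and
unweighted mean differences by the unweighted pooled SD (the conventional
scaling, so weighting changes the numerator only).

## Design matrix

Reference-cell dummy coding with fixed reference levels gives 23 covariate
columns — birth year (6 levels → 5), parental education (3 → 2), parental
income band (4 → 3), parental disability (2 → 1), mother's marital status
(4 → 3), childhood chronic disease benefit (3 → 2), conscript IQ stanine
band (3 → 2), conscript BMI band (4 → 3), military eligibility (2 → 1), and
the continuous district unemployment rate — plus the 0/1 exposure indicator:
24 parameters per transition, 336 over the 14 transitions. Field of study
(general studies vs vocational tracks) is a stratifier, not a covariate:
every pipeline analysis runs separately per field with its own risk sets,
weights and curves.

## Synthetic registry generator

The generator emulates the statistical structure of national registry data
that cannot be redistributed:

* **Covariates** drawn from configurable marginals matching the published
  cohort composition (e.g. 58/16/26% across IQ bands, 2.8% ± 1.4 district
  unemployment); field of study general with probability 0.403.
* **Exposure** from a logistic model on the encoded covariates plus a field
  effect. Default coefficients load on IQ, parental education/income and
  related covariates, calibrated so completion runs at roughly 80% in
  general studies and 50% in vocational tracks — creating measured
  confounding by construction.
* **Trajectories** from competing piecewise-exponential clocks: baseline
  intensities are piecewise-constant on `[0,3)`, `[3,6)`, `[6,12.5]` years
  (three pieces capture the early unemployment peak and later
  stabilisation), scaled per person by `exp(β'z)`. Sojourns are sampled by
  exact inversion within pieces. Default exposure log-hazard-ratios roughly
  halve entries into unemployment/sick leave and double-to-triple entries
  into education. The initial state comes from a multinomial logistic model
  (completers, especially in general studies, start in education far more
  often). An optional **semi-Markov mode** multiplies any transition's rate
  by a piecewise-constant function of time-since-state-entry, sampled
  exactly by merging the calendar and sojourn breakpoint grids.
* **Nuisance structure**: observation gaps (emigration / paternal leave,
  Poisson with mean `gap_rate` per person-year, mean length 0.5 years,
  same-type overlaps merged) and overlapping spells at rate `overlap_rate`.
  Injected overlaps always *lose* the precedence contest (education under
  work paying ≥ 2G, sub-2G work under education, education under
  unemployment/sick leave), so the resolved trajectory equals the latent
  Markov path exactly while the precedence and 2G rules are genuinely
  exercised. Configurable fractions of persons carry each exclusion flag or
  degenerate history (starting in disability, only paternal leave).
* **Randomness**: one master seed; every person draws from deterministic
  substreams (`SeedSequence(seed, spawn_key=(stream, person))`), so growing
  the cohort never reshuffles earlier persons, and cohort, path and nuisance
  draws are independent.
* **Oracle**: for Markov specs, exact occupation probabilities come from
  composing matrix exponentials of the piecewise generator, averaged over
  the empirical covariate distribution for marginal quantities (optionally
  under a counterfactual exposure forced on everyone — the IPTW estimand).

What the generator does **not** emulate: the joint dependence structure of
real covariates beyond marginals, calendar-time effects, mortality (the
five-state model has no death state; persons are censored, not killed),
informative censoring, and measurement error in spell boundaries. Passing
tests therefore demonstrate correctness of the estimators under the model's
own assumptions plus the specific violations injected (semi-Markov sojourn
dependence, confounding, gaps), not robustness to everything real registry
data can do.

### The designed confounding scenario

`confounded_study_config()` fixes the study conditions for the
confounding-correction check: exposure and transition intensities both load
strongly on IQ and parental education (rebalanced to 40/30/30 marginals),
field effects are zeroed, and gaps/overlaps/exclusions are disabled so the
matrix-exponential oracle is exact. Under these conditions the unadjusted
completion effect on occupation probabilities at t = 5 is biased by more
than 0.05 (maximum ≈ 0.065, on unemployment) — verified analytically from
the oracle, not by simulation — while weighting on the same covariates
removes the bias.

## Problem sizes

The test suite and the acceptance script use cohorts of 5 000 (oracle
agreement), 2 000 (Cox recovery), 20 000 (confounding correction), and
10 000 (semi-Markov robustness) persons, 1 000 random spell sets for the
precedence oracle at 1e-3-year grid resolution, and reduced-scale replication
counts for the sandwich-variance (40 × n=400) and bootstrap-coverage
(60 × B=120) properties; these sizes give Monte-Carlo error comfortably
inside each check's tolerance while keeping a full run to a few minutes on
one CPU.

## Known limitations

* Breslow ties only (no Efron), a single baseline per transition (no
  stratified Cox), no time-varying coefficients or exposures, no frailties.
* No inverse probability of censoring weights; missingness at the end of
  follow-up is assumed non-informative.
* Conditional (Cox-predicted) curves can require truncation near the end of
  follow-up in small samples, as described above.
* The multinomial initial-state model can separate in small strata; the
  pipeline then falls back to empirical starting proportions and logs it.
* `trajectories_from_counting_process` reconstructs a terminal disability
  interval only up to an unknown stop time (absorbed time generates no
  at-risk rows); it is a validation tool, not a general inverse.
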