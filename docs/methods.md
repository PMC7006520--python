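# Methods

This note records the statistical models and procedures the package
implements, the conventions chosen where the methods literature leaves
room, and what the synthetic-data generators do and do not emulate.

## Colony complexity

A colony's branch architecture is a rooted tree (root = holdfast end,
leaves = distal branch tips; polytomies preserved). Orders follow the
Strahler stream-ordering convention generalised to polytomies:

* tip segments are order 1 (primary);
* at a junction where k ≥ 2 children share the maximal child order m,
  the parent takes order m+1 and those children are **source**
  branches; any lower-order children there are **tributaries**;
* where the maximal child order is unique, the parent continues that
  child's branch at order m and every lower-order child is a
  tributary.

A *branch* is a maximal constant-order path, so N_w counts branch heads
(nodes whose parent has a different order), not segments between nodes.
Every branch below the top order is classified exactly once as source
or tributary — a conservation property the tests check on randomly
generated trees.

The bifurcation ratio is computed per colony as R_b = 10^|slope| from
the unweighted OLS regression of log₁₀ N_w on w over w = 1..max order.
The absolute slope is used because counts decrease with order: the raw
antilog would land below 1, while the convention that perfectly
dichotomous branching has R_b = 2 requires the reciprocal. The result
is independent of the logarithm base (tested with base e, 2 and 10).
Unbranched colonies (max order 1) have no R_b and are excluded from
site means rather than imputed. T/S ratios are reported for orders 1
and 2 only; a site's value is the unweighted arithmetic mean of
per-colony ratios, and a colony with zero source branches at an order
has an *undefined* ratio (distinct from a ratio of 0, which means
"sources but no tributaries").

## Double-reader ageing QA

Ring counts by two independent readers enter a square age-agreement
table over the union of both readers' age ranges; "above the diagonal"
means reader 2 older. Three chi-squared symmetry tests differ only in
pooling:

* **McNemar** (maximal pooling): χ² = (A−B)²/(A+B) with A, B the total
  counts above/below the diagonal; df = 1; no continuity correction.
* **Evans–Hoenig** (diagonal pooling): one term (A_d−B_d)²/(A_d+B_d)
  per off-diagonal distance d with any disagreement; df = number of
  such distances.
* **Bowker** (no pooling): one term (n_ij−n_ji)²/(n_ij+n_ji) per
  unordered cell pair with n_ij+n_ji > 0; df = number of such pairs.

Zero-denominator diagonals/cell pairs are dropped from the df count,
matching the fisheries formulations these names refer to. When every
disagreement is ±1 year, Evans–Hoenig and McNemar coincide exactly.
A perfectly symmetric table gives χ² = 0 with p = 1; perfect agreement
leaves the tests undefined rather than "passing".

Precision indices for R = 2 readers, all on the percent scale: PA is
the share of exact agreements; APE averages ½Σ|x_i − x̄|/x̄ over
colonies; ACV averages sd/x̄ with the two-read sample sd (denominator
R−1 = 1). ACV = √2 × APE is then an algebraic identity, used as a
cross-check. Pairs with mean age 0 are excluded with a warning.

Consensus age is the mean of the two reads. Half-year means are
resolved by a configurable rule (default banker's rounding,
`half_even`); `keep_fraction` keeps the raw mean, which is what the
growth fit uses by default so no information is discarded.

## Age-length keys and age assignment

Length bins are left-closed, right-open, width 5 cm from origin 0, so a
bin is named by its lower bound. The observed key is the raw
cross-tabulation p_la = n_la/n_l; bins with no aged colonies stay
flagged empty (NaN rows), never zero-filled. The smoothed key fits a
multinomial logistic regression of age class on bin midpoint (reference
category = youngest age) by maximum likelihood and returns fitted
probabilities for *every* bin in the occupied range, including empty
ones. The covariate is standardised internally purely for optimizer
conditioning (the fit is invariant to that affine map); BFGS is used
with an L-BFGS fallback, and a non-converged (typically
completely-separated) fit is returned with a warning rather than
raised.

Isermann–Knight assignment distributes ages to length-only colonies per
bin in two stages: each age first receives ⌊n_l·p_la⌋ colonies
(deterministic), then the remaining r_l colonies each receive one age
drawn without replacement with probabilities proportional to the
fractional remainders (stochastic, seeded). Which colony gets which
age is uniform-random within the bin. Counts are conserved exactly,
and the expected assigned composition equals n_l·p_l· — both verified
over seeded replicates. The top occupied bin can be declared
all-inclusive so longer unaged colonies fall into it (their assigned
ages are then understated — the caveat that motivates the flag); the
CLI pipeline symmetrically clips unaged lengths below the key's bottom
bin into it, since a key cannot extrapolate below its data either.

## Von Bertalanffy growth

E[L|t] = L∞(1 − e^(−K(t−t₀))) with L∞ the asymptotic average length
(cm), K the Brody growth-rate coefficient (1/y) and t₀ the nominal age
at zero length (a model artifact). `VonBertalanffyModel.fit()`
minimises Σ(L_i − E[L|t_i])² with a Levenberg–Marquardt least-squares
solver using the analytic Jacobian. Starting values: L∞ = 1.05 × max
observed length, K from an OLS fit of log(1 − L/L∞₀) on t, t₀ = 0.
Requirements: n ≥ 4 and at least three distinct ages (with fewer, the
three-parameter curve is unidentifiable).

Wald standard errors come from the linearised curvature s²(JᵀJ)⁻¹ at
the optimum with n−3 df; they are reported but known to be unreliable
for this model, so 95% intervals are also computed by case-resampling
bootstrap (resample (age, length) pairs with replacement, refit from
the original estimates, take 2.5/97.5 percentiles; default B = 1000,
minimum 100). Replicates that fail to converge or draw fewer than
three distinct ages are dropped and counted, with a warning above 20%
loss. Case resampling (rather than residual resampling) is robust to
heteroscedastic length noise; percentile (rather than BCa) intervals
are the plain default. A Walford-plot slope b over step Δt converts to
K = −ln(b)/Δt for comparisons with increment-based studies.

## Site comparisons

Distributions are compared pairwise with the two-sample KS statistic
D = sup|ECDF₁ − ECDF₂|; p-values are exact when n₁·n₂ ≤ 10,000 and
asymptotic beyond (field site sizes of ~20–30 sit comfortably in the
exact range). All C(k,2) pairs are tested and the family-wise α is
divided by the test count (for four sites: six tests, critical
α = 0.05/6 ≈ 0.008). Means are compared by one-way ANOVA
(F = MS_between/MS_within on (k−1, n−k) df; all-constant input is
reported as degenerate, not as F = 0) and by Tukey HSD with the
Tukey–Kramer standard error for unequal n, p from the studentized-range
distribution; for two groups q² = 2F exactly.

## Synthetic data: what it emulates

`gen_branch_trees` builds trees top-down from one top-order segment:
each order-(w+1) segment spawns c source children of order w — exactly
`target_rb` when that is an integer, else max(2, 1 + Poisson(target_rb
− 1)) — plus Poisson(`tributary_rate`) order-w tributaries attached
along the segment without promoting its order. Realised branch counts
then satisfy N_w ≥ N_{w+1}, the integer/tributary-free limit is exactly
a perfect `target_rb`-ary tree, and tributaries push the realised R_b
above the target (N_w/N_{w+1} ≈ c + rate).

`gen_population` draws integer true ages from a categorical
distribution whose default puts quartiles at 6 and 8 y over a 2–15 y
range (~14% younger than 6, ~22% older than 8), evaluates the VBGF
(default L∞ = 86.1 cm, K = 0.14 /y, t₀ = 1.44 y) and adds
Normal(0, 5 cm) noise truncated at 1 cm, recording lengths to 0.1 cm
(noise-free populations sit exactly on the curve so exact-recovery
tests are meaningful). With probability `read_error_prob` (default
0.18) the two reads of a collected colony disagree: one reader,
chosen at random, is off by exactly one year, direction set by
`read_bias` (default symmetric). This makes PA = 1 − error rate with
all disagreements ±1 year, and marginally each read errs by ±1 with
equal probability — the symmetric null the QA tests assume. Colonies
are spread round-robin over four named sites; optional per-site length
and age shifts create true between-site differences for the comparison
battery. Identical spec + seed reproduces outputs bit-for-bit.

What the generator does *not* emulate: size-stratified collection
(ages are drawn i.i.d., not conditioned on a diver's size strata),
measurement error in length beyond additive Gaussian noise, net
negative growth of damaged colonies, read errors larger than one year,
and any spatial or temporal (recruitment-pulse) structure. Passing
tests therefore demonstrate the estimators' correctness and
calibration under a clean version of the field design, not robustness
to those field realities.

## Problem sizes and numerical choices

The simulation-backed checks run at the scale of the motivating study:
102 aged colonies per population, noise sd 5 cm, 4 sites, ~30 trees per
site. Calibration suites use 2000 simulated tables/batteries; bootstrap
coverage is assessed with B = 200 inner replicates over 200 outer
replications; the reported VBGF parameters in the acceptance script are
medians over 40 replicate populations, because a single n = 102 sample
identifies L∞ and t₀ only loosely (the worked example's CI shows this).
Least-squares convergence tolerances are ftol 1e−10/xtol 1e−12;
multinomial convergence is gradient-based (gtol 1e−8); ALK row sums are
validated to 1e−9; the deterministic Isermann–Knight floor uses a 1e−12
guard against float round-off in n_l·p.

## Known limitations

* **Bowker's test is conservative on sparse tables.** With ~100 pairs
  and disagreements confined to ±1 year across many age classes, each
  discordant cell pair holds only 1–3 observations; the chi-squared
  approximation then over-states the null spread and the empirical
  type-I error at α = 0.05 falls to ~0.006 (measured over 2000
  simulated tables). The implementation is verified against an
  independent reference and hand arithmetic — the miscalibration is a
  property of the unpooled statistic at this sparsity, and is exactly
  why the pooled (McNemar, Evans–Hoenig) variants, which do calibrate
  to nominal here, are preferred for small ageing studies.
* Smoothed keys assume proportions-at-age vary smoothly (log-linearly)
  with bin midpoint; strong non-monotone age-length structure is
  flattened.
* The growth model assumes additive, age-independent residual noise;
  no random colony effects or alternative growth forms (Gompertz,
  logistic) are offered.
* Assigned ages for unaged colonies beyond the key's top bin inherit
  the top bin's composition and are likely underestimates.
* Branch topology only: branch lengths, 3-D morphology and biomass are
  out of scope.
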