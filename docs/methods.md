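# Methods

This note documents the models, calibrations, and numerical choices
behind `propcontest`, and what the synthetic-data results do and do not
establish about real experimental data.

## 1. Contest model

The game is the two-player proportional-prize contest: endowment
*E* = 80 francs, prize *V* = 80 francs, bids in [0, 80]. The share rule
is *Pᵢ* = *eᵢ*/(*eᵢ*+*eⱼ*), with *Pᵢ* = ½ when both bids are zero, and
the per-period earning is *E* − *eᵢ* + *Pᵢ V*. Differentiating gives
the best response BR(*e*) = √(*eV*) − *e* and the symmetric equilibrium
*e\** = *V*/4.

Numerical choices:

- **Best response at a zero opponent bid.** The payoff has a supremum
  but no maximum (any positive bid takes the whole prize and beats the
  coin-flip payoff of bidding zero). `best_response(0)` returns a
  configurable `epsilon_bid` (default 0.01 francs); the brute-force
  grid oracle independently lands on the smallest positive grid point.
- **Fixed-point solver.** Undamped iteration of BR from any interior
  start, tolerance 1e−9, cap 10 000 iterations. The map's derivative
  vanishes at the fixed point for this game, so convergence is fast
  and the cap is never approached in practice.
- **Real-valued bids.** Bids are treated as continuous; an integer
  rounding mode exists in the generator only (the input granularity of
  the original experiment is not recorded; its summary tables report
  non-integer means with integer-looking extremes, consistent with
  either convention).
- Bids above *e\** are never best responses (BR ≤ *V*/4 with equality
  only at *e* = *V*/4); the package asserts this *never-a-best-response*
  property and deliberately does not claim strict dominance, which the
  model as stated does not establish.

## 2. Session engine

Sessions replay the 20-period protocol deterministically: every
participant faces the same fixed pseudo-opponent schedule
(19, 22, 25, 27, 30, 26, 29, 31, 30, 27, 29, 31, 34, 37, 39, 39, 25,
26, 34, 37 francs; mean 29.85) in the same order, each period is
settled by the share rule, and two periods per participant are drawn
uniformly without replacement (seeded) and summed as the realized
payment. Periods are indexed 1–20 throughout. Payment stays in francs;
conversion to cash is outside the computational contract. Whether paid
periods were drawn per participant or per session group is not
recorded in the protocol description; per participant is the default
here.

## 3. Synthetic cohort generator

The generator's job is to produce cohorts with the statistical
structure of the three-condition design — 3 conditions × 30
participants × 20 periods — so the entire pipeline can be exercised
and validated without access to the (non-public) raw data.

Per condition, a bid is a two-part mixture:

- with probability `p_eq`, the bid is exactly the equilibrium
  20 francs (the observed share of exact-equilibrium bids:
  0.2067 anodal, 0.1233 cathodal, 0.1567 sham);
- otherwise, bid = `mu` + *uᵢ* + ε, with participant intercept
  *uᵢ* ~ N(0, σᵤ²) drawn once per participant and idiosyncratic noise
  ε ~ skew-normal standardized to mean 0 and SD `sigma_eps`, shape
  `noise_skew` = −4; draws are resampled until they land in [0, 80].

**Why skewed noise.** The emulation targets per condition are the
published mean (26.490 / 29.515 / 30.467), SD (10.416 / 10.446 /
11.677), the exact-equilibrium shares above, and — in the anodal
condition — a *bimodal* kernel density: a peak at the equilibrium plus
a second peak above it. These constraints jointly rule out symmetric
noise: with the SD pinned near 10.5 and the continuous component's
mean only ~8 francs above the equilibrium, any symmetric unimodal
noise law yields an expected density that decreases monotonically
above the equilibrium spike after kernel smoothing — no second mode
can exist. A left-skewed component (mode a few francs above 30, long
left tail reaching the observed minima of 0–1 francs) reproduces the
two-peak shape while matching the published moments exactly. The shape
value −4 places the component's mode near 31–33 francs; it is exposed
in the configuration (0 recovers Gaussian noise).

**Calibration.** For each condition, (`mu`, `sigma_eps`) solve a
two-equation moment match: the mixture's marginal mean and SD (point
mass + truncated skew-normal, participant intercept integrated out by
31-node Gauss–Hermite quadrature, truncated moments by trapezoid
integration on a 2001-point grid) equal the published mean and SD.
The solver is `scipy.optimize.root`; the frozen defaults reproduce
their targets to <1e−3 francs and `calibrate_condition` re-derives
them in the test suite.

**Variance split.** Only the *total* SD is identified by the published
tables; the between/within split is free. The default σᵤ = 5 francs
puts roughly 15–20 % of the bid variance between participants
(intraclass correlation ≈ 0.16 in the default cohort), a typical
magnitude for repeated economic games. The split is a configuration
parameter.

**Truncation by resampling**, not clamping, so the generator places no
artificial point mass on 0 or 80.

**Demographics** are drawn once per participant: female shares
(19/30, 21/30, 15/30) and age moments (21.967 ± 1.691, 21.100 ± 1.729,
22.067 ± 3.258) per condition follow the published sample description;
major ~ Bernoulli(0.5), GPA ~ N(3.0, 0.5) and log-income ~ N(8.0, 0.7)
are invented defaults (the study reports no distributions for them)
and are labeled as such in the configuration. The `income` column is
the log value, matching its use as a regression control.

**What the generator does not emulate:** learning or adaptation across
periods (bids are exchangeable within participant by construction),
reaction to opponent feedback, integer bid granularity (off by
default), and any dependence of demographics on bidding beyond
condition membership. Consequently, pipeline results on synthetic
cohorts validate the *statistical machinery* — estimator bias,
coverage, df conventions, qualitative density shapes — not behavioral
dynamics.

**Known limitation (condition-mean ordering).** With the published
moments, the cathodal–sham mean gap is 0.95 francs while the sampling
SD of a condition mean at the design size (30 participants × 20
periods) is ≈ 0.8 francs for any admissible variance split (floor
≈ 0.43 at a fully-within split). Strict ordering
anodal < cathodal < sham therefore holds in only ~83 % of seeds, and
no parameterization matching the published moments can push it near
certainty; the anodal-lowest ordering, by contrast, holds essentially
always (gap ≥ 3 francs). The corresponding fidelity check in the
acceptance suite records this gap honestly rather than relaxing the
generator.

## 4. Statistical pipeline

Units of analysis mirror the original report and are exposed as an
option:

- overbidding-rate tests use the 20 period-level condition means per
  condition → rate ANOVA df (2, 57), pairwise *t* df 38;
- expenditure tests pool observations → ANOVA df (2, 1797), one-sample
  *t* df 599 — deliberately ignoring within-participant dependence,
  exactly as those df imply. The random-effects regression is the
  dependence-aware complement.

Other conventions: all tests two-sided; Bonferroni over the 3 pairwise
comparisons; the homogeneity gate is Levene with mean centering at
α = 0.05 (the original report names no specific test); Mann–Whitney
uses the tie-corrected normal approximation with continuity correction
on by default (*z* < 0 when the first sample tends smaller); Fisher's
exact two-sided p uses the point-probability rule (sum of
hypergeometric probabilities ≤ that of the observed table), which
matches full enumeration exactly; bids within 1e−9 of *e\** count as
at-equilibrium. Summary tables are rounded to 3 decimals for display
only; serialized JSON keeps full precision.

**Kernel density.** Gaussian kernel, Silverman rule-of-thumb bandwidth
h = 0.9·min(SD, IQR/1.34)·n^(−1/5), evaluated on a 321-point grid over
[0, 80]. If the IQR degenerates to zero on a discrete-ish sample the
SD alone is used; a zero-spread sample has no density estimate. Mode
detection reports strict interior local maxima at least 5 % of the
curve's peak height, so a single isolated tail observation (which
always produces a tiny kernel bump) does not count as a mode.

**Random-effects regression.** The one-way error-components model is
estimated by Swamy–Arora feasible GLS: within residual variance from
the group-demeaned regression (time-invariant regressors drop out;
with the default all-time-invariant design this is the ANOVA estimate
with df N − G), between variance from the group-means regression with
negative estimates truncated at zero, quasi-demeaning weight
θᵢ = 1 − √(σ²_ε/(σ²_ε + Tᵢσ²ᵤ)), then OLS on transformed data. This
estimator was written in-house; the general-purpose panel FGLS
estimators in the installed stack cover ML/REML mixed models but not
this moment-based form, and the ML fit (`statsmodels` MixedLM) serves
as an independent cross-check in the tests. Standard errors are CR1
cluster-robust at the participant level with small-sample factor
G/(G−1)·(N−1)/(N−k); inference uses t with G−1 df. A rank-deficient
design raises an error naming (a member of) the collinear column set.
With all regressors time-invariant, the GLS point estimates coincide
with OLS on participant means regardless of θ — the tests assert this
identity — so the random-effects machinery matters for the *standard
errors*, and for any design with time-varying covariates.

## 5. Published-number re-derivation

`printed_checks()` recomputes every published value that follows
mechanically from printed inputs: the equilibrium bid (analytic and
fixed point), the three mean overbidding rates implied by the
published mean expenditures, the three one-sample *t* statistics
implied by the published (mean, SD, n) summaries (tolerance 0.01,
since the inputs are printed at 3 decimals — e.g. the anodal statistic
recomputes to 15.262 against a printed 15.263), and the ½ share under
a double zero bid.

One published number is excluded from pass/fail: the Fisher-exact
*p* < 0.001 for at-equilibrium proportions of 20.67 % vs 15.67 %
(124/600 vs 94/600). A standard two-sided Fisher exact test on those
counts gives *p* ≈ 0.033, and no conventional variant (one-sided,
chi-square, with/without continuity correction) reaches 0.001; the
test actually run is unclear, so `printed_checks` reports the
recomputation as informational with an explicit
"not reproducible as stated" note.

The empirical condition-level values themselves (Table-style means,
ANOVA F's, Mann–Whitney z's, regression coefficients) depend on the
unavailable raw data; the pipeline's correctness on those statistics
is instead established by parameter-recovery experiments: across 200
synthetic cohorts with planted condition effects (−3.6 and −0.6
francs), the random-effects dummy estimates show < 0.3 francs mean
bias and 95 % CI coverage within binomial tolerance of nominal.

## 6. Problem sizes and reproducibility

Default problem sizes: cohorts of 1800 observations (90 clusters);
recovery and fidelity experiments use 200 seeds. Every random quantity
flows from a single `numpy` `default_rng` seed; identical
configuration and seed give byte-identical cohort CSVs. Each output
directory carries a metadata JSON (seed, configuration hash, package
version) sufficient to reproduce the run bit-for-bit. The default
quickstart seed is fixed (20190611) so the worked example in the
README prints the same numbers everywhere.
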