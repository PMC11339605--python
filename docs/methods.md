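# Methods

## Generative model of the synthetic cohorts

Cohorts are drawn from a liability threshold model (LTM). Individual *j* in
group *g* has latent liability

    L_j = √V · PRS_j + w_env · PCE_j + b_g + ε_j ,

where `PRS` and `PCE` are independent standardized scores (the polygenic and
the measured non-genetic component), `b_g` a per-group liability shift, and
`ε_j ~ N(0, 1 − V − w_env² − sd(b)²)` so that marginally `Var(L) = 1`.
Disease occurs when `L > T = Φ⁻¹(1−K)`. In the LTM literature the "genetic
liability" is the unstandardized component with variance `V`; because the
generator emits a standardized PRS column `z`, the identity tested is
`Cov(L, √V·z) = V`, equivalently `Cov(L, z) = √V`.

Defaults and their rationale (units in parentheses):

- `prevalence K = 0.0321` (proportion): the incidence regime the analyses
  target — a low-prevalence binary outcome.
- `prs_variance_explained V = 0.05`: a PRS-only AUC near 0.63 at this
  prevalence corresponds to a few percent of liability variance; 0.05 is a
  typical value for a single complex-disease score.
- `env_weight = √0.27 ≈ 0.52`: a clinical risk score with stand-alone AUC
  near 0.75 explains roughly a quarter of liability variance.
- `group_effect_sd = 0` (liability SD): the base LTM has no group structure;
  group differences enter deliberately, via explicit `group_effects`
  offsets, participation bias, or quantile regrouping.
- 21 groups × 2,000 individuals: the default simulation scale for all
  experiments and tests; it keeps each group's observed rate informative
  (≈60 cases) while the whole suite runs on a laptop. Sample-size and
  seed-sweep choices in the tests are stated in the tests themselves.
- age uniform on 40–69 years; non-genetic covariates (total and HDL
  cholesterol in mg/dl, systolic blood pressure in mmHg, BMI, deprivation
  index, and binary smoking/antihypertensive/diabetes flags) are generated
  as noisy loadings on the PCE score with mid-life population means and
  spreads. They give the covariate-subset search and the correlation scan a
  realistic 10-variable surface; they do not feed liability except through
  `PCE`.

All randomness flows from one integer seed through `numpy.random.SeedSequence`.

### What the generator does *not* emulate

Real cohorts have geographically clustered recruitment, informative
missingness, measurement error correlated with deprivation, age-dependent
incidence, and secular trends. None of these are modelled. Passing tests
therefore demonstrate the *statistical mechanisms* — threshold liability,
selection-induced sign reversal, within/between effect separation — not
fidelity to any particular cohort's numbers.

## Participation (ascertainment) bias

Retention is logistic in liability and age:
`P(retain) = logistic(−(strength · gradient_g · L + age_coef · age + offset))`,
with `offset = −2` giving ≈88 % baseline retention. `strength = 0` disables
selection exactly. The sign-reversal demonstration combines rising baseline
group risk (`group_effects` from −0.4 to +0.4 liability SD) with a rising
selection gradient (0 → 1, strength 1.2): risky groups lose their
high-liability — hence high-PRS — members, so survivors' group-mean PRS falls
while group case rates still rise. Individually PRS remains positively
associated with disease; across group means the correlation turns negative.
This is the minimal mechanism that produces the reversal; the magnitudes were
chosen to give a clear effect at ≈85 % overall retention.

## Structured permutations (quantile grouping)

Groups are rebuilt as equal-sized quantiles (sizes differing by at most one,
ties broken by stable row order) of a freshly drawn hidden variable
`y_j ~ N(α₁·PRS_j + α₂·PCE_j, 1)`. Same-sign weights produce groups in which
mean PRS and mean PCE rise together; opposite-sign weights (−0.5, +0.5)
produce groups whose mean PRS *falls* as the case rate rises — engineered
Simpson's paradox. Both canonical weight settings (0.2, 0.2) and (−0.5, 0.5)
are exercised in the tests; 21 groups is the default group count.

## Inference choices

- **Permutation test.** Two groups are pooled and labels reshuffled B times
  (default 2,000). The default p-value is two-sided with the add-one
  correction, `p = (1 + #{|d*| ≥ |d|})/(B+1)`; a `paper_literal` mode returns
  the raw one-sided proportion, which is what makes all-pairs heat maps
  asymmetric. The Monte-Carlo stream is run on a canonically ordered, sorted
  pool so the two-sided p-value is exactly invariant to swapping the two
  groups; a 1e-9 relative tolerance on the comparison keeps splits exactly at
  the observed difference (e.g. the identity relabeling) counted despite
  floating-point summation jitter. Available statistics: mean, median,
  variance, upper-tail proportion (threshold from a pooled quantile, default
  0.95), and mean LTM case probability.
- **Multiplicity.** BH step-up across all pairs of one matrix jointly
  (statsmodels' `fdr_bh` behind the `bh_adjust` surface, verified against the
  direct formula in tests).
- **Reversal screen.** A variable pair is flagged only if the individual- and
  group-level correlation signs differ *and* the BH-adjusted p-values pass
  both screens (individual < 0.01, group < 0.05; both configurable).
- **Mann–Whitney.** Exact enumeration for tie-free pooled samples ≤ 25,
  otherwise normal approximation with continuity correction; fully tied data
  return p = 1.
- **Age standardization.** Direct standardization; empty bands with no cases
  are skipped with a warning, cases without denominators are an error.

## Model fitting

`fit_logistic` wraps IRLS (statsmodels GLM/Binomial, `tol 1e-10`, 100
iterations max) and adds loud failure modes: rank-deficient designs are
rejected naming the collinear columns, perfect separation raises instead of
returning divergent estimates, and non-convergence is reported in the result.
The Mundlak design emits, per covariate, a group-demeaned column (within
effect β) and a group-mean column (between effect γ); the demeaned columns
have exactly zero group means, and the reparameterization identity against
the raw parameterization (`β' = β`, `γ' = γ − β`) is verified to 1e-10 in
fitted probabilities.

**LOCOCV.** Each group is predicted by a model trained on the other groups;
for the Mundlak model the held-out group's between columns are its *own
covariate means* — the only choice consistent with predicting a new group for
which no outcome data exist. A known consequence, documented by the null test:
under exchangeable (pure-noise) grouping the observed-vs-predicted correlation
is *negative*, not zero — excluding a randomly high-rate group lowers its own
training set's base rate — so null behaviour should be read as "no positive
discrimination", and single-seed correlation comparisons between two
well-performing models carry noise of this order.

**Wilson interval.** Bounds are the fixed points of
`p = p̂ ± z√(p(1−p)/n)`. The literal recursion does not contract everywhere
(the map's slope exceeds 1 in magnitude near the boundaries), so the
iteration is slope-damped and bracket-safeguarded (lower root in `[0, p̂]`,
upper in `[p̂, 1]`); converged bounds match the closed-form Wilson score
interval to 1e-8 over a broad random sweep. Degenerate point estimates 0 and
1 pin the corresponding bound.

**AUC.** Mid-rank Mann–Whitney AUC; the CI uses the placement-value
(structural components) variance estimator `var(V₁₀)/n₁ + var(V₀₁)/n₀` with a
normal quantile, clipped to [0, 1].

## PCE-style scoring

The score is `1 − S₀^exp(xb − mean_lp)` with sex-stratified coefficient maps
over log-transformed covariates and interaction terms (treated and untreated
systolic pressure are separate terms). Published coefficient values are not
bundled; the shipped `data/pce_synthetic_coefficients.json` is a
synthetic-labelled stand-in with plausible signs and magnitudes, and users
supply their own JSON of the same shape for real scoring. Eligibility bounds
are strict inequalities (exactly 320 mg/dl total cholesterol is still
eligible), all violated rules are reported, and missing measurements make a
record ineligible rather than being imputed. Age-coded events are converted
to dates as July 1 of (birth year + onset age), with the half-year ambiguity
surfaced as a flag.

## Known limitations

- The same-sign structured-permutation scenario separates the two models much
  more clearly in calibration (RMSE) than in Pearson correlation, because both
  models' predictions are monotone in the same latent group index; at
  2,000 individuals per group the correlation comparison between them is noisy
  seed by seed.
- The subset search ranks by in-sample AUC by default (a cross-validated
  ranking is a one-line change via `lococv`); in-sample AUC differences among
  nested logistic models are typically small.
- The synthetic PCE coefficient table is for interface exercise only; scores
  computed from it are not clinically meaningful.
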