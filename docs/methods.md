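# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `staggerdid`.

## Outcome scale and the linear probability model

Event outcomes are coded 0/1000 rather than 0/1, so every ordinary
least-squares coefficient reads as a change in events per 1,000
persons.  This is the only coding under which headline coefficients of
magnitude ~40–50 and an intercept of ~100–200 are coherent for a binary
outcome, and it is adopted everywhere: the generator stores events this
way, `validate_panel` enforces it, and all tables report per-1,000
effects.  Linear probability fits can imply fitted probabilities
outside [0, 1]; that is a property of the estimand, not an error, and
no link function is applied (the designs under study are linear ones).

## The staggered DID design

The treatment indicator is 1 for records in a pilot region in or after
its adoption year (boundary inclusive).  The default design regresses
the outcome on that indicator, an ever-treated group dummy, the
individual controls and wave fixed effects, clustering at region level.

The ever-treated main effect deserves a note.  A specification with
time fixed effects but no group main effect identifies the
treated-versus-control *post-period level difference*, not a
difference-in-differences: in the two-period, common-adoption case it
reduces to ȳ(treated, post) − ȳ(control, post).  Including the group
dummy restores the classic 2×2 identity — the package's two-period
estimate equals the four-cell difference of group×period means to
machine precision — and removes the treated-level nuisance from the
policy coefficient.  It is on by default
(`ModelSpec.include_treated_main`) and can be disabled to reproduce the
level-comparison variant.  Region fixed effects are supported
(`region_fe="region_id"`) but off by default, matching the printed
specifications this pipeline mirrors (whose near-zero R² is consistent
with no region effects).

## Cluster-robust inference with few treated clusters

The policy varies at region level, so region is the default clustering
unit.  With ~125 clusters but only 8 carrying the treatment, the
textbook cluster sandwich (CR1, small-sample factor
G/(G−1)·(N−1)/(N−K), t on G−1 df) is biased downward for the treatment
coefficient: in the package's own Monte-Carlo calibration its mean
standard error was ~14% below the true sampling dispersion and 95%
intervals covered ~91%.  The default covariance is therefore the
Bell–McCaffrey bias-reduced sandwich (CR2): each cluster's residuals
are pre-multiplied by (I − H_gg)^(−1/2) before entering the meat, and
each coefficient gets Satterthwaite degrees of freedom
df = (tr Ω)²/tr(Ω²) computed under the working i.i.d. model.  For the
treatment term this yields df ≈ 7 (≈ treated clusters − 1) and restores
nominal coverage.  All cluster-level algebra is reduced to k×k
eigendecompositions, so clusters of any size cost the same.  CR1
remains available (`cov_method="cr1"`) and is tested against the
hand-computed sandwich, including the singleton-cluster = HC1 identity.

Degenerate note: CR2's adjustment is undefined when a cluster's
projection eigenvalue reaches 1 (e.g. region fixed effects clustered by
region); eigenvalues are clipped at 1 − 1e−10, which leaves such
configurations finite but conservative.

## Event study

Treated records receive a dummy for their wave-relative event time,
computed in survey waves (biennial), with periods outside the
[−pre, +post] window binned into the endpoints (defaults: 2 pre, 3
post).  The reference period defaults to −1, the wave before adoption —
the conventional normalization — with any in-window period selectable
instead (some studies normalize on a later phase).  The reference
coefficient is identically 0 with a zero-width band.  Never-treated
regions anchor the counterfactual trend.

## Permutation placebo

Pilot status is reassigned uniformly at random across regions, keeping
the cohort structure (the number of regions adopting in each year)
fixed so placebo designs are comparable to the observed one; a
free-timing mode additionally draws adoption years uniformly from the
post-baseline waves.  Region-level reassignment is the default (the
policy varies at region level and region-level exchangeability makes
the test exact under the null); the two-sided empirical p-value uses
the add-one formula p = (1 + #{|draw| ≥ |observed|})/(B + 1), which is
always positive and gives p = 1/(B+1) when the observed estimate is
beyond every draw.  Each draw needs only the treatment coefficient,
which is computed exactly by Frisch–Waugh–Lovell partialling against a
pre-factorized fixed design — verified in tests to match a full refit
to 1e−9 — keeping hundreds of draws cheap.  Draws use independent
seeded substreams per replicate, so the distribution is reproducible
from (seed, B) and invariant to record order.

## Entropy balancing

Control weights minimize KL divergence from base weights subject to
matching treated covariate moments (means by default,
`moment_order=2` adds second moments).  The dual is an unconstrained
convex problem in the tilting parameters; a Newton iteration with step
halving solves it, with constraint columns centered at the target and
scaled to unit dispersion for conditioning.  The dual gradient *is* the
moment violation, so the convergence tolerance (1e−8 on the raw scale,
200 iteration cap) is a direct guarantee on balance quality; the solved
weights satisfy the exponential-tilting form w_i ∝ q_i·exp(c_i′λ) and
are normalized to sum to the number of treated units.  Infeasible
targets (a treated moment outside the control range) raise with the
violating moment named.  Propensity scores are IRLS logistic fits
implemented in-module (cold start, deterministic), with zero-variance
covariates dropped and divergence flagged as separation; matching is
greedy 1:1 nearest-neighbor on the logit scale, default caliper 0.05,
without replacement, ties broken by unit identifier — standard
defaults, stated here because the balancing literature leaves them to
the analyst.

## Entropy-weight pollution index

Indicators are min–max normalized per column over the pooled
region-year panel (not within year), so the index is comparable across
years; inverse-direction indicators use (max − x)/(max − min).  Shares
p_ij, entropies e_j = −(1/ln n)Σp ln p (with 0·ln 0 = 0 exactly, no
epsilon shifts), divergences 1 − e_j and normalized weights follow the
standard formulation.  Constant columns carry no information and are
excluded with a flag.  The index is invariant to positive affine
rescaling of any raw indicator, and all four default indicators (SO₂,
dust, wastewater emissions, PM2.5) are larger-is-more-polluted.

## Moderation, subgroups, Chow

The moderation design adds the moderator main effect and the
moderator×treat×post triple interaction to the base model.  An
identically-zero moderator contributes all-zero columns; they are
dropped with a note and the fit equals the plain DID.  Any other
constant moderator makes the interaction collinear with treat×post and
raises.  Subgroup analysis stratifies the panel (continuous variables
cut at supplied thresholds, e.g. BMI at 18.5/25), drops the grouping
variable from the subgroup covariate sets, flags groups with no treated
observations, and compares coefficients across estimable groups with
the Chow statistic F = [(RSS_p − ΣRSS_g)/((G−1)k)]/[ΣRSS_g/(N − Gk)],
computed on the pooled design columns so k is common.  The per-outcome
loop applies no multiple-testing correction by default (an optional
Benjamini–Hochberg flag exists), matching the primary analysis it
mirrors; "significant" for pan-cancer membership means two-sided
p < 0.05 on the treatment term with a negative estimate.

## The synthetic cohort generator

The generator emulates the panel structure the estimators assume — it
is the test bed, not a model of any real survey.  Defaults are the
study conditions: 125 regions, pilot cohorts of 5 (2013), 2 (2014) and
1 (2016), four biennial waves 2011–2018, 200 individuals per region,
baseline incidence 117.916 per 1,000, policy effect −47.2 per 1,000,
covariate effects with the printed-table magnitudes (female −26.252,
age −0.592/year, CES-D +3.045/unit, ...), Gaussian region random
effects with SD 10 per 1,000, and parallel trends
(`pretrend_slope = 0`).  Covariate effects apply to mean-centered
covariates, so `baseline_rate` is the null-model mean incidence and the
printed magnitudes keep implied probabilities interior.  Covariate
distributions are plausibility choices for a 45+ cohort (ages uniform
45–85 at baseline and aging with calendar time, BMI ~ N(23.5, 3.5²),
sleep ~ N(6.5, 1.5²), CES-D a non-negative clipped normal, binary
covariates Bernoulli) — they are documented defaults, not calibrated to
any survey, and all overridable.  Probabilities are clamped to [0, 1];
a clamping rate above 1% triggers a warning because heavy clamping
attenuates recovery.  The per-site catalog gives 22 cancer sites with
six policy-responsive ones whose shifts sum to −47.2 per 1,000
(cervical −9.848 and breast −11.074 matching the printed per-site
coefficients).  Outcomes are independent Bernoulli draws per record —
no absorbing-event dynamics, no attrition, no survey weighting, no
geography — so passing recovery tests demonstrates estimator
correctness under the assumed sampling structure, not robustness to
real-survey pathologies.

The pre-trend power property was calibrated once and frozen: a slope of
40 per 1,000 per wave at 500 individuals per region is detected by the
event study in >80% of replicates (15/15 in the calibration run; 30 per
1,000 gave ~87%, too close to the bar for a small-replicate regression
test).

## Problem sizes in the test suite

Monte-Carlo tests use the study-scale panel (125×200×4, 200
replicates) for DID recovery and coverage; the placebo calibration runs
200 datasets × 99 draws on a 40-region/25-individual panel (region-level
exchangeability makes the test exact at any size, so the compact panel
is a pure economy choice); moderation recovery uses 40 regions × 60
individuals × 200 replicates.  These sizes are the package's chosen
regression-test conditions.

## Known limitations

- The plain interaction estimator is used throughout;
  heterogeneity-robust staggered-DID estimators (Callaway–Sant'Anna
  and relatives) are out of scope by design.
- No generalized linear models: the designs are linear probability
  fits, and rare outcomes with rich covariates can imply negative
  fitted probabilities.
- The BMI-imputation robustness stand-in is simple median imputation,
  clearly labeled; it is not multiple imputation.
- Whether real analyses of this kind cluster at region level, and which
  covariates enter balancing, is typically unstated; the defaults here
  (region clustering, all covariates balanced) are documented choices.
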