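# Methods

## Effect measures

For a comparison of a high-sexual-selection group (mean m_h, SD s_h,
size n_h) against a low-sexual-selection group (m_l, s_l, n_l):

* **Hedges' g.** d = (m_h − m_l)/s_p with the pooled SD
  s_p = √[((n_h−1)s_h² + (n_l−1)s_l²)/df], df = n_h+n_l−2; the
  small-sample factor J = 1 − 3/(4df − 1) gives g = J·d and
  var(g) = J²·[(n_h+n_l)/(n_h n_l) + d²/(2(n_h+n_l))]. Conversions
  from statistics: t gives d = t√((n_h+n_l)/(n_h n_l)); F (one
  numerator df only — larger df have no unique d and are rejected)
  gives |d| = √(F(n_h+n_l)/(n_h n_l)) signed by the recorded
  direction; a one-df χ² with total N goes through r = √(χ²/N),
  d = 2r/√(1−r²); a proportion difference uses the Cox logit
  transform d = [logit(p_h) − logit(p_l)]/1.65. Boundary proportions
  apply a continuity rule on the implied count (1 → (n−1)/n,
  0 → 1/n); a boundary proportion with unknown count is an error.
  All converted d are then J-corrected with the same df and variance
  formula.
* **lnRR** = ln(m_h/m_l), var = s_h²/(n_h m_h²) + s_l²/(n_l m_l²);
  requires positive means.
* **lnCVR** = ln[(s_h/m_h)/(s_l/m_l)]; its variance sums the
  delta-method variances of the log means and log SDs, minus
  2ρ·(√·√ + √·√) cross terms where ρ is the assumed within-group
  correlation between log mean and log SD. Default ρ = 0, settable
  per run; the source describing this estimator leaves ρ handling
  open, so exposing it as a parameter (rather than estimating it
  silently) keeps the analysis explicit.
* **lnVR** = ln(s_h/s_l) + 1/(2(n_h−1)) − 1/(2(n_l−1)) (the additive
  terms are the log-SD small-sample bias corrections), var =
  1/(2(n_h−1)) + 1/(2(n_l−1)).

**Sign orientation.** Traits expected to be negatively related to
population fitness (parasite load, mutation load, extinction
risk/rate, male mating latency, senescence rate; an editable packaged
list) have g and lnRR negated so that positive always means higher
fitness under sexual selection. The variability ratios are *not*
re-signed: reversing a trait's polarity does not change the direction
of a variance comparison.

## Multilevel REML model

Effects y with known sampling variances v follow
y = Xβ + Σ_l Z_l u_l + e, u_l ~ N(0, σ²_l I), e ~ N(0, diag(v)).
Random levels are study, fitness component (trait), taxon and
optionally the observation level ("effect"), which carries residual
heterogeneity; the moderated model suite includes it because the
motivating analyses report substantial residual I². σ²_l maximise the
restricted log-likelihood
−½[ln|V| + ln|XᵀV⁻¹X| + rᵀV⁻¹r], V = diag(v) + Σσ²_l Z_l Z_lᵀ.

Numerical choices:

* Optimisation over log σ² (positivity without constraints) by
  L-BFGS-B with analytic gradients; the gradient uses thin-Z identities
  (tr(P Z Zᵀ) via triangular solves) so no k×k inverse is formed.
* Restarts from 10⁻³ and from 0.1× and 1× a DerSimonian–Laird-style
  method-of-moments total, split evenly across levels; best optimum
  kept. Tolerances: relative objective change 1e−13, projected
  gradient 1e−8.
* Bounds [1e−10, 1e4] on σ²; estimates within 1e−8 of the floor are
  reported as exactly 0 (boundary tie-break), and fixed effects and
  their covariance are re-profiled at the reported σ².
* Fixed-effect inference is Wald-type: z = β̂/SE against the standard
  normal, 95% CIs at ±1.96·SE, matching common meta-analytic practice;
  no small-sample (Knapp–Hartung) adjustment. Contrasts L'β̂ use
  SE = √(LᵀΣL) with the same normal reference. Hypothesis contrasts
  phrased as one-sided "A > B" comparisons are reported as signed
  estimates with two-sided CIs.
* Treatment coding with reference levels male (sex) and benign
  (environment); the sex×environment design therefore has six columns
  (intercept, both, female, stressed, both×stressed, female×stressed).
  Rank-deficient designs raise an error naming the aliased columns.
* Degenerate inputs: k ≤ p, non-positive sampling variances, and
  unknown moderator levels are errors; non-convergence is flagged on
  the result, never silent.

Cross-validation: on a fixed 40-effect fixture the engine matches
metafor::rma.mv (R) coefficients and variance components to ~1e−4
(frozen oracle values in the test suite), and with all σ² = 0 it
reduces exactly to inverse-variance weighted least squares.

The per-trait analyses fit separate intercept-only models (random:
study, taxon) for every fitness component with more than three
effects; others are reported as skipped.

## Heterogeneity

I² uses the typical sampling variance
v̄ = (k−1)Σw/[(Σw)² − Σw²], w = 1/v, with
I²_l = 100·σ̂²_l/(Σσ̂² + v̄); levels sum to the total exactly. Optional
CIs come from a seeded parametric bootstrap (default B = 1000):
resimulate y from N(Xβ̂, V̂), refit, take percentile intervals. Levels
estimated at the σ² = 0 boundary keep a degenerate lower bound of 0.
Percentile intervals stabilise rather than narrow as B grows, so the
bootstrap sanity checks assert containment and reproducibility, not
width decay.

## Publication-bias diagnostics

Egger's test regresses the standardized effect y/SE on precision 1/SE
by OLS; the intercept estimates funnel asymmetry and is tested with a
normal z. A precision-weighted variant (effect on SE, weighted 1/v) is
available for sensitivity, since asymmetry tests differ across
implementations. Trend regressions of effect on publication year and
journal impact factor are unweighted OLS with t on k−2 df over the
rows where the covariate exists (a precision-weighted option exists).
The funnel export carries (effect, SE) pairs, the fixed-effect pooled
mean and pseudo-CI envelopes mean ± z·SE at 95% and 99.8%.

## Synthetic-data generator

The generator emulates the *meta-dataset layer* only — study labels,
moderators and two-group summaries — not the underlying evolution
experiments. Per record, a true effect θ = x'β + u_study + u_trait +
u_taxon (+ u_effect) is drawn with independent normal level
deviations; a baseline mean μ_l ~ U(5, 15) and a within-group CV ~
U(cv_range) set s = CV·μ in both groups (a positive mean–variance
relationship, which is what makes lnCVR and lnVR behave differently);
the high-group mean is placed so the population standardized
difference equals θ exactly; then the observed mean is drawn
N(μ, s²/n) and the observed SD via a scaled χ²_{n−1} draw. Computed
Hedges' g therefore has expectation θ to first order and the analytic
variance formulas hold. A single global seed is split deterministically
per record, so datasets are bit-reproducible and stable under partial
regeneration.

Defaults describe a realistic synthesis: 10–60 individuals per group,
CVs 0.1–0.4, a skewed number of effects per study, and a moderator
mix dominated by benign-environment assays.

`generate_paperlike` fixes the marginal layout of the motivating
459-effect synthesis exactly: 65 studies (1–30 effects each via a
preferential-attachment partition), 22 fitness components with a
self-consistent trait→fitness-class map, 7 taxa assigned per study,
sex counts 189/219/51, environment counts 92/337/30 (30 undefined),
354 records with summaries and 105 reported as statistics (70 t, 25
F, 8 χ², 2 proportions), and 20 records without year/impact factor so
trend regressions carry 437 df. Its ground truth uses
sex-by-environment fixed effects of realistic magnitude
(0.19, 0, 0.11, −0.16, 0.18, 0.26) and variance components
(σ²_study = 0.60, σ²_trait = 0.007, σ²_taxon = 0.023,
σ²_effect = 0.96) that put ~95% of variance into heterogeneity with a
study-dominated partition, as is typical for ecology/evolution
syntheses.

**What passing tests on synthetic data do and do not show.** The
generator draws exactly normal group samples with variances tied to
the analytic formulas, so recovery and calibration results validate
the estimation machinery under its own assumptions. Real datasets add
non-normal traits, digitisation error, correlated effect sizes within
shared control groups, and selective reporting — none of which the
generator emulates, so synthetic performance is a necessary, not
sufficient, indication of real-data behaviour.

**Known second-order limitation.** Hedges'-g sampling variances are
plug-in estimates correlated with the observed effects; REML treats
them as known. At group sizes of 10–60 this depresses σ̂²_study by
roughly 4% (measured −0.0015 on a true 0.04 across 200 replicates of
200 studies × 3 effects), while the same engine on data simulated
from the exact known-variance model is unbiased (−0.0001 ± 0.0005)
and β̂ and its CI coverage are unaffected. This is the familiar
"estimated v treated as known" artifact of standardized-mean-
difference meta-analysis, visible here only because the Monte-Carlo
resolution (~1%) is finer than the artifact.

## Problem sizes used in the test suite

The Monte-Carlo recovery experiment uses 200 replicates of 200
studies × 3 effects (10 trait and 6 taxon labels to keep the
between-replicate variance of β̂ modest); Egger type-I calibration
uses 5000 replicates of k = 100 symmetric-funnel datasets; bootstrap
checks use small B (15–40) since they test mechanics, not CI
accuracy. These sizes give 2-SE Monte-Carlo resolution below 0.01 on
β̂ while keeping the suite comfortably reproducible on a laptop.
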