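# Methods

## The problem

A performance-based financing (PBF) scheme pays facilities a quarterly
bonus B = Σᵢ qᵢ·pᵢ over nine incentivized service indicators. Facilities
self-report the quantities qᵢ; independent verification reconstructs them
from registers and tally sheets. The package studies the regulator's
targeting problem: given a fixed audit budget, which facilities should be
verified so that as many over-reporters as possible are caught, and what
is that worth in money?

## The over-reporting label

A facility-quarter is labeled over-reporting when the reported bonus
exceeds the verified bonus by a relative excess of at least τ = 0.10. The
boundary is inclusive ("10% or more"): equality at exactly 1.1× flags.
Because the product (1 + τ)·B_verified is subject to float rounding, the
comparison uses a 10⁻¹² relative tolerance so that an arithmetically
exact boundary case is classified as inclusive on every platform. A
positive reported bonus against a zero verified bonus is flagged by
default (`zero_verified_rule`): the relative excess is infinite and a
claim against zero delivered services is the clearest gaming signal. The
label is computed at the bonus level, not per indicator, so a facility
that inflates cheap indicators while under-reporting expensive ones can
net out below the threshold — that is a property of the labeling rule
itself, not of this implementation.

## The synthetic panel generator

No operational verification dataset is public, so the generator is the
package's test bed. It emulates the marginal structure such data exhibit.

**Population.** `n_facilities` (default 140) facilities are spread
round-robin over 10 PBF and 8 non-PBF districts, with 75% of facilities
in PBF districts. Covariates: facility type (8 levels), managing
authority (3), location (rural / peri-urban / urban), catchment
population (log-normal, median e⁹ ≈ 8,100), established and filled
posts. PBF facilities are randomized over audit-probability arms {10, 30,
100}%; non-PBF facilities always have arm 0.

**Who games.** Each facility belongs to a gaming-frequency class
k ∈ {0,…,4}: the number of quarters it over-reports. Class shares default
to 81/140, 32/140, 12/140, 9/140, 6/140 and are apportioned exactly
(largest-remainder), which pins the never-offender share at 57.9% and the
mean quarterly prevalence at (0·81+1·32+2·12+3·9+4·6)/560 ≈ 19.1% by
construction. Which facilities land in the gaming classes is driven by a
latent risk index with a deliberate threshold-interaction form: gaming
concentrates where exactly one of {large catchment, severe
understaffing} holds (an exclusive-or), plus Gumbel noise. The XOR makes
gaming propensity non-representable by any additive logistic function of
the covariates, so a tree ensemble can exploit the covariates while a
linear model cannot — the generator plants the non-linearity that risk
modeling debates in this field turn on. An alternative mechanism
(`gaming_mechanism="additive"`) makes each quarter an independent
Bernoulli draw with log-odds linear in the covariates; under it a
logistic model is well-specified and matches the forest, which the test
suite checks as the complementary case.

**When they game.** A facility with k gaming quarters places them
sequentially: the first gamed quarter is uniform over the four; each
subsequent one is drawn with weight `persistence` (default 0.577) if
adjacent to an already-gamed quarter and weight equal to the
unconditional prevalence otherwise. This is the simplest mechanism with
two required properties: (i) when persistence exceeds prevalence, gamed
quarters cluster serially, reproducing conditional over-reporting rates
of the observed magnitude (≈0.58 for adjacent quarters); (ii) when
persistence equals prevalence the draw is uniform over k-subsets, which —
combined with a Binomial(4, π) class distribution — makes the quarter
flags i.i.d., giving an exact independence limit the tests verify.
A single persistence parameter cannot reproduce a full 4×4 asymmetric
conditional matrix; calibration targets the adjacent-quarter rate only.

**Counts.** Verified counts are negative binomial with per-indicator
means scaled by catchment population (default means 45–180 services per
quarter, a tuberculosis-type rare indicator at 6) and dispersion 8 —
overdispersion typical of facility-level service volumes. Defaults were
chosen so a median facility's quarterly bonus is near $1,900, the
sanction magnitude used in the cost examples.

**Reports.** In honest quarters each reported count is the verified count
perturbed by an independent relative error uniform in ±`honest_noise`
(default 0.05). In gamed quarters all nine counts are inflated by a
common factor drawn from `inflation_range` (default [1.15, 1.60]). The
config validator enforces honest_noise < τ < inflation lower bound − 1,
so the label reproduces the latent gaming flag exactly: honest bonus
ratios cannot reach 1.10 and gamed ratios cannot fall below 1.15.
Reported counts are kept as floats (verified counts are integers);
rounding honest reports to integers could push a tiny facility across the
threshold and break the exactness. A gamed quarter whose verified counts
are all zero receives a small fabricated positive report so the
zero-verified rule still flags it. Per-indicator (selective) gaming is
out of scope — the label operates at the bonus level, so the generator
games at the bonus level too.

**What passing tests do not show.** Real verification data have
features the generator omits: under-reporting, recording and transcription
errors that are not mean-zero, selective inflation of high-price
indicators, audit-arm behavioral responses, and covariate-gaming
relationships of unknown form. Results on synthetic panels validate the
machinery (labeling arithmetic, sampling distributions, estimator
plumbing) and the qualitative ordering of strategies under persistence —
not the numerical accuracy any classifier would attain on a real program.

## Audit strategies

Fractional sample sizes round half-up (per stratum for the stratified
scheme; the default 50% of 140 is exact). The mixed offender design draws
⌈target/2⌉ from prior offenders; if fewer exist, the shortfall moves to
the non-offender draw so the plan size stays at the 28-facility target.
The offenders-first design subsamples offenders only when they exceed the
target. "Prior" always means the immediately preceding quarter.
Model-ranked selection takes the top-k by risk score with ties broken by
a seeded shuffle followed by a stable sort, so equal scores cannot leak
input order. All strategies take explicit seeds; nothing touches global
random state.

## Classifiers

scikit-learn provides the estimator internals; the module owns the
encoding, the grids, the seeding and the score interface. One-hot
encoding uses fixed level sets so feature schemas are identical across
quarters and panels, and a fitted model refuses a matrix whose columns do
not match its training schema. Risk scores are `predict_proba` of the
positive class (Platt scaling for the SVM), thresholded at 0.5 for class
predictions.

Two variants are hand-written because no installed library provides them:
a kernel naive Bayes (per-class, per-feature Gaussian KDE, Silverman
bandwidth with a 10⁻³ floor so one-hot point masses stay defined) and a
supervised discretizer for the discretized naive Bayes (equal-frequency
candidate binnings scored by class-conditional entropy with a log₂(n)/n
per-cut penalty, followed by a categorical naive Bayes).

The ridge grid maps λ ∈ {0, 10⁻⁵, …, 10⁻²} to C = 1/λ (C = ∞
unpenalized). Grid search is exhaustive, scored by stratified k-fold CV
accuracy, ties to the earlier (smaller) grid entry; a degenerate
validation fold triggers one re-seeded retry before erroring. No
class-imbalance correction is applied beyond stratified folds.

The feature sets: `basic` (9 reported + 9 verified counts, district,
audit arm), `expanded` (+6 facility covariates), plus `reported_only` and
`covariates_only`. The basic/expanded sets include verified counts as
predictors, which is circular for facilities that have not been audited —
verification is what produces those values. They remain the default
because they represent the regulator's retrospective analysis setting;
`reported_only` is the honest prospective configuration. Note that with
both count blocks present, the label is a deterministic function of the
features (the bonus ratio), so high in-sample metrics there measure
signal recovery, not generalization to unaudited facilities.

## Evaluation

Accuracy, per-class precision/recall and macro-F1 (mean over classes of
the per-class harmonic mean) are computed directly from the confusion
matrix; an absent true class yields NaN, never zero. ROC points come from
a threshold sweep with tied scores collapsed to one step; AUC is the
trapezoid area, cross-checked against scikit-learn in the tests.
Cross-validation averages the k per-fold metric values rather than
pooling predictions. Detection yield of a sampling strategy is averaged
over 1,000 independent iterations, with per-iteration seeds spawned from
a master seed via `SeedSequence`. The comparison table mixes two metric
kinds by design — detection yield for sampling rows, classification
accuracy for model rows — and records the kind per row explicitly.

## Cost model

tc = n[p(mc − s) + (1 − p)mc] + fc, with the per-facility form
mc − p·s + afc (exactly tc/n when afc = fc/n). The standard example uses
mc = $800, s = $1,900 (the detected over-reporter forfeits a full
quarterly bonus), afc = $1,600: p = 0.19 costs $2,039 per facility,
p = 0.88 costs $728 — a ~64% saving. The deterrence channel (future
over-reporting declining as detection improves) is deliberately not
modeled; it has no agreed functional form, so the model prices only the
direct sanction-recovery channel. The `full` pipeline uses a model's
classification accuracy as its detection probability p when pricing
classifier targeting, consistent with how such comparisons are usually
presented; yield-based p for model-ranked plans is available through the
library API.

## Problem sizes and determinism

Default test and pipeline sizes: 140-facility panels, 1,000 sampling
iterations, 10-fold CV; calibration property tests use 2,000–5,000
facilities where a tight Monte-Carlo standard error matters, and the
strategy-ordering check averages 12 independent default-sized panels to
damp panel-level noise. Every stochastic component takes an explicit seed
and the whole pipeline is byte-reproducible given the master seed (named
substreams derived via CRC-salted `SeedSequence`).

## Known limitations

- Marginal calibration only: the generator matches frequency-class and
  adjacent-quarter persistence targets, not a full joint label
  distribution.
- The planted XOR gaming mechanism is one stylized non-linearity; real
  covariate-gaming relationships are unknown and likely messier.
- Prices default to plausible magnitudes for a rural primary-care
  program; analyses that depend on the price vector should supply their
  own schedule.
- Sanction recovery assumes full collection; partial or tiered sanctions
  can be represented only by rescaling s.
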