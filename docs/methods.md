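# Methods

## Response speed and exclusion filtering

The unit of observation is the participant-visit. Response speed is the total
word count of responded variables divided by the elapsed survey time in
seconds (words/s); word counts are taken as given — reproducing the survey
engine's skip logic is out of scope. Visit indices are mapped to coded time
t = 0, 1, … (visit 50 ↦ 0 in the default window); this is the single time
convention used everywhere.

Three exclusion filters run in a fixed order — missing start time, missing
end time, illogical times — and are mutually exclusive, so the cleaning
report partitions the input exactly and sequential exclusion arithmetic can
be reproduced to the record. "Illogical" means duration ≤ 0 or above a 24 h
cap (configurable): timestamps are interpreted on one calendar day, so an
evening start with a morning end is a negative duration, not a midnight
wrap; a wrap-tolerant mode is deliberately not provided, and the cap guards
against multi-day artefacts. Participants are never dropped for contributing
few visits: the trajectory model handles unbalanced panels.

## Group-based trajectory model

The mixture assumes, conditional on latent group j, independent normal
residuals around a polynomial mean trajectory, with a residual SD shared
across groups by default (per-group SDs behind `shared_sigma=False`). The
outcome density is a *plain* normal rather than the censored normal of the
classic SAS implementation: response speeds here are strictly positive and
uncensored, so censoring machinery would never bind. The default polynomial
order is cubic for every group.

Estimation is EM with multiple restarts. The first start is deterministic:
participants are ranked by mean speed (linear-trend tiebreak) and split into
K quantile blocks; later starts perturb the ranking scores with seeded
noise. The E-step computes posterior responsibilities per participant; the
M-step solves responsibility-weighted polynomial least squares per group,
sets mixing proportions to responsibility means (floored at 1e-6 and
renormalised, with collapse reported), and pools weighted residuals for σ.
Convergence is a relative log-likelihood change below 1e-8, capped at 500
iterations; if no start converges the best iterate is returned flagged.
Fitted groups are relabelled by ascending intercept so reported labels are
deterministic; the likelihood itself is label-invariant.

BIC is computed as `log L − ½·k·ln(n)` with `k = K(order+1) + (K−1) + 1`
(shared σ) and n = number of participants, so "largest negative BIC" means
maximal BIC. The per-observation-n alternative sits behind
`GbtmSpec(bic_n="observations")`, since which n the criterion should use is
genuinely ambiguous for panel data. Ties in model selection break toward the
smaller K.

## Two-step satisficer classification

"Accelerating over the recent visits" is inherently a judgement about a
plotted trajectory; the classifier operationalises it from the fitted
polynomial as: derivative at the final visit > 0 **and** fitted rise over
the trailing window (default 2 visits) above δ, with δ defaulting to 0.1·σ̂.
This reproduces the qualitative calls the method is meant to make — a group
with an early rise but a declining end is rejected (overall decreasing
pattern), a late acceleration after a dip is accepted. The δ default is this
package's choice; no numeric threshold exists in the source analysis, and δ
is exposed in `ClassifierConfig` with satisficer counts monotonically
non-increasing in δ.

Step 1 selects K over 1..5 on the whole cohort, hard-assigns by maximum
posterior (ties to the lowest group index), and carries *every* flagged
group into step 2 independently. Step 2 reruns selection inside each
candidate; members of flagged subgroups are satisficers, everyone else is
not, so the labels always partition the cohort. A candidate group smaller
than 10·max(K) members skips the refit and is labelled satisficer wholesale
with a warning — mixture fits on tiny groups are unstable. Reported
percentages round half-up to two decimals.

## Repeated-measures association models

The satisficing label is participant-constant but observed over repeated
visits; associations are estimated with GEE logistic models, exchangeable
working correlation, robust sandwich SEs clustered by participant, Wald 95%
CIs and p-values, no multiple-testing adjustment. Reference levels are
fixed (white / college / HIV-negative / no sexual activity / no drug use)
and baseline age enters centred and divided by 10, so its OR is per 10-year
increase (centring does not affect that OR). Rows with missing visit-level
covariates are dropped listwise with a logged count. A random-intercept
logistic model would be the conditional-effects alternative; the marginal
GEE is the default because population-level ORs are the target.

**A degeneracy worth knowing about**: with a participant-constant outcome
the estimated exchangeable correlation approaches 1, and the exchangeable
weighting then discards within-participant contrasts — coefficients of
*visit-level* covariates (sexual activity, drug use) are shrunk toward zero
essentially regardless of their true marginal association. Participant-level
covariates (age, race, education, HIV) are unaffected. For visit-level
effects use `fit_repeated_logistic(..., cov_struct="independence")`, which
keeps the robust clustered SEs and recovers marginal effects. The crude 2×2
odds ratio with a Woolf CI (`or_from_2x2`) is retained as an independent
oracle: with one visit per participant and a single binary covariate the
GEE estimate equals it exactly.

## Synthetic cohorts

The generator emulates the structure of the motivating semiannual cohort:
~2000 participants, 9 visits, three latent speed groups with means near 2, 4
and 6 words/s and mixing proportions 0.378 / 0.490 / 0.131, within-group
cubic time trends (slow group flat then rising late; middle declining then
flat; fast declining overall after an early rise), ~23.5% missing visits,
and timestamp corruption at the observed exclusion rates. Corruption uses
without-replacement quota sampling — exact counts, not i.i.d. Bernoulli —
so fixtures can reproduce printed exclusion arithmetic digit for digit.
`subgroup_study_config()` additionally splits the slow group into its three
subgroups (4.33% / 62.79% / 32.88% of the group): a small rapidly
accelerating one, a large dip-then-accelerate one, and a nearly constant
one; the first two are the planted satisficers (marginal share 25.40%).

Observed speed at a visit is μ_j(t) + ε with ε ~ Normal(0, σ), truncated to
stay positive; duration is N/speed and the timestamps are laid out
consistently before corruption, so the analysis pipeline recovers the
planted speed up to timestamp resolution (exactly, when N/μ lands on whole
microseconds). σ defaults to 0.5 words/s — small enough that the three
cohort-level groups are well separated (≥ 4σ), realistic in that the
within-group subgroups overlap. Word counts are Poisson around the
questionnaire size (default 2400 words) with a 360-word drop from coded
time 6 onward, emulating the shortened late-window questionnaire; the
source analysis reports no word-count distribution, so this model is a free
choice of this package. Covariates follow the cohort's published margins
(age ~ Normal(51, 9.6); race 0.627/0.249/0.124; education
0.179/0.466/0.355; HIV 0.5). Membership in the satisficing-prone groups is
a binary logit tilted by the covariates with log-odds set to the published
multivariate odds ratios, centred so the marginal share stays at the
configured mixing mass (exact only to first order: the logit's
nonlinearity adds a small Jensen gap, ~1 percentage point at the default
settings). Visit-level behaviours derive from a stable participant-level
propensity redrawn per visit with probability 0.2.

### What the synthetic cohorts do not emulate

Question-level latencies, skip-logic-driven word-count dependence on the
answers themselves, site effects (the real missing-end-time records
clustered at one site), calendar drift, drop-out correlated with speed, and
any non-normal speed noise. Passing recovery tests therefore shows the
estimators are correct under the stated model, not that the model captures
every feature of real paradata.

## Problem sizes and observed behaviour

Tests and the acceptance script use n = 120–2000 participants, K ≤ 5, 20
replicates for the BIC-consistency study and 200 for GEE null calibration —
sizes at which every documented guarantee is exercised in minutes on one
CPU. Under the default noise level the dip-then-accelerate and constant
subgroups of the slow group overlap; the classifier then attains
sensitivity ≈ 1 but labels part of the constant subgroup as satisficers,
inflating prevalence (and attenuating downstream ORs through
misclassification). This is a property of the method under overlap, shown
honestly by `scripts/acceptance.py`; with ≥ 3σ separation between the
accelerating subpopulation and the rest, sensitivity and specificity both
exceed 0.9 and prevalence error stays within 5 points (the planted-recovery
test).

## Known limitations

- The classifier's δ and window defaults are reasoned choices, not estimated
  quantities; cohorts with different visit spacing may need both adjusted.
- BIC selection is only shown consistent at desk scale under clear
  separation; heavily overlapping groups can legitimately select fewer
  groups than planted.
- The exchangeable-GEE degeneracy above means visit-level behavioural ORs
  from the default estimator should not be interpreted.
- Speeds are modelled as normal within group; strongly skewed speed
  distributions would call for a transformed outcome.
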