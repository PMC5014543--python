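# trajsat

Detecting **survey satisficing** — answering questions quickly without reading
or comprehending them — in *longitudinal* cohorts, from interview paradata
alone.

Single-survey satisficing indicators (straightlining, instructional
manipulation checks, response-latency thresholds) do not transfer to a panel
study in which near-identical questionnaires are administered twice a year
for decades: respondents learn the instrument, and speed thresholds
calibrated on one questionnaire are meaningless for the next. `trajsat`
instead treats a participant's **response speed** across visits as a
trajectory and flags participants whose speed *accelerates* over the recent
visits. It is aimed at epidemiologists and survey methodologists running
long-standing cohort studies (semiannual ACASI behavioural interviews and
similar) who have timestamps and word counts but no gold-standard labels.

## Method

For participant-visit records with start/end timestamps and the total word
count *N* of responded variables, the per-visit response speed is

```
speed = N / T        (words per second; T = elapsed survey time in seconds)
```

after excluding records with a missing start time, missing end time, or
illogical timestamps (end ≤ start, duration > 24 h), in that order.

Speed panels are modelled with a **group-based trajectory model** — a finite
mixture of K latent groups, each with a polynomial mean trajectory over coded
visit time t (first visit ↦ 0) and normal residuals:

```
y_it | group j ~ Normal( Σ_m β_jm t^m , σ² )
log L = Σ_i log Σ_j π_j Π_t φ((y_it − μ_j(t)) / σ) / σ
```

fitted by EM on unbalanced panels, with K chosen by BIC in the convention
`BIC = log L − ½·k·ln(n)` (the largest, i.e. least negative, BIC wins).

**Satisficers are identified in two steps**: (1) fit the cohort-level mixture
and flag groups whose fitted trajectory accelerates over the recent visits
(positive derivative at the final visit *and* a rise above a margin δ over
the trailing window); (2) refit a mixture inside each flagged group and label
members of its accelerating subgroups as satisficers.

Covariate associations with the resulting binary label are estimated with
**repeated-measures logistic models** (GEE: exchangeable working correlation,
robust standard errors clustered by participant), reported as odds ratios
with Wald 95% CIs.

Because the motivating cohort's individual-level data are restricted, the
package ships a **synthetic-cohort generator** with planted trajectory
groups, covariate effects, missing visits, and timestamp corruption, so every
stage is testable against known truth.

## Worked example

`examples/03_fit_trajectories.py` simulates 600 participants from the
three-group default configuration, selects K by BIC and prints:

```
BIC comparison:
  K=1: loglik -9286.9, BIC -9302.9
  K=2: loglik -6416.4, BIC -6448.4
  K=3: loglik -4546.4, BIC -4594.3
  K=4: loglik -4545.8, BIC -4609.8
  K=5: loglik -4541.9, BIC -4621.9
selected K = 3, shared sigma = 0.503 words/s
fitted mean speeds at visits 50..58:
[[2.01 2.07 2.06 2.03 2.   2.   2.06 2.21 2.47]
 [4.41 4.25 4.12 4.02 3.94 3.89 3.86 3.86 3.89]
 [6.07 6.22 6.2  6.06 5.82 5.53 5.22 4.92 4.66]]
```

K = 3 maximises the BIC, and the three fitted rows recover the planted
shapes: a slow group flat near 2 words/s that rises over the last two visits
(the satisficing-prone pattern), a middle group declining from ~4.4 and
flattening, and a fast group declining overall from ~6. The recovered σ
matches the planted 0.5 words/s.

The other examples cover simulation and corruption (`01`), cleaning and
speed computation (`02`), the two-step classification with its summary table
(`04`), GEE odds ratios against planted effects (`05`), and the one-seed
reproducible pipeline (`06`).

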