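"""Estimate covariate associations with satisficing via repeated-measures GEE.

The panel has one row per participant-visit with a participant-constant
satisficing outcome; GEE logistic models with exchangeable working
correlation and robust clustered standard errors give population-level odds
ratios with Wald 95% confidence intervals.
"""

from trajsat import (
    build_panel,
    clean_visits,
    fit_repeated_logistic,
    generate_cohort,
    subgroup_study_config,
    table1_summary,
)
from trajsat.classify import SatisficingResult

config = subgroup_study_config(seed=11, n_participants=1500)
cohort = generate_cohort(config)
kept, _ = clean_visits(list(cohort.records))

# use the planted labels here to show undiluted effect recovery
truth = cohort.true_satisficer
labels = SatisficingResult(
    label=dict(truth),
    step1_group={p: 0 for p in truth},
    step2_subgroup={p: None for p in truth},
    n_total=len(truth),
    n_satisficers=sum(truth.values()),
    provenance={},
)

panel = build_panel(labels, kept, cohort.participants)
table = fit_repeated_logistic(
    panel, covariates=["baseline_age", "race", "education", "hiv"], mode="multivariate"
)
print(table[["covariate", "level", "OR", "ci_low", "ci_high", "p_value"]]
      .round(3).to_string(index=False))

t1 = table1_summary(labels, cohort.participants)
print("\nbaseline age by satisficing status:")
print(t1.age.round(1).to_string(index=False))
# The ORs estimate the planted membership log-odds (age per 10 y: 1.44,
# black vs white: 2.22, less-than-college vs college: 1.67, HIV+: 1.13);
# estimates should cover those values within sampling error at this n.
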