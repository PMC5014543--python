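"""Identify satisficers with the two-step trajectory classification.

Step 1 fits a cohort-level mixture and flags groups whose fitted speed
accelerates over the recent visits; step 2 refits inside each flagged group
and labels members of accelerating subgroups as satisficers.
"""

from trajsat import (
    ClassifierConfig,
    GbtmSpec,
    build_series,
    clean_visits,
    generate_cohort,
    subgroup_study_config,
    summarize,
    two_step_classify,
)

config = subgroup_study_config(seed=11, n_participants=800)
cohort = generate_cohort(config)
kept, _ = clean_visits(list(cohort.records))
series = build_series(kept)

result = two_step_classify(
    series, ClassifierConfig(step1_spec=GbtmSpec(n_starts=2, seed=3))
)
print(summarize(result).to_string(index=False))

truth = cohort.true_satisficer
sens = sum(result.label[p] and truth[p] for p in result.label) / sum(truth.values())
print(f"\ncandidate groups in step 1: {result.provenance['candidate_groups']}")
print(f"sensitivity against the planted satisficers: {sens:.2f}")
# The summary's satisficer percentage is driven by the two accelerating
# subgroups planted inside the slow group (true marginal share 25.4%);
# sensitivity is high, while overlap between the dip-then-accelerate and the
# constant subgroup can pull extra members into the satisficer label.
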