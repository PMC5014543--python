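"""Generate a synthetic interview-paradata cohort and write it to CSV.

The cohort emulates a semiannual behavioural-survey panel: three latent
response-speed groups (means near 2, 4 and 6 words/s), missing visits, a
questionnaire that shrinks late in the window, and timestamp corruption.
"""

from trajsat import SynthConfig, generate_cohort, inject_timestamp_errors
from trajsat.synth import write_cohort_csvs

config = SynthConfig(n_participants=500, seed=42)
cohort = generate_cohort(config)
cohort, log = inject_timestamp_errors(cohort, config.corrupt_rates, seed=43)
write_cohort_csvs(cohort, "visits.csv", "participants.csv")

n_groups = len(config.true_pi)
print(f"participants: {cohort.n_participants}, visit records: {len(cohort.records)}")
for j in range(n_groups):
    share = sum(g == j for g in cohort.true_group.values()) / cohort.n_participants
    mean = config.group_means().mean(axis=1)[j]
    print(f"  group {j}: share {share:.1%}, mean speed {mean:.2f} words/s")
print(f"corrupted records: { {k: len(v) for k, v in log.items()} }")
# The shares track the configured mixing proportions (0.378/0.490/0.131) up
# to binomial noise; the corruption counts are exact quotas of the rates.
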