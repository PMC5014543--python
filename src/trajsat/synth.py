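"""Synthetic longitudinal interview-paradata cohorts with planted trajectory groups.

The real cohort data behind this analysis are restricted, so every downstream
stage is exercised on synthetic cohorts that emulate their structure: ~2000
participants observed at 9 semiannual visits, three latent response-speed
groups with means near 2, 4 and 6 words/s, within-group polynomial time
trends, missing visits, record corruption (missing start time, missing end
time, end before start), a questionnaire that shrinks by ~30 questions late
in the window, and socio-demographic covariates whose log-odds of membership
in the slow (satisficing-prone) groups match the reported association sizes.

Latent-group membership is a participant-level draw: a binary logit decides
membership in the satisficing-prone groups (tilted by covariates, centred so
the marginal matches the configured mixing proportions), and within each arm
the specific group is drawn proportionally to the configured proportions.

Observed speed at a visit is mu_g(t) + eps with eps ~ Normal(0, sigma)
truncated so the speed stays positive; the survey duration is then
word_count / speed, and start/end timestamps are laid out consistently with
that duration before any corruption is injected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .ingest import VISIT_BASE, VisitRecord

__all__ = [
    "CovariateModel",
    "SynthConfig",
    "SyntheticCohort",
    "ConfigError",
    "generate_cohort",
    "inject_timestamp_errors",
    "subgroup_study_config",
    "poly_from_visit_means",
]


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration; the message names the field."""


def poly_from_visit_means(means, order: int = 3) -> tuple[float, ...]:
    """Cubic (by default) coefficients, ascending powers of coded time, fitted
    through per-visit mean speeds.  Used to turn the qualitative trajectory
    shapes of the study cohort into the polynomial form the generator needs."""
    means = np.asarray(means, dtype=float)
    t = np.arange(len(means), dtype=float)
    return tuple(np.polynomial.polynomial.polyfit(t, means, order))


# Archetype per-visit mean speeds (words/s) over coded times 0..8 for the three
# cohort-level groups: slow group flat near 2 then rising over the last visits,
# middle group declining from ~4.4 and flattening near 3.9, fast group with an
# early rise then an overall decline from ~6.
_SLOW_RISING = (2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.05, 2.2, 2.5)
_MID_DECLINING = (4.4, 4.25, 4.1, 4.0, 3.95, 3.9, 3.9, 3.9, 3.9)
_FAST_DECLINING = (6.0, 6.2, 6.25, 6.1, 5.8, 5.5, 5.2, 4.9, 4.6)

# Reported multivariate odds ratios of satisficing, used as the default planted
# log-odds of membership in the satisficing-prone groups.
_DEFAULT_GROUP_LOGODDS = {
    "age_per10": math.log(1.44),
    "race_black": math.log(2.22),
    "race_other": math.log(1.99),
    "edu_lt_college": math.log(1.67),
    "edu_gt_college": math.log(0.83),
    "hiv_pos": math.log(1.13),
    "sex_one": math.log(0.85),
    "sex_multiple": math.log(0.76),
    "drug_one": math.log(1.02),
    "drug_multiple": math.log(0.72),
}


@dataclass(frozen=True)
class CovariateModel:
    """Baseline and visit-level covariate distributions plus their planted
    log-odds of satisficing-group membership.

    Category probabilities default to the study cohort's margins (median
    baseline age 51, IQR 45-58; 62.7% non-Hispanic white; 46.6% college
    graduates; 50% HIV seropositive).  Visit-level behaviours are generated
    from a stable per-participant propensity category, redrawn per visit with
    probability ``1 - visit_stability``.
    """

    age_mean: float = 51.0
    age_sd: float = 9.6
    race_probs: tuple[float, float, float] = (0.6272, 0.2493, 0.1235)  # white/black/other
    education_probs: tuple[float, float, float] = (0.1791, 0.4659, 0.3550)  # lt/college/gt
    hiv_pos_prob: float = 0.50
    sexual_activity_probs: tuple[float, float, float] = (0.35, 0.35, 0.30)  # none/one/multiple
    drug_use_probs: tuple[float, float, float] = (0.60, 0.25, 0.15)
    visit_stability: float = 0.8
    group_logodds: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_LOGODDS)
    )


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic cohort.

    ``true_beta`` holds per-group polynomial coefficients (ascending powers of
    coded time, words/s); ``true_pi`` the group mixing proportions, which must
    sum to 1.  ``satisficer_groups`` lists the group indices whose members are
    the planted satisficers — the groups whose trajectories accelerate over
    the recent visits.  ``corrupt_rates`` are the fractions of records given a
    missing start time, missing end time, and end-before-start timestamps.
    ``word_count_drop`` is subtracted from the expected word count from coded
    time ``drop_at`` onward, emulating the shortened late-window questionnaire.
    """

    n_participants: int = 2000
    n_visits: int = 9
    true_pi: tuple[float, ...] = (809 / 2138, 1048 / 2138, 281 / 2138)
    true_beta: tuple[tuple[float, ...], ...] = (
        poly_from_visit_means(_SLOW_RISING),
        poly_from_visit_means(_MID_DECLINING),
        poly_from_visit_means(_FAST_DECLINING),
    )
    sigma: float = 0.5
    satisficer_groups: tuple[int, ...] = (0,)
    visit_missing_rate: float = 0.235
    corrupt_rates: tuple[float, float, float] = (14 / 14722, 1887 / 14722, 34 / 14722)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    base_word_count: int = 2400
    word_count_drop: int = 360
    drop_at: int = 6
    seed: int = 20160808

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        if self.n_visits < 2:
            raise ConfigError("n_visits must be at least 2")
        pi = np.asarray(self.true_pi, dtype=float)
        if (pi < 0).any():
            raise ConfigError("true_pi entries must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ConfigError(f"true_pi must sum to 1 (got {pi.sum()!r})")
        if len(self.true_beta) != len(pi):
            raise ConfigError("true_beta must have one coefficient vector per group")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if not 0 <= self.visit_missing_rate <= 1:
            raise ConfigError("visit_missing_rate must lie in [0, 1]")
        for name, rate in zip(
            ("missing_start", "missing_end", "illogical"), self.corrupt_rates
        ):
            if not 0 <= rate <= 1:
                raise ConfigError(f"corrupt_rates[{name}] must lie in [0, 1]")
        if sum(self.corrupt_rates) > 1:
            raise ConfigError("corrupt_rates must sum to at most 1")
        if any(g < 0 or g >= len(pi) for g in self.satisficer_groups):
            raise ConfigError("satisficer_groups indices out of range")
        if self.base_word_count < 1:
            raise ConfigError("base_word_count must be positive")
        if not 0 <= self.drop_at:
            raise ConfigError("drop_at must be nonnegative")

    def group_means(self, times: np.ndarray | None = None) -> np.ndarray:
        """Planted mean speed per group evaluated on coded times (default 0..n_visits-1)."""
        if times is None:
            times = np.arange(self.n_visits, dtype=float)
        return np.vstack(
            [np.polynomial.polynomial.polyval(times, b) for b in self.true_beta]
        )


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: visit records, participant table, and ground truth."""

    records: tuple[VisitRecord, ...]
    participants: pd.DataFrame  # participant_id, baseline_age, race, education, hiv
    true_group: dict[str, int]
    true_satisficer: dict[str, bool]

    @property
    def n_participants(self) -> int:
        return len(self.true_group)


def _centred_logit_offset(cov: CovariateModel) -> float:
    """Expected covariate contribution to the membership logit, subtracted so
    the marginal satisficer share matches the configured mixing proportions."""
    lo = cov.group_logodds
    pr, pe = cov.race_probs, cov.education_probs
    ps, pd_ = cov.sexual_activity_probs, cov.drug_use_probs
    return (
        pr[1] * lo["race_black"]
        + pr[2] * lo["race_other"]
        + pe[0] * lo["edu_lt_college"]
        + pe[2] * lo["edu_gt_college"]
        + cov.hiv_pos_prob * lo["hiv_pos"]
        + ps[1] * lo["sex_one"]
        + ps[2] * lo["sex_multiple"]
        + pd_[1] * lo["drug_one"]
        + pd_[2] * lo["drug_multiple"]
    )  # age is centred, so its expected contribution is 0


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Generate a cohort according to ``config``; deterministic in (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    cov = config.covariates
    lo = cov.group_logodds

    pids = [f"P{i:05d}" for i in range(n)]
    age = rng.normal(cov.age_mean, cov.age_sd, size=n)
    race = rng.choice(["white", "black", "other"], size=n, p=cov.race_probs)
    education = rng.choice(
        ["lt_college", "college", "gt_college"], size=n, p=cov.education_probs
    )
    hiv = np.where(rng.random(n) < cov.hiv_pos_prob, "pos", "neg")
    sex_typ = rng.choice(["none", "one", "multiple"], size=n, p=cov.sexual_activity_probs)
    drug_typ = rng.choice(["none", "one", "multiple"], size=n, p=cov.drug_use_probs)

    # Membership in the satisficing-prone groups via a centred binary logit.
    pi = np.asarray(config.true_pi, dtype=float)
    sat_idx = np.asarray(config.satisficer_groups, dtype=int)
    other_idx = np.array(
        [j for j in range(len(pi)) if j not in set(config.satisficer_groups)], dtype=int
    )
    p_sat = pi[sat_idx].sum()
    eta = (
        (age - cov.age_mean) / 10.0 * lo["age_per10"]
        + np.where(race == "black", lo["race_black"], 0.0)
        + np.where(race == "other", lo["race_other"], 0.0)
        + np.where(education == "lt_college", lo["edu_lt_college"], 0.0)
        + np.where(education == "gt_college", lo["edu_gt_college"], 0.0)
        + np.where(hiv == "pos", lo["hiv_pos"], 0.0)
        + np.where(sex_typ == "one", lo["sex_one"], 0.0)
        + np.where(sex_typ == "multiple", lo["sex_multiple"], 0.0)
        + np.where(drug_typ == "one", lo["drug_one"], 0.0)
        + np.where(drug_typ == "multiple", lo["drug_multiple"], 0.0)
        - _centred_logit_offset(cov)
    )
    if 0.0 < p_sat < 1.0:
        eta += math.log(p_sat / (1.0 - p_sat))
        in_sat = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    else:
        in_sat = np.full(n, p_sat >= 1.0)

    group = np.empty(n, dtype=int)
    for mask, idx in ((in_sat, sat_idx), (~in_sat, other_idx)):
        m = int(mask.sum())
        if m == 0:
            continue
        w = pi[idx]
        w = w / w.sum() if w.sum() > 0 else np.full(len(idx), 1.0 / len(idx))
        group[mask] = idx[rng.choice(len(idx), size=m, p=w)]

    # Visit attendance: each visit independently missing; at least one kept.
    attend = rng.random((n, config.n_visits)) >= config.visit_missing_rate
    none = ~attend.any(axis=1)
    if none.any():
        forced = rng.integers(0, config.n_visits, size=int(none.sum()))
        attend[np.flatnonzero(none), forced] = True

    # Visit calendar: semiannual windows from 2008-10-01, with per-participant
    # day/time jitter inside each window.
    base_date = datetime(2008, 10, 1)
    day_off = rng.integers(0, 150, size=(n, config.n_visits))
    sec_off = rng.integers(8 * 3600, 17 * 3600, size=(n, config.n_visits))

    mu = config.group_means()  # K x n_visits
    records: list[VisitRecord] = []
    for i, pid in enumerate(pids):
        for t in range(config.n_visits):
            if not attend[i, t]:
                continue
            mean_wc = config.base_word_count - (
                config.word_count_drop if t >= config.drop_at else 0
            )
            n_words = max(int(rng.poisson(mean_wc)), 1)
            speed = mu[group[i], t] + rng.normal(0.0, config.sigma)
            while speed <= 0:  # truncated normal: duration must stay positive
                speed = mu[group[i], t] + rng.normal(0.0, config.sigma)
            duration = n_words / speed
            sex = sex_typ[i] if rng.random() < cov.visit_stability else rng.choice(
                ["none", "one", "multiple"], p=cov.sexual_activity_probs
            )
            drug = drug_typ[i] if rng.random() < cov.visit_stability else rng.choice(
                ["none", "one", "multiple"], p=cov.drug_use_probs
            )
            start = base_date + timedelta(
                days=int(182 * t + day_off[i, t]), seconds=int(sec_off[i, t])
            )
            records.append(
                VisitRecord(
                    participant_id=pid,
                    visit=VISIT_BASE + t,
                    start_time=start,
                    end_time=start + timedelta(seconds=duration),
                    word_count=n_words,
                    sexual_activity=str(sex),
                    drug_use=str(drug),
                )
            )

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "baseline_age": age,
            "race": race,
            "education": education,
            "hiv": hiv,
        }
    )
    sat_set = set(config.satisficer_groups)
    return SyntheticCohort(
        records=tuple(records),
        participants=participants,
        true_group={pid: int(g) for pid, g in zip(pids, group)},
        true_satisficer={pid: int(g) in sat_set for pid, g in zip(pids, group)},
    )


def inject_timestamp_errors(
    cohort: SyntheticCohort,
    corrupt_rates: tuple[float, float, float],
    seed: int,
) -> tuple[SyntheticCohort, dict[str, list[tuple[str, int]]]]:
    """Corrupt record timestamps by without-replacement quota sampling.

    Quotas are ``round(rate * n_records)`` per category, drawn disjointly (a
    record receives at most one corruption; priority missing-start, then
    missing-end, then illogical).  Quota sampling makes the corruption counts
    exact rather than binomial, so fixtures can reproduce printed exclusion
    arithmetic.  Returns the corrupted cohort and a bookkeeping map from
    corruption category to the affected (participant_id, visit) keys.
    """
    rates = tuple(float(r) for r in corrupt_rates)
    if any(r < 0 or r > 1 for r in rates):
        raise ConfigError("corrupt rates must lie in [0, 1]")
    if sum(rates) > 1:
        raise ConfigError("corrupt rates must sum to at most 1")

    n = len(cohort.records)
    quotas = [round(r * n) for r in rates]
    if sum(quotas) > n:
        raise ConfigError("corruption quotas exceed the number of records")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    plan: dict[int, str] = {}
    pos = 0
    for kind, q in zip(("missing_start", "missing_end", "illogical"), quotas):
        for j in perm[pos : pos + q]:
            plan[int(j)] = kind
        pos += q

    log: dict[str, list[tuple[str, int]]] = {
        "missing_start": [],
        "missing_end": [],
        "illogical": [],
    }
    out = []
    for j, rec in enumerate(cohort.records):
        kind = plan.get(j)
        if kind is None:
            out.append(rec)
            continue
        log[kind].append((rec.participant_id, rec.visit))
        if kind == "missing_start":
            out.append(replace(rec, start_time=None))
        elif kind == "missing_end":
            out.append(replace(rec, end_time=None))
        else:  # end moved before start by the original duration
            out.append(
                replace(rec, end_time=rec.start_time - (rec.end_time - rec.start_time))
            )
    return (
        SyntheticCohort(
            records=tuple(out),
            participants=cohort.participants,
            true_group=cohort.true_group,
            true_satisficer=cohort.true_satisficer,
        ),
        log,
    )


# Archetype subgroup shapes inside the slow cohort-level group: a small
# dramatically accelerating subgroup, a larger dip-then-accelerate subgroup,
# and a nearly constant one.
_SUB_I_RAPID = (2.0, 2.1, 2.25, 2.45, 2.75, 3.2, 3.7, 4.3, 5.0)
_SUB_II_LATE = (2.3, 2.2, 2.1, 2.0, 1.9, 1.8, 1.8, 2.05, 2.5)
_SUB_III_CONST = (1.9, 1.9, 1.9, 1.9, 1.9, 1.9, 1.9, 1.9, 1.9)


def subgroup_study_config(seed: int = 20160808, n_participants: int = 2000) -> SynthConfig:
    """Study-structure configuration with the slow group split into its three
    subgroups (shares 4.33% / 62.79% / 32.88% of the slow group's 37.84% of
    the cohort); the two accelerating subgroups are the planted satisficers,
    for a marginal satisficer share of 25.40%.
    """
    slow = 809 / 2138
    return SynthConfig(
        n_participants=n_participants,
        true_pi=(
            slow * (35 / 809),
            slow * (508 / 809),
            slow * (266 / 809),
            1048 / 2138,
            281 / 2138,
        ),
        true_beta=(
            poly_from_visit_means(_SUB_I_RAPID),
            poly_from_visit_means(_SUB_II_LATE),
            poly_from_visit_means(_SUB_III_CONST),
            poly_from_visit_means(_MID_DECLINING),
            poly_from_visit_means(_FAST_DECLINING),
        ),
        satisficer_groups=(0, 1),
        seed=seed,
    )


def config_from_file(path) -> SynthConfig:
    """Load a SynthConfig from a YAML (or JSON; YAML is a superset) file.

    Keys mirror the SynthConfig fields; ``covariates`` may be a nested mapping
    with CovariateModel fields.  Unknown keys raise a ConfigError.
    """
    from pathlib import Path

    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    cov_data = data.pop("covariates", None)
    known = {f.name for f in fields(SynthConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "true_pi" in data:
        data["true_pi"] = tuple(data["true_pi"])
    if "true_beta" in data:
        data["true_beta"] = tuple(tuple(b) for b in data["true_beta"])
    if "corrupt_rates" in data:
        data["corrupt_rates"] = tuple(data["corrupt_rates"])
    if "satisficer_groups" in data:
        data["satisficer_groups"] = tuple(data["satisficer_groups"])
    if cov_data is not None:
        cov_known = {f.name for f in fields(CovariateModel)}
        cov_unknown = set(cov_data) - cov_known
        if cov_unknown:
            raise ConfigError(f"unknown covariate keys: {sorted(cov_unknown)}")
        for key in ("race_probs", "education_probs", "sexual_activity_probs", "drug_use_probs"):
            if key in cov_data:
                cov_data[key] = tuple(cov_data[key])
        data["covariates"] = CovariateModel(**cov_data)
    cfg = SynthConfig(**data)
    cfg.validate()
    return cfg


def write_cohort_csvs(cohort: SyntheticCohort, visits_path, participants_path) -> None:
    """Write the visit-level and participant-level CSV files."""
    from .ingest import write_visits_csv

    write_visits_csv(list(cohort.records), visits_path)
    cohort.participants.to_csv(participants_path, index=False)
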