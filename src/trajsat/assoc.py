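"""Covariate associations with satisficing.

The satisficing label is a participant-level binary outcome observed across
repeated visits, so associations are estimated with marginal logistic models
fitted by generalized estimating equations: exchangeable working correlation,
robust (sandwich) standard errors clustered by participant.  Odds ratios are
exp(coefficient) with Wald 95% confidence intervals and two-sided Wald
p-values.  Univariate mode fits one covariate at a time; multivariate mode
fits all covariates jointly.

Reference levels are fixed: race = white, education = college, HIV = negative,
sexual activity = none, drug use = none.  Baseline age enters centred and
scaled by 10 years, so its odds ratio is per 10-year increase (centring does
not change that OR).

A crude 2x2 odds-ratio helper with a Woolf confidence interval is provided as
an independent oracle for the degenerate one-visit-per-participant case.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .classify import SatisficingResult, percent
from .ingest import VISIT_BASE, VisitRecord

__all__ = [
    "build_panel",
    "fit_repeated_logistic",
    "or_from_2x2",
    "table1_summary",
    "COVARIATE_TERMS",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: Model terms per covariate, with the fixed reference levels.
COVARIATE_TERMS = {
    "baseline_age": "age10",
    "race": "C(race, Treatment('white'))",
    "education": "C(education, Treatment('college'))",
    "hiv": "C(hiv, Treatment('neg'))",
    "sexual_activity": "C(sexual_activity, Treatment('none'))",
    "drug_use": "C(drug_use, Treatment('none'))",
}

_PARAM_RE = re.compile(r"C\((\w+),.*\)\[T\.([^\]]+)\]")


def build_panel(
    labels: SatisficingResult,
    records: list[VisitRecord],
    participants: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format panel joining labels, cleaned visit records, and baseline
    covariates; one row per retained participant-visit.

    ``age10`` is (baseline age - cohort mean) / 10.  Rows whose visit-level
    covariates are missing are dropped listwise; the count is attached as
    ``panel.attrs['n_dropped_missing_covariates']``.
    """
    labelled = set(labels.label)
    with_visits = {r.participant_id for r in records}
    orphans = sorted(labelled - with_visits)
    if orphans:
        raise ValueError(f"labelled participants without visits: {orphans[:10]}")

    part = participants.set_index("participant_id")
    rows = []
    for r in records:
        if r.participant_id not in labelled:
            continue
        base = part.loc[r.participant_id]
        rows.append(
            {
                "participant_id": r.participant_id,
                "t": r.visit - VISIT_BASE,
                "satisficer": int(labels.label[r.participant_id]),
                "baseline_age": float(base["baseline_age"]),
                "race": base["race"],
                "education": base["education"],
                "hiv": base["hiv"],
                "sexual_activity": r.sexual_activity,
                "drug_use": r.drug_use,
            }
        )
    panel = pd.DataFrame(rows)
    n_before = len(panel)
    panel = panel.dropna(subset=["sexual_activity", "drug_use"]).reset_index(drop=True)
    panel["age10"] = (panel["baseline_age"] - panel["baseline_age"].mean()) / 10.0
    panel.attrs["n_dropped_missing_covariates"] = n_before - len(panel)
    return panel


def _extract_or_rows(result, model_tag: str) -> list[dict]:
    params = result.params
    ses = result.bse
    pvals = result.pvalues
    rows = []
    for name in params.index:
        if name == "Intercept":
            continue
        m = _PARAM_RE.match(name)
        if m:
            covariate, level = m.group(1), m.group(2)
        else:
            covariate, level = name, ""
        b, se = float(params[name]), float(ses[name])
        rows.append(
            {
                "covariate": covariate,
                "level": level,
                "log_or": b,
                "OR": math.exp(b),
                "ci_low": math.exp(b - Z_95 * se),
                "ci_high": math.exp(b + Z_95 * se),
                "p_value": float(pvals[name]),
                "model": model_tag,
                "converged": bool(getattr(result, "converged", True)),
            }
        )
    return rows


def fit_repeated_logistic(
    panel: pd.DataFrame,
    covariates: list[str] | None = None,
    mode: str = "multivariate",
    cov_struct: str = "exchangeable",
) -> pd.DataFrame:
    """Fit GEE logistic models of satisficing and return the odds-ratio table.

    ``mode='multivariate'`` fits all ``covariates`` jointly; ``'univariate'``
    fits one at a time.  Raises if the outcome has a single class, and raises
    a RuntimeError naming the covariate on a failed fit.

    ``cov_struct`` selects the working correlation.  The exchangeable default
    is appropriate for participant-level covariates, but note that a
    participant-constant outcome drives the estimated within-participant
    correlation toward 1, which makes the exchangeable weighting discard
    within-participant variation — the coefficients of visit-level covariates
    are then shrunk toward zero.  Use ``'independence'`` (still with robust
    clustered standard errors) when visit-level covariate effects are of
    interest.
    """
    if covariates is None:
        covariates = list(COVARIATE_TERMS)
    if panel["satisficer"].nunique() < 2:
        raise ValueError("outcome must contain both classes")
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    structs = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }
    if cov_struct not in structs:
        raise ValueError(f"cov_struct must be one of {sorted(structs)}")

    groups_spec = [covariates] if mode == "multivariate" else [[c] for c in covariates]
    rows: list[dict] = []
    for covs in groups_spec:
        terms = " + ".join(COVARIATE_TERMS.get(c, c) for c in covs)
        try:
            result = smf.gee(
                f"satisficer ~ {terms}",
                groups="participant_id",
                data=panel,
                family=sm.families.Binomial(),
                cov_struct=structs[cov_struct](),
            ).fit()
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"GEE fit failed for terms [{terms}]: {exc}") from exc
        rows.extend(_extract_or_rows(result, mode))
    table = pd.DataFrame(rows)
    bad = table.loc[~table["converged"]]
    if len(bad):
        # surfaced in the table rather than raised: estimates may still be usable
        table.attrs["warning"] = f"{len(bad)} non-converged terms"
    return table


def or_from_2x2(a: float, b: float, c: float, d: float) -> tuple[float, tuple[float, float]]:
    """Crude odds ratio (a*d)/(b*c) with the Woolf 95% confidence interval.

    Layout: a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls.  If any cell is zero, the standard 0.5 continuity
    correction is added to every cell.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be nonnegative")
    if any(x == 0 for x in cells):
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return orr, (orr * math.exp(-Z_95 * se), orr * math.exp(Z_95 * se))


@dataclass(frozen=True)
class Table1:
    """Descriptive summary by satisficing status."""

    categorical: pd.DataFrame
    age: pd.DataFrame


_TABLE1_VARS = {
    "race": ["white", "black", "other"],
    "education": ["lt_college", "college", "gt_college"],
    "hiv": ["neg", "pos"],
}


def table1_summary(labels: SatisficingResult, participants: pd.DataFrame) -> Table1:
    """Counts and column percentages per category by satisficing status, plus
    median and IQR of baseline age."""
    df = participants.copy()
    df["satisficer"] = df["participant_id"].map(labels.label)
    if df["satisficer"].isna().any():
        df = df.dropna(subset=["satisficer"])
    strata = {
        "nonsatisficer": df[~df["satisficer"].astype(bool)],
        "satisficer": df[df["satisficer"].astype(bool)],
        "total": df,
    }
    rows = []
    for var, levels in _TABLE1_VARS.items():
        for level in levels:
            row = {"characteristic": var, "level": level}
            for name, sub in strata.items():
                count = int((sub[var] == level).sum())
                row[f"{name}_n"] = count
                row[f"{name}_pct"] = percent(count, len(sub)) if len(sub) else float("nan")
            rows.append(row)
    age_rows = []
    for name, sub in strata.items():
        q1, med, q3 = (
            sub["baseline_age"].quantile([0.25, 0.5, 0.75]).tolist()
            if len(sub)
            else (float("nan"),) * 3
        )
        age_rows.append(
            {"stratum": name, "n": len(sub), "median": med, "iqr_low": q1, "iqr_high": q3}
        )
    return Table1(categorical=pd.DataFrame(rows), age=pd.DataFrame(age_rows))
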