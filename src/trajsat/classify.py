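"""Two-step trajectory-based identification of survey satisficers.

Step 1 fits a trajectory mixture to the whole cohort (number of groups chosen
by BIC) and flags the groups whose fitted speed accelerates over the recent
visits.  Step 2 refits a mixture inside each flagged group and flags the
accelerating subgroups; members of those subgroups are labelled satisficers.

"Accelerating over the recent visits" is operationalised from the fitted
polynomial: the derivative at the final visit must be positive AND the fitted
speed at the final visit must exceed the minimum over the trailing window by
more than a margin delta (default 0.1 of the fitted residual SD).  A group
with an early rise but a negative end derivative — an overall decreasing
pattern — is therefore not a candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .gbtm import GbtmModel, GbtmSpec, posteriors, select_k
from .ingest import SpeedSeries

__all__ = [
    "ClassifierConfig",
    "TrajectoryShape",
    "SatisficingResult",
    "shape_flags",
    "select_candidate_groups",
    "two_step_classify",
    "summarize",
    "percent",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Controls for the two-step classifier.

    ``window`` is the trailing number of visits over which the recent rise is
    measured; ``margin_sigma_mult`` scales the fitted residual SD into the
    minimum rise delta.  ``k_range`` applies to both steps; ``step2_spec``
    defaults to ``step1_spec``.  A candidate group smaller than
    ``min_members_per_k * max(k_range)`` skips the refit and is labelled
    satisficer wholesale (mixtures on tiny groups are unstable).
    """

    window: int = 2
    margin_sigma_mult: float = 0.1
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    step1_spec: GbtmSpec = field(default_factory=GbtmSpec)
    step2_spec: GbtmSpec | None = None
    min_members_per_k: int = 10

    def validate(self, n_visits: int) -> None:
        if self.window < 1 or self.window >= n_visits:
            raise ValueError("window must be >= 1 and smaller than the visit span")
        if self.margin_sigma_mult < 0:
            raise ValueError("margin_sigma_mult must be nonnegative")
        if not self.k_range:
            raise ValueError("k_range is empty")


@dataclass(frozen=True)
class TrajectoryShape:
    """Shape summary of one fitted group trajectory over coded times 0..t_max."""

    group: int
    fitted_means: tuple[float, ...]
    end_derivative: float
    recent_rise: float  # mu(t_max) - min over the trailing window+1 fitted values
    overall_change: float  # mu(t_max) - mu(0)
    delta: float
    recent_increase: bool
    overall_decreasing: bool


@dataclass(frozen=True)
class SatisficingResult:
    """Per-participant labels with full two-step provenance."""

    label: dict[str, bool]  # True = satisficer
    step1_group: dict[str, int]
    step2_subgroup: dict[str, int | None]
    n_total: int
    n_satisficers: int
    provenance: dict

    def __post_init__(self) -> None:
        if len(self.label) != self.n_total:
            raise ValueError("labels must cover the whole cohort")
        if sum(self.label.values()) != self.n_satisficers:
            raise ValueError("satisficer count inconsistent with labels")

    @property
    def n_nonsatisficers(self) -> int:
        return self.n_total - self.n_satisficers

    @property
    def proportion_satisficers(self) -> float:
        return self.n_satisficers / self.n_total


def percent(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to two decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def shape_flags(
    model: GbtmModel, config: ClassifierConfig, t_max: int
) -> list[TrajectoryShape]:
    """Shape summary and candidate flags for every group of a fitted model."""
    if t_max < config.window:
        raise ValueError(f"t_max={t_max} smaller than trailing window {config.window}")
    grid = np.arange(0, t_max + 1, dtype=float)
    mu = model.mean_at(grid)
    deriv = model.derivative_at(np.array([float(t_max)]))[:, 0]
    delta = config.margin_sigma_mult * float(np.mean(np.atleast_1d(model.sigma)))
    shapes = []
    for j in range(model.K):
        tail = mu[j, -(config.window + 1):]
        recent_rise = float(mu[j, -1] - tail.min())
        overall_change = float(mu[j, -1] - mu[j, 0])
        recent_increase = bool(deriv[j] > 0 and recent_rise > delta)
        shapes.append(
            TrajectoryShape(
                group=j,
                fitted_means=tuple(float(v) for v in mu[j]),
                end_derivative=float(deriv[j]),
                recent_rise=recent_rise,
                overall_change=overall_change,
                delta=delta,
                recent_increase=recent_increase,
                overall_decreasing=bool(overall_change < -delta and not recent_increase),
            )
        )
    return shapes


def select_candidate_groups(shapes: list[TrajectoryShape]) -> list[int]:
    """Groups whose trajectory accelerates over the recent visits (may be empty)."""
    return [s.group for s in shapes if s.recent_increase]


def two_step_classify(
    series: list[SpeedSeries], config: ClassifierConfig
) -> SatisficingResult:
    """Run the two-step classification on a cohort of speed series."""
    if len(series) < 2:
        raise ValueError("need at least 2 participants")
    t_max = int(max(s.times.max() for s in series))
    config.validate(t_max + 1)
    spec2 = config.step2_spec or config.step1_spec

    model1, table1 = select_k(series, config.k_range, config.step1_spec)
    assign1 = posteriors(model1, series)
    shapes1 = shape_flags(model1, config, t_max)
    candidates = select_candidate_groups(shapes1)

    label = {s.participant_id: False for s in series}
    step2_subgroup: dict[str, int | None] = {s.participant_id: None for s in series}
    step2_prov: dict[int, dict] = {}
    notes: list[str] = []

    min_size = config.min_members_per_k * max(config.k_range)
    by_pid = {s.participant_id: s for s in series}
    for g in candidates:
        members = [pid for pid, grp in assign1.hard_label.items() if grp == g]
        if len(members) < min_size:
            msg = (
                f"candidate group {g} has only {len(members)} members "
                f"(< {min_size}); labelled satisficer wholesale without a refit"
            )
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
            for pid in members:
                label[pid] = True
            step2_prov[g] = {"refit": False, "n_members": len(members)}
            continue
        sub_series = [by_pid[pid] for pid in members]
        sub_tmax = int(max(s.times.max() for s in sub_series))
        model2, table2 = select_k(sub_series, config.k_range, spec2)
        assign2 = posteriors(model2, sub_series)
        shapes2 = shape_flags(model2, config, sub_tmax)
        flagged = set(select_candidate_groups(shapes2))
        for pid in members:
            sub = assign2.hard_label[pid]
            step2_subgroup[pid] = sub
            if sub in flagged:
                label[pid] = True
        step2_prov[g] = {
            "refit": True,
            "n_members": len(members),
            "model": model2.as_dict(),
            "bic_table": table2,
            "shapes": [vars(s) | {"fitted_means": list(s.fitted_means)} for s in shapes2],
            "flagged_subgroups": sorted(flagged),
        }

    n_sat = sum(label.values())
    return SatisficingResult(
        label=label,
        step1_group=dict(assign1.hard_label),
        step2_subgroup=step2_subgroup,
        n_total=len(series),
        n_satisficers=n_sat,
        provenance={
            "step1_model": model1.as_dict(),
            "step1_bic_table": table1,
            "step1_shapes": [
                vars(s) | {"fitted_means": list(s.fitted_means)} for s in shapes1
            ],
            "candidate_groups": candidates,
            "step2": step2_prov,
            "notes": notes,
            "config": {
                "window": config.window,
                "margin_sigma_mult": config.margin_sigma_mult,
                "k_range": list(config.k_range),
            },
        },
    )


def summarize(result: SatisficingResult) -> pd.DataFrame:
    """Count/percentage table of the classification outcome.

    Cohort-level rows use the cohort size as denominator; subgroup rows use
    their parent step-1 group.  Percentages are rounded half-up to two
    decimals, matching the usual printed style.
    """
    rows = [
        ("satisficers", result.n_satisficers, result.n_total),
        ("nonsatisficers", result.n_nonsatisficers, result.n_total),
    ]
    groups = sorted(set(result.step1_group.values()))
    g_counts = {g: 0 for g in groups}
    for g in result.step1_group.values():
        g_counts[g] += 1
    for g in groups:
        rows.append((f"step1_group_{g}", g_counts[g], result.n_total))
    sub_counts: dict[tuple[int, int], int] = {}
    for pid, sub in result.step2_subgroup.items():
        if sub is not None:
            key = (result.step1_group[pid], sub)
            sub_counts[key] = sub_counts.get(key, 0) + 1
    for (g, sub), c in sorted(sub_counts.items()):
        rows.append((f"step1_group_{g}_subgroup_{sub}", c, g_counts[g]))
    return pd.DataFrame(
        [
            {
                "category": name,
                "count": count,
                "denominator": den,
                "percent": percent(count, den),
            }
            for name, count, den in rows
        ]
    )
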