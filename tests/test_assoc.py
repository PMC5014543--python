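"""Panel construction, GEE odds ratios, crude 2x2 oracle, descriptive table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from trajsat.assoc import build_panel, fit_repeated_logistic, or_from_2x2, table1_summary
from trajsat.classify import SatisficingResult
from trajsat.ingest import VisitRecord, clean_visits
from trajsat.synth import SynthConfig, generate_cohort

from tests.conftest import make_records


def _result_from_labels(label: dict) -> SatisficingResult:
    return SatisficingResult(
        label=label,
        step1_group={p: int(v) for p, v in label.items()},
        step2_subgroup={p: None for p in label},
        n_total=len(label),
        n_satisficers=sum(label.values()),
        provenance={},
    )


def _participants(pids, **overrides):
    base = {
        "baseline_age": 50.0,
        "race": "white",
        "education": "college",
        "hiv": "neg",
    }
    rows = []
    for pid in pids:
        row = {"participant_id": pid} | base
        for col, mapping in overrides.items():
            row[col] = mapping.get(pid, base.get(col))
        rows.append(row)
    return pd.DataFrame(rows)


class TestBuildPanel:
    def test_long_format_with_constant_outcome(self):
        records = make_records(18)  # 2 participants x 9 visits
        pids = sorted({r.participant_id for r in records})
        labels = _result_from_labels({pids[0]: True, pids[1]: False})
        panel = build_panel(labels, records, _participants(pids))
        assert len(panel) == 18
        assert (panel.groupby("participant_id")["satisficer"].nunique() == 1).all()
        assert panel.loc[panel.participant_id == pids[0], "satisficer"].eq(1).all()

    def test_age_scaled_per_ten_years_and_centred(self):
        records = make_records(18)
        pids = sorted({r.participant_id for r in records})
        labels = _result_from_labels({pids[0]: True, pids[1]: False})
        parts = _participants(pids, baseline_age={pids[0]: 40.0, pids[1]: 60.0})
        panel = build_panel(labels, records, parts)
        assert panel["age10"].mean() == pytest.approx(0.0, abs=1e-12)
        spread = panel.groupby("participant_id")["age10"].first()
        assert spread[pids[1]] - spread[pids[0]] == pytest.approx(2.0)

    def test_reference_dummy_coding_matches_hand_built_design(self):
        import patsy

        panel = pd.DataFrame(
            {
                "race": ["white", "black", "other"],
                "satisficer": [0, 1, 0],
            }
        )
        mat = np.asarray(
            patsy.dmatrix("C(race, Treatment('white'))", panel, return_type="matrix")
        )
        expected = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1]], dtype=float)
        np.testing.assert_array_equal(mat, expected)

    def test_labelled_participant_without_visits_rejected(self):
        records = make_records(9)
        labels = _result_from_labels({"Q00000": True, "GHOST": False})
        with pytest.raises(ValueError, match="GHOST"):
            build_panel(labels, records, _participants(["Q00000", "GHOST"]))


def _sim_panel(n, planted_log_or, seed, n_visits=9, base_p=0.25):
    """Participant-level binary covariate with a planted log-OR on a
    participant-constant outcome, expanded to a visit-level panel."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(int)
    y = (rng.random(n) < expit(np.log(base_p / (1 - base_p)) + planted_log_or * x)).astype(int)
    rows = [
        (f"P{i:05d}", t, y[i], x[i]) for i in range(n) for t in range(n_visits)
    ]
    return pd.DataFrame(rows, columns=["participant_id", "t", "satisficer", "x"]), x, y


class TestFitRepeatedLogistic:
    def test_single_visit_panel_equals_crude_2x2_odds_ratio(self):
        panel, x, y = _sim_panel(400, 0.9, seed=42, n_visits=1)
        table = fit_repeated_logistic(panel, covariates=["x"], mode="univariate")
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 0) & (y == 1)).sum())
        c = int(((x == 1) & (y == 0)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        crude, _ = or_from_2x2(a, b, c, d)
        assert table["OR"].iloc[0] == pytest.approx(crude, abs=1e-4)

    def test_planted_log_odds_recovered_with_repeated_visits(self):
        panel, _, _ = _sim_panel(2000, 0.8, seed=7)
        table = fit_repeated_logistic(panel, covariates=["x"], mode="multivariate")
        assert table["log_or"].iloc[0] == pytest.approx(0.8, abs=0.15)

    def test_null_covariate_estimate_centred_on_zero(self):
        # average over independent replicates so the check reflects the null
        # expectation rather than one draw's sampling noise
        logs, covers = [], 0
        for seed in range(5):
            panel, _, _ = _sim_panel(5000, 0.0, seed=11 + seed)
            table = fit_repeated_logistic(panel, covariates=["x"], mode="univariate")
            logs.append(table["log_or"].iloc[0])
            covers += bool(table["ci_low"].iloc[0] < 1.0 < table["ci_high"].iloc[0])
        assert abs(np.mean(logs)) < 0.1
        assert covers >= 4

    def test_univariate_and_multivariate_modes_differ_under_confounding(self):
        rng = np.random.default_rng(3)
        n = 1500
        z = (rng.random(n) < 0.5).astype(int)
        x = (rng.random(n) < expit(-0.5 + 1.5 * z)).astype(int)
        y = (rng.random(n) < expit(-1.0 + 1.2 * z)).astype(int)  # x has no direct effect
        rows = [(f"P{i}", t, y[i], x[i], z[i]) for i in range(n) for t in range(2)]
        panel = pd.DataFrame(rows, columns=["participant_id", "t", "satisficer", "x", "z"])
        uni = fit_repeated_logistic(panel, covariates=["x"], mode="univariate")
        multi = fit_repeated_logistic(panel, covariates=["x", "z"], mode="multivariate")
        x_multi = multi.set_index("covariate").loc["x", "log_or"]
        assert uni["log_or"].iloc[0] > 0.2  # confounded crude association
        assert abs(x_multi) < abs(uni["log_or"].iloc[0])  # adjusted moves toward 0

    def test_single_class_outcome_rejected(self):
        panel, _, _ = _sim_panel(50, 0.0, seed=1)
        panel["satisficer"] = 0
        with pytest.raises(ValueError, match="both classes"):
            fit_repeated_logistic(panel, covariates=["x"])

    def test_generator_planted_baseline_effects_recovered(self):
        # cohort-level recovery through the real panel-building path
        cfg = SynthConfig(n_participants=2000, visit_missing_rate=0.0,
                          corrupt_rates=(0.0, 0.0, 0.0), seed=23)
        cohort = generate_cohort(cfg)
        kept, _ = clean_visits(list(cohort.records))
        labels = _result_from_labels(dict(cohort.true_satisficer))
        panel = build_panel(labels, kept, cohort.participants)
        table = fit_repeated_logistic(
            panel, covariates=["baseline_age", "race", "education", "hiv"],
            mode="multivariate",
        )
        idx = table.set_index(["covariate", "level"])
        assert idx.loc[("age10", ""), "log_or"] == pytest.approx(np.log(1.44), abs=0.15)
        assert idx.loc[("race", "black"), "log_or"] == pytest.approx(np.log(2.22), abs=0.25)


class TestOrFrom2x2:
    def test_symmetric_table_gives_unit_odds_ratio(self):
        orr, (lo, hi) = or_from_2x2(1, 1, 1, 1)
        assert orr == 1.0 and lo < 1.0 < hi

    def test_study_population_race_counts(self):
        # black vs white satisficer/nonsatisficer counts: crude OR, which is
        # deliberately not the repeated-measures estimate (2.17)
        orr, _ = or_from_2x2(194, 268, 339, 1073)
        assert orr == pytest.approx(2.29, abs=0.005)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            or_from_2x2(-1, 1, 1, 1)

    def test_zero_cell_uses_continuity_correction(self):
        orr, (lo, hi) = or_from_2x2(0, 5, 5, 5)
        assert np.isfinite(orr) and orr > 0 and np.isfinite(lo)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_doubling_cells_preserves_or_and_shrinks_ci(self, cells):
        a, b, c, d = cells
        or1, (lo1, hi1) = or_from_2x2(a, b, c, d)
        or2, (lo2, hi2) = or_from_2x2(2 * a, 2 * b, 2 * c, 2 * d)
        assert or2 == pytest.approx(or1, rel=1e-12)
        assert (hi2 / lo2) < (hi1 / lo1)


class TestTable1Summary:
    def test_counts_and_column_percentages(self):
        pids = [f"P{i}" for i in range(10)]
        label = {p: i < 4 for i, p in enumerate(pids)}  # 4 satisficers
        race = {p: ("black" if i % 2 else "white") for i, p in enumerate(pids)}
        parts = _participants(pids, race=race)
        parts["baseline_age"] = np.arange(45, 55, dtype=float)
        t1 = table1_summary(_result_from_labels(label), parts)
        cat = t1.categorical.set_index(["characteristic", "level"])
        assert cat.loc[("race", "white"), "satisficer_n"] == 2
        assert cat.loc[("race", "white"), "satisficer_pct"] == 50.00
        assert cat.loc[("race", "black"), "nonsatisficer_n"] == 3
        total = t1.age.set_index("stratum").loc["total"]
        assert total["n"] == 10 and total["median"] == pytest.approx(49.5)

    def test_single_participant_is_its_own_category(self):
        parts = _participants(["A"])
        parts["baseline_age"] = [51.0]
        t1 = table1_summary(_result_from_labels({"A": True}), parts)
        cat = t1.categorical.set_index(["characteristic", "level"])
        assert cat.loc[("race", "white"), "satisficer_pct"] == 100.00
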