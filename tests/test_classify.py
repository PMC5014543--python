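"""Two-step satisficer identification: shape flags, candidates, labels, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajsat.classify import (
    ClassifierConfig,
    percent,
    select_candidate_groups,
    shape_flags,
    summarize,
    two_step_classify,
)
from trajsat.gbtm import GbtmSpec
from trajsat.ingest import build_series, clean_visits
from trajsat.synth import SynthConfig, generate_cohort, poly_from_visit_means

from tests.conftest import make_series, toy_model

CFG = ClassifierConfig()


class TestShapeFlags:
    def test_flat_trajectory_is_neither_rising_nor_decreasing(self):
        model = toy_model(pi=[1.0], beta=[[3.0]], sigma=0.5)
        (shape,) = shape_flags(model, CFG, t_max=8)
        assert not shape.recent_increase and not shape.overall_decreasing
        assert shape.end_derivative == 0.0

    def test_early_rise_then_decline_is_not_a_candidate(self):
        # fast group archetype: rises to visit ~2, declines thereafter
        beta = poly_from_visit_means((6.0, 6.2, 6.25, 6.1, 5.8, 5.5, 5.2, 4.9, 4.6))
        model = toy_model(pi=[1.0], beta=[beta], sigma=0.5)
        (shape,) = shape_flags(model, CFG, t_max=8)
        assert shape.end_derivative < 0
        assert not shape.recent_increase
        assert shape.overall_decreasing

    def test_flat_then_late_rise_is_a_candidate(self):
        # flat to t=6, rising ~0.5 words/s by t=8; delta = 0.1 * sigma = 0.05
        beta = poly_from_visit_means((2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.15, 2.5))
        model = toy_model(pi=[1.0], beta=[beta], sigma=0.5)
        (shape,) = shape_flags(model, CFG, t_max=8)
        assert shape.end_derivative > 0
        assert shape.recent_rise > 0.05
        assert shape.recent_increase

    def test_rise_below_margin_not_flagged(self):
        beta = poly_from_visit_means((2.0,) * 8 + (2.02,))
        model = toy_model(pi=[1.0], beta=[beta], sigma=1.0)  # delta = 0.1
        (shape,) = shape_flags(model, CFG, t_max=8)
        assert not shape.recent_increase

    def test_raising_margin_never_flags_more_groups(self):
        beta = [
            poly_from_visit_means((2.0,) * 7 + (2.2, 2.5)),
            poly_from_visit_means((4.0,) * 7 + (4.02, 4.06)),
            [6.0, -0.1],
        ]
        model = toy_model(pi=[0.4, 0.4, 0.2], beta=beta, sigma=1.0)
        counts = []
        for mult in (0.0, 0.02, 0.1, 0.5, 2.0):
            cfg = ClassifierConfig(margin_sigma_mult=mult)
            counts.append(len(select_candidate_groups(shape_flags(model, cfg, t_max=8))))
        assert counts == sorted(counts, reverse=True)

    def test_window_larger_than_span_rejected(self):
        model = toy_model(pi=[1.0], beta=[[2.0]])
        with pytest.raises(ValueError, match="window"):
            shape_flags(model, ClassifierConfig(window=9), t_max=8)


class TestSelectCandidates:
    def test_only_rising_groups_selected(self):
        beta = [
            poly_from_visit_means((2.0,) * 7 + (2.2, 2.6)),
            [4.0, 0.0],
            [6.0, -0.15],
        ]
        model = toy_model(pi=[0.3, 0.5, 0.2], beta=beta, sigma=0.5)
        assert select_candidate_groups(shape_flags(model, CFG, t_max=8)) == [0]

    def test_empty_when_no_group_rises(self):
        model = toy_model(pi=[0.5, 0.5], beta=[[2.0], [6.0, -0.1]], sigma=0.5)
        assert select_candidate_groups(shape_flags(model, CFG, t_max=8)) == []


def _cohort_series(cfg):
    cohort = generate_cohort(cfg)
    kept, _ = clean_visits(list(cohort.records))
    return cohort, build_series(kept)


class TestTwoStepClassify:
    def test_all_constant_cohort_has_zero_satisficers(self):
        cfg = SynthConfig(
            n_participants=150, true_pi=(1.0,), true_beta=((3.0,),), sigma=0.4,
            visit_missing_rate=0.0, corrupt_rates=(0.0, 0.0, 0.0), seed=13,
        )
        _, series = _cohort_series(cfg)
        res = two_step_classify(
            series, ClassifierConfig(k_range=(1, 2), step1_spec=GbtmSpec(n_starts=2, order=1))
        )
        assert res.n_satisficers == 0
        assert res.provenance["candidate_groups"] == []

    def test_labels_partition_the_cohort(self):
        cfg = SynthConfig(
            n_participants=200,
            true_pi=(0.3, 0.7),
            true_beta=(poly_from_visit_means((2.0,) * 7 + (2.3, 2.8)), (4.5,)),
            sigma=0.4, visit_missing_rate=0.1, corrupt_rates=(0.0, 0.0, 0.0), seed=14,
        )
        _, series = _cohort_series(cfg)
        res = two_step_classify(
            series, ClassifierConfig(k_range=(1, 2, 3), step1_spec=GbtmSpec(n_starts=2))
        )
        assert set(res.label) == {s.participant_id for s in series}
        assert res.n_satisficers + res.n_nonsatisficers == res.n_total == len(series)

    def test_two_rising_groups_are_both_processed(self):
        cfg = SynthConfig(
            n_participants=300,
            true_pi=(0.4, 0.4, 0.2),
            true_beta=(
                poly_from_visit_means((1.5,) * 7 + (1.9, 2.5)),
                poly_from_visit_means((4.0,) * 7 + (4.4, 5.0)),
                (7.0,),
            ),
            sigma=0.3, visit_missing_rate=0.0, corrupt_rates=(0.0, 0.0, 0.0), seed=15,
        )
        cohort, series = _cohort_series(cfg)
        res = two_step_classify(
            series, ClassifierConfig(k_range=(1, 2, 3), step1_spec=GbtmSpec(n_starts=2, seed=2))
        )
        assert len(res.provenance["candidate_groups"]) == 2
        truth = cohort.true_satisficer  # groups 0 and 1 both rise, group 2 is flat
        agree = np.mean([res.label[p] == (cohort.true_group[p] in (0, 1)) for p in res.label])
        assert agree > 0.9

    def test_tiny_candidate_group_labelled_wholesale_with_warning(self):
        cfg = SynthConfig(
            n_participants=120,
            true_pi=(0.08, 0.92),
            true_beta=(poly_from_visit_means((2.0,) * 7 + (2.6, 3.4)), (5.0,)),
            sigma=0.25, visit_missing_rate=0.0, corrupt_rates=(0.0, 0.0, 0.0), seed=16,
        )
        _, series = _cohort_series(cfg)
        with pytest.warns(UserWarning, match="wholesale"):
            res = two_step_classify(
                series,
                ClassifierConfig(k_range=(1, 2), step1_spec=GbtmSpec(n_starts=2, order=1)),
            )
        assert res.n_satisficers > 0
        assert res.provenance["notes"]

    def test_fixed_seed_reproduces_identical_labels(self):
        cfg = SynthConfig(
            n_participants=150,
            true_pi=(0.3, 0.7),
            true_beta=(poly_from_visit_means((2.0,) * 7 + (2.3, 2.8)), (4.5,)),
            sigma=0.4, visit_missing_rate=0.0, corrupt_rates=(0.0, 0.0, 0.0), seed=17,
        )
        _, series = _cohort_series(cfg)
        ccfg = ClassifierConfig(k_range=(1, 2), step1_spec=GbtmSpec(n_starts=2, seed=9))
        assert two_step_classify(series, ccfg).label == two_step_classify(series, ccfg).label


class TestSummarize:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(543, 2138, 25.40), (35, 809, 4.33), (0, 100, 0.00), (1, 3, 33.33), (1, 8, 12.50)],
    )
    def test_percent_rounds_half_up_to_two_decimals(self, num, den, expected):
        assert percent(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent(1, 0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 10**6), st.integers(1, 10**6))
    def test_percent_matches_integer_half_up_oracle(self, num, den):
        q, r = divmod(10000 * num, den)
        expected = (q + (1 if 2 * r >= den else 0)) / 100
        assert percent(num, den) == pytest.approx(expected, abs=1e-9)

    def test_summary_table_counts_and_denominators(self):
        from trajsat.classify import SatisficingResult

        label = {"A": True, "B": False, "C": False, "D": True}
        res = SatisficingResult(
            label=label,
            step1_group={"A": 0, "B": 0, "C": 1, "D": 0},
            step2_subgroup={"A": 1, "B": 0, "C": None, "D": 1},
            n_total=4,
            n_satisficers=2,
            provenance={},
        )
        table = summarize(res).set_index("category")
        assert table.loc["satisficers", "count"] == 2
        assert table.loc["satisficers", "percent"] == 50.00
        assert table.loc["step1_group_0", "count"] == 3
        assert table.loc["step1_group_0_subgroup_1", "denominator"] == 3
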