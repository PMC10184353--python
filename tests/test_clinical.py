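"""Survival curves, log-rank tests, Fisher associations and the four
cohort constructions."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from bruteforce import bf_fisher, bf_logrank
from multicris import clinical
from multicris.types import ClinicalTable, MultiLabelAssignment, ValidationError


class TestHorizonRecoding:
    def test_event_beyond_horizon_becomes_censored_at_horizon(self):
        t, e = clinical.recode_horizon([40.0], [True], horizon=36)
        assert t[0] == 36.0 and not e[0]

    def test_event_at_horizon_is_kept(self):
        t, e = clinical.recode_horizon([36.0], [True], horizon=36)
        assert t[0] == 36.0 and e[0]

    def test_negative_times_rejected(self):
        with pytest.raises(ValidationError):
            clinical.recode_horizon([-1.0], [True])


class TestKaplanMeier:
    def test_no_events_gives_flat_curve(self):
        curve = clinical.km_curve([5, 10, 20], [False, False, False])
        assert (curve["survival"] == 1.0).all()

    def test_product_limit_by_hand(self):
        curve = clinical.km_curve([1.0, 2.0], [True, True])
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(0.5)
        assert surv[2.0] == pytest.approx(0.0)

    def test_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(1, 30, size=50)
        curve = clinical.km_curve(times, [True] * 50)
        for _, row in curve.iloc[1:].iterrows():
            empirical = np.mean(times > row["time"])
            assert row["survival"] == pytest.approx(empirical, abs=1e-12)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValidationError):
            clinical.km_curve([], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [3.0, 8.0, 15.0, 30.0]
        e = [True, True, False, True]
        stat, p = clinical.logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_sample_risk_table_example(self):
        # groupA events at 1,2; groupB events at 3,4 -> chi2 = 49/17
        stat, p = clinical.logrank([1, 2], [True, True], [3, 4], [True, True])
        assert stat == pytest.approx(49 / 17, abs=1e-9)
        assert p == pytest.approx(1 - scipy.stats.chi2.cdf(49 / 17, df=1), abs=1e-12)

    def test_matches_risk_set_enumeration_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            na, nb = rng.integers(3, 15, size=2)
            ta = rng.uniform(0, 36, na).round(1)
            tb = rng.uniform(0, 36, nb).round(1)
            ea = rng.random(na) < 0.7
            eb = rng.random(nb) < 0.7
            if not ea.any() and not eb.any():
                continue
            stat, _ = clinical.logrank(ta, ea, tb, eb, horizon=36)
            assert stat == pytest.approx(bf_logrank(ta, ea, tb, eb), abs=1e-9)

    def test_no_events_anywhere_is_an_error(self):
        with pytest.raises(ValidationError):
            clinical.logrank([1, 2], [False, False], [3], [False])


def assignment(sample_id, primary, secondary=()):
    return MultiLabelAssignment(sample_id, primary, frozenset(secondary))


ASSIGNMENTS = [
    assignment("p1", "B"),
    assignment("p2", "B", {"C"}),
    assignment("s1", "A", {"B"}),
    assignment("s2", "C", {"B"}),
    assignment("x1", "A"),
    assignment("x2", "C"),
    assignment("nc", "NC"),
]


class TestCohorts:
    def test_four_constructions_for_target_b(self):
        cohorts = clinical.build_cohorts(ASSIGNMENTS, "B")
        assert set(cohorts["single_label"].in_group) == {"p1", "p2"}
        assert set(cohorts["single_label"].out_group) == {"s1", "s2", "x1", "x2"}
        assert set(cohorts["primary_only_excluding_secondary"].in_group) == {"p1", "p2"}
        assert set(cohorts["primary_only_excluding_secondary"].out_group) == {"x1", "x2"}
        assert set(cohorts["secondary_only"].in_group) == {"s1", "s2"}
        assert set(cohorts["secondary_only"].out_group) == {"x1", "x2"}
        assert set(cohorts["primary_plus_secondary"].in_group) == {"p1", "p2", "s1", "s2"}

    def test_secondary_carriers_are_in_neither_group_when_excluded(self):
        c = clinical.build_cohorts(ASSIGNMENTS, "B")["primary_only_excluding_secondary"]
        assert "s1" not in c.in_group and "s1" not in c.out_group

    def test_union_identity(self):
        cohorts = clinical.build_cohorts(ASSIGNMENTS, "B")
        assert set(cohorts["primary_plus_secondary"].in_group) == set(
            cohorts["primary_only_excluding_secondary"].in_group
        ) | set(cohorts["secondary_only"].in_group)

    def test_not_classified_samples_belong_to_no_group(self):
        for c in clinical.build_cohorts(ASSIGNMENTS, "B").values():
            assert "nc" not in c.in_group and "nc" not in c.out_group

    def test_untouched_class_gives_empty_in_groups(self):
        only_a = [assignment("s", "A")]
        cohorts = clinical.build_cohorts(only_a, "B")
        assert all(not c.in_group for c in cohorts.values())


def make_cohort(a, b, c, d):
    in_group = [f"i{k}" for k in range(a + b)]
    out_group = [f"o{k}" for k in range(c + d)]
    annotation = {}
    for k, s in enumerate(in_group):
        annotation[s] = k < a
    for k, s in enumerate(out_group):
        annotation[s] = k < c
    cohort = clinical.CohortDefinition("T", "single_label", tuple(in_group), tuple(out_group))
    return cohort, annotation


class TestFisher:
    def test_known_table(self):
        cohort, annotation = make_cohort(8, 2, 1, 5)
        res = clinical.fisher_association(cohort, annotation)
        assert res.table == ((8, 2), (1, 5))
        assert res.odds_ratio == pytest.approx(20.0)
        p_ref, _ = bf_fisher(8, 2, 1, 5)
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)

    def test_zero_cell_is_corrected_and_flagged(self):
        cohort, annotation = make_cohort(5, 0, 2, 6)
        res = clinical.fisher_association(cohort, annotation)
        assert res.haldane_corrected
        assert math.isfinite(res.odds_ratio)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_empty_margin_is_an_error(self):
        cohort, annotation = make_cohort(0, 3, 0, 4)  # no positives anywhere
        with pytest.raises(ValidationError):
            clinical.fisher_association(cohort, annotation)

    def test_independent_annotation_gives_or_near_one(self):
        rng = np.random.default_rng(3)
        ors = []
        for rep in range(50):
            flags = rng.random(200) < 0.4
            in_group = tuple(f"s{i}" for i in range(60))
            out_group = tuple(f"s{i}" for i in range(60, 200))
            cohort = clinical.CohortDefinition("T", "single_label", in_group, out_group)
            annotation = {f"s{i}": bool(flags[i]) for i in range(200)}
            ors.append(clinical.fisher_association(cohort, annotation).odds_ratio)
        assert np.median(ors) == pytest.approx(1.0, abs=0.25)

    def test_effect_sizes_report_both_framings(self):
        cohort, annotation = make_cohort(8, 2, 10, 30)
        res = clinical.fisher_association(cohort, annotation)
        assert res.rate_in == pytest.approx(0.8)
        assert res.rate_out == pytest.approx(0.25)
        assert res.rate_overall == pytest.approx(18 / 50)
        assert res.lift_vs_overall == pytest.approx(0.8 / (18 / 50))
        assert res.risk_ratio_vs_complement == pytest.approx(3.2)


class TestResponseDichotomy:
    def test_sensitive_versus_rest(self):
        frame = pd.DataFrame(
            {"response": ["sensitive", "stable", "resistant"]},
            index=["a", "b", "c"],
        )
        flag = clinical.dichotomize_response(ClinicalTable(frame))
        assert flag == {"a": True, "b": False, "c": False}


class TestSurvivalAssociation:
    def test_runs_over_all_four_modes(self):
        rng = np.random.default_rng(5)
        n = 60
        ids = [f"s{i}" for i in range(n)]
        assignments = []
        for i, s in enumerate(ids):
            primary = "B" if i < 20 else "A"
            secondary = {"B"} if (20 <= i < 30) else set()
            assignments.append(assignment(s, primary, secondary))
        times = np.where(np.arange(n) < 20, rng.exponential(10, n), rng.exponential(30, n))
        frame = pd.DataFrame({"time": times, "event": True}, index=ids)
        table = ClinicalTable(frame)
        out = clinical.survival_association(assignments, table, "B")
        assert list(out.index) == list(clinical.COHORT_MODES)
        assert (out["p_value"].dropna() <= 1).all()
        assert out.loc["single_label", "p_value"] < 0.05
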