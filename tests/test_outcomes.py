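"""RFS arithmetic, Kaplan-Meier, log-rank, lead times, recurrence summaries
and hypergeometric enrichment."""

import datetime
import math

import numpy as np
import pytest

from pericfdna.errors import UndefinedStatisticError, ValidationError
from pericfdna.models import MaxAfResult
from pericfdna.outcomes import (compute_rfs, hypergeometric_enrichment,
                                km_estimate, logrank_test,
                                recurrence_summary, summarize_lead_times)

from conftest import make_record


class TestComputeRfs:
    def test_recurrence_213_days_is_seven_months(self):
        record = make_record(
            recurrence=True,
            surgery_date=datetime.date(2021, 1, 1),
            recurrence_date=datetime.date(2021, 1, 1)
            + datetime.timedelta(days=213),
            last_followup_date=datetime.date(2021, 1, 1)
            + datetime.timedelta(days=213))
        months, event = compute_rfs(record)
        assert months == pytest.approx(213 / 30.44)
        assert months == pytest.approx(7.0, abs=0.01)
        assert event

    def test_same_day_followup_censored_at_zero(self):
        record = make_record(
            surgery_date=datetime.date(2021, 5, 1),
            last_followup_date=datetime.date(2021, 5, 1))
        assert compute_rfs(record) == (0.0, False)

    def test_random_cohort_matches_date_arithmetic(self, small_cohort):
        for record in small_cohort.clinical:
            months, event = compute_rfs(record)
            end = (record.recurrence_date if record.recurrence
                   else record.last_followup_date)
            assert months == pytest.approx(
                (end - record.surgery_date).days / 30.44)
            assert event is record.recurrence


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([3.0, 5.0, 9.0], [False, False, False])
        assert curve.event_times == ()
        assert curve.survival_at(100.0) == 1.0

    def test_single_event_drops_to_n_minus_one_over_n(self):
        curve = km_estimate([2.0, 4.0, 6.0, 8.0], [False, True, False, False])
        assert curve.event_times == (4.0,)
        assert curve.survival == (pytest.approx(2 / 3),)

    def test_ten_subject_hand_table(self):
        # events at 2 (1/10), 5 (2 events among 8 at risk), censor at 3, 6, 7
        times = [2, 3, 5, 5, 6, 7, 8, 9, 10, 11]
        events = [True, False, True, True, False, False, False, False,
                  False, False]
        curve = km_estimate(times, events)
        assert curve.event_times == (2.0, 5.0)
        assert curve.at_risk == (10, 8)
        assert curve.events == (1, 2)
        assert curve.survival[0] == pytest.approx(9 / 10)
        assert curve.survival[1] == pytest.approx(9 / 10 * 6 / 8)

    def test_order_invariance_and_late_censoring(self, rng):
        times = list(rng.uniform(0.5, 20, 30))
        events = list(rng.random(30) < 0.4)
        order = rng.permutation(30)
        reordered = km_estimate([times[i] for i in order],
                                [events[i] for i in order])
        assert km_estimate(times, events) == reordered
        # moving a subject censored after the last event even later does not
        # change the curve (it stays in every earlier risk set either way)
        last_event = max(t for t, e in zip(times, events) if e)
        base = km_estimate(times + [last_event + 5], events + [False])
        moved = km_estimate(times + [last_event + 50], events + [False])
        assert base.survival == moved.survival

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        times = list(rng.uniform(0.5, 30, 60))
        events = list(rng.random(60) < 0.5)
        if not any(events):
            events[0] = True
        curve = km_estimate(times, events)
        fitter = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                float(fitter.survival_function_at_times(t).iloc[0]))


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        group = ([2.0, 4.0, 6.0], [True, False, True])
        chi_square, p = logrank_test(group, group)
        assert chi_square == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_early_events_versus_late_censoring_is_positive(self):
        early = ([1.0, 2.0, 3.0], [True, True, True])
        late = ([10.0, 11.0, 12.0], [False, False, False])
        chi_square, p = logrank_test(early, late)
        assert chi_square > 0
        assert p < 0.05

    def test_hand_computed_small_example(self):
        # group A events at 1, 3; group B event at 2
        group_a = ([1.0, 3.0], [True, True])
        group_b = ([2.0, 4.0], [True, False])
        # t=1: n=4, nA=2, d=1, E=.5, V=(2*2*3)/(16*3)=.25
        # t=2: n=3, nA=1, d=1, E=1/3, V=(1*2*2)/(9*2)=2/9
        # t=3: n=2, nA=1, d=1, E=.5, V=(1*1*1)/(4*1)=.25
        o_minus_e = (1 - 0.5) + (0 - 1 / 3) + (1 - 0.5)
        variance = 0.25 + 2 / 9 + 0.25
        chi_square, _ = logrank_test(group_a, group_b)
        assert chi_square == pytest.approx(o_minus_e ** 2 / variance)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        ta, tb = rng.exponential(10, 25), rng.exponential(5, 20)
        ea = rng.random(25) < 0.7
        eb = rng.random(20) < 0.7
        chi_square, p = logrank_test((list(ta), list(ea)),
                                     (list(tb), list(eb)))
        reference = ll_logrank(ta, tb, event_observed_A=ea,
                               event_observed_B=eb)
        assert chi_square == pytest.approx(reference.test_statistic)
        assert p == pytest.approx(reference.p_value)

    def test_no_events_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            logrank_test(([1.0], [False]), ([2.0], [False]))


class TestLeadTimes:
    def test_reported_lead_times(self):
        summary = summarize_lead_times([409, 184, 25])
        assert summary.median_days == 184.0  # standard median
        assert summary.mean_days == pytest.approx(206.0)

    def test_single_value(self):
        assert summarize_lead_times([100]).median_days == 100.0

    def test_odd_length_matches_sort_and_middle(self, rng):
        values = [int(v) for v in rng.integers(1, 500, 9)]
        assert summarize_lead_times(values).median_days == \
            float(sorted(values)[4])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_lead_times([])


def _maxaf(sample_id, pct):
    return MaxAfResult(sample_id=sample_id, maxaf_pct=pct,
                       n_eligible_variants=1 if pct else 0,
                       positive=pct > 6.29)


class TestRecurrenceSummary:
    def _records(self):
        surgery = datetime.date(2021, 1, 1)
        later = surgery + datetime.timedelta(days=200)
        records, maxaf = [], {}
        # 5 positive, 3 recurred with the reported MaxAF values
        for i, pct in enumerate([31.3, 13.6, 11.4, 20.0, 15.0]):
            recurred = i < 3
            records.append(make_record(
                sample_id=f"POS{i}", surgery_date=surgery,
                recurrence=recurred,
                recurrence_date=later if recurred else None,
                last_followup_date=later))
            maxaf[f"POS{i}"] = _maxaf(f"POS{i}", pct)
        # 18 negative, 2 recurred
        for i in range(18):
            recurred = i < 2
            records.append(make_record(
                sample_id=f"NEG{i}", surgery_date=surgery,
                recurrence=recurred,
                recurrence_date=later if recurred else None,
                last_followup_date=later))
            maxaf[f"NEG{i}"] = _maxaf(f"NEG{i}", 5.1 if i == 0 else 0.0)
        return records, maxaf

    def test_reported_group_summaries(self):
        records, maxaf = self._records()
        summary = recurrence_summary(records, maxaf)
        positive, negative = summary["positive"], summary["negative"]
        assert (positive.n, positive.recurrences) == (5, 3)
        assert positive.recurrence_pct == 60.0
        # exact mean 18.766... (the reported group mean truncates to 18.7)
        assert positive.mean_recurrent_maxaf_pct == pytest.approx(18.8)
        assert (negative.n, negative.recurrences) == (18, 2)
        assert negative.recurrence_pct == 11.1

    def test_zero_recurrences_reported_as_zero(self):
        surgery = datetime.date(2021, 1, 1)
        records = [make_record(sample_id="A", surgery_date=surgery,
                               last_followup_date=surgery)]
        summary = recurrence_summary(records, {"A": _maxaf("A", 0.0)})
        assert summary["negative"].recurrence_pct == 0.0
        assert summary["positive"].recurrence_pct is None  # empty group

    def test_pooling_conserves_counts(self):
        records, maxaf = self._records()
        summary = recurrence_summary(records, maxaf)
        assert summary["positive"].n + summary["negative"].n == len(records)
        assert summary["positive"].recurrences + \
            summary["negative"].recurrences == \
            sum(1 for r in records if r.recurrence)


class TestEnrichment:
    BACKGROUND = [f"G{i}" for i in range(20)]

    def test_pathway_equal_to_background_is_not_enriched(self):
        results = hypergeometric_enrichment(
            ["G0", "G1", "G2"], self.BACKGROUND,
            {"ALL": set(self.BACKGROUND)})
        assert results[0].p_value == pytest.approx(1.0)

    def test_full_overlap_combinatorial_oracle(self):
        results = hypergeometric_enrichment(
            ["G0", "G1", "G2"], self.BACKGROUND,
            {"HIT": {"G0", "G1", "G2"}})
        expected = (math.comb(3, 3) * math.comb(17, 0)) / math.comb(20, 3)
        assert results[0].p_value == pytest.approx(expected)

    def test_bh_qvalues_match_step_up_oracle(self, rng):
        pathways = {f"P{i}": set(rng.choice(self.BACKGROUND, size=5,
                                            replace=False)) for i in range(10)}
        query = ["G0", "G1", "G2", "G3"]
        results = hypergeometric_enrichment(query, self.BACKGROUND, pathways)
        by_id = {r.pathway_id: r for r in results}
        ps = sorted((r.p_value, r.pathway_id) for r in results)
        m = len(ps)
        # step-up: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1
        raw = [p * m / (i + 1) for i, (p, _) in enumerate(ps)]
        qs = np.minimum.accumulate(raw[::-1])[::-1]
        for (p, pid), q in zip(ps, np.minimum(qs, 1.0)):
            assert by_id[pid].q_value == pytest.approx(max(q, p))
        # monotone in p-order
        ordered = [by_id[pid].q_value for _, pid in ps]
        assert all(a <= b + 1e-12 for a, b in zip(ordered, ordered[1:]))

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValidationError, match="NOTINBG"):
            hypergeometric_enrichment(["NOTINBG"], self.BACKGROUND, {})
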