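"""Recurrence outcomes: recurrence-free survival, lead times, recurrence
summaries by cfDNA positivity, and hypergeometric pathway enrichment.

RFS is the interval from radical surgery to recurrence (event) or last
follow-up (censored), converted to months at 30.44 days/month. The
Kaplan-Meier product-limit estimator and the log-rank test are implemented
from their standard formulas; pathway over-representation uses the
upper-tail hypergeometric test with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedStatisticError, ValidationError
from .models import EnrichmentResult, MaxAfResult, SampleRecord, SurvivalCurve
from .utils import round_half_up

DAYS_PER_MONTH = 30.44


def compute_rfs(record: SampleRecord) -> tuple[float, bool]:
    """(time in months, event flag) for one patient.

    Event time is the recurrence date when the patient recurred, else the
    last follow-up date (censored). Date-ordering invariants are enforced
    by :class:`SampleRecord` at construction.
    """
    end = record.recurrence_date if record.recurrence else record.last_followup_date
    days = (end - record.surgery_date).days
    if days < 0:
        raise ValidationError("dates: follow-up precedes surgery")
    return days / DAYS_PER_MONTH, record.recurrence


def km_estimate(times: Sequence[float], events: Sequence[bool],
                ) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    At each distinct event time t_i with d_i events among n_i at risk the
    survival multiplies by (1 - d_i/n_i); censored subjects leave the risk
    set after their censoring time.
    """
    if len(times) != len(events):
        raise ValidationError("times/events: unequal lengths")
    if not times:
        raise ValidationError("times: empty input")
    order = np.argsort(np.asarray(times, dtype=float), kind="stable")
    t = np.asarray(times, dtype=float)[order]
    e = np.asarray([bool(x) for x in events])[order]
    event_times, at_risk, n_events, survival = [], [], [], []
    s = 1.0
    n = len(t)
    i = 0
    while i < n:
        current = t[i]
        d = 0
        j = i
        while j < n and t[j] == current:
            d += int(e[j])
            j += 1
        risk = n - i
        if d > 0:
            s *= 1.0 - d / risk
            event_times.append(float(current))
            at_risk.append(risk)
            n_events.append(d)
            survival.append(s)
        i = j
    return SurvivalCurve(event_times=tuple(event_times),
                         at_risk=tuple(at_risk),
                         events=tuple(n_events),
                         survival=tuple(survival))


def logrank_test(group_a: tuple[Sequence[float], Sequence[bool]],
                 group_b: tuple[Sequence[float], Sequence[bool]],
                 ) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value, 1 df).

    At each pooled event time the observed events in group A are compared
    with the expectation under the hypergeometric null; the statistic is
    (sum(O - E))^2 / sum(V). Undefined when no events occur in either group.
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], bool)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], bool)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("groups: both groups must be nonempty")
    if not (ea.any() or eb.any()):
        raise UndefinedStatisticError("log-rank undefined: no events observed")
    pooled_event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    variance = 0.0
    for t in pooled_event_times:
        n_a = int((ta >= t).sum())
        n_b = int((tb >= t).sum())
        d_a = int(((ta == t) & ea).sum())
        d_b = int(((tb == t) & eb).sum())
        n = n_a + n_b
        d = d_a + d_b
        if n <= 1 or d == 0:
            continue
        expected_a = d * n_a / n
        o_minus_e += d_a - expected_a
        variance += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if variance <= 0:
        raise UndefinedStatisticError(
            "log-rank undefined: zero variance (no at-risk overlap)")
    chi_square = o_minus_e ** 2 / variance
    p = float(stats.chi2.sf(chi_square, df=1))
    return float(chi_square), p


@dataclass(frozen=True)
class LeadTimeSummary:
    """Days by which cfDNA positivity preceded radiographic recurrence."""

    lead_days: tuple[int, ...]
    median_days: float
    mean_days: float


def summarize_lead_times(lead_days: Sequence[int]) -> LeadTimeSummary:
    """Median (lower-middle convention for even n) and mean of per-case lead
    times in days."""
    if not lead_days:
        raise ValidationError("lead_days: empty input")
    ordered = sorted(lead_days)
    n = len(ordered)
    median = float(ordered[(n - 1) // 2])
    mean = sum(ordered) / n
    return LeadTimeSummary(lead_days=tuple(lead_days), median_days=median,
                           mean_days=mean)


@dataclass(frozen=True)
class GroupOutcome:
    """Recurrence summary for one positivity group."""

    n: int
    recurrences: int
    recurrence_pct: float | None
    mean_recurrent_maxaf_pct: float | None


def recurrence_summary(records: Sequence[SampleRecord],
                       maxaf_results: Mapping[str, MaxAfResult],
                       ) -> dict[str, GroupOutcome]:
    """Recurrence counts and proportions per cfDNA positivity group, with
    the mean MaxAF of the recurrent cases in each group."""
    missing = [r.sample_id for r in records
               if r.sample_id not in maxaf_results]
    if missing:
        raise ValidationError(
            f"maxaf_results: positivity unknown for {missing[:5]}")
    summary: dict[str, GroupOutcome] = {}
    for group, positive in (("positive", True), ("negative", False)):
        members = [r for r in records
                   if maxaf_results[r.sample_id].positive is positive]
        recurrent = [r for r in members if r.recurrence]
        maxafs = [maxaf_results[r.sample_id].maxaf_pct for r in recurrent]
        summary[group] = GroupOutcome(
            n=len(members),
            recurrences=len(recurrent),
            recurrence_pct=(
                None if not members
                else round_half_up(100.0 * len(recurrent) / len(members))),
            mean_recurrent_maxaf_pct=(
                None if not maxafs
                else round_half_up(sum(maxafs) / len(maxafs))),
        )
    return summary


def hypergeometric_enrichment(query_genes: Sequence[str],
                              background_genes: Sequence[str],
                              pathways: Mapping[str, frozenset[str] | set[str]],
                              ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of each pathway in the
    query gene set, with Benjamini-Hochberg q-values across pathways.

    Both the query and every pathway are restricted to the background
    universe; a query gene outside the background is an error.
    """
    background = set(background_genes)
    query = set(query_genes)
    offenders = sorted(query - background)
    if offenders:
        raise ValidationError(
            f"query_genes: not in background: {offenders[:10]}")
    names = list(pathways)
    p_values = []
    overlaps = []
    sizes = []
    for name in names:
        members = set(pathways[name]) & background
        overlap = len(query & members)
        # P(X >= overlap), X ~ Hypergeom(N=|background|, K=|pathway|, n=|query|)
        p = float(stats.hypergeom.sf(overlap - 1, len(background),
                                     len(members), len(query)))
        p_values.append(min(max(p, np.finfo(float).tiny), 1.0))
        overlaps.append(overlap)
        sizes.append(len(members))
    if not names:
        return []
    _, q_values, _, _ = multipletests(p_values, method="fdr_bh")
    results = [EnrichmentResult(pathway_id=name, overlap=overlaps[i],
                                pathway_size=sizes[i], query_size=len(query),
                                p_value=p_values[i],
                                q_value=float(min(max(q_values[i],
                                                      p_values[i]), 1.0)))
               for i, name in enumerate(names)]
    return sorted(results, key=lambda r: (r.p_value, r.pathway_id))
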