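"""FLD/TIS concordance partitions, summaries and Cohen's kappa."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pericfdna.concordance import (cohens_kappa_unweighted,
                                   concordance_summary, match_variants,
                                   per_gene_concordance,
                                   variant_sensitivity_pct)
from pericfdna.errors import UndefinedStatisticError, ValidationError
from pericfdna.utils import round_half_up

from conftest import make_variant, random_variants


class TestMatchVariants:
    def test_identical_lists_all_shared(self, rng):
        variants = random_variants(rng, 20)
        shared, fld_only, tis_only = match_variants(variants, variants)
        assert len(shared) == len({v.site_key for v in variants})
        assert not fld_only and not tis_only

    def test_disjoint_lists_share_nothing(self):
        fld = [make_variant(pos=1)]
        tis = [make_variant(pos=2, origin="TIS")]
        shared, fld_only, tis_only = match_variants(fld, tis)
        assert not shared
        assert len(fld_only) == len(tis_only) == 1

    def test_partition_equals_set_algebra_oracle(self, rng):
        fld = random_variants(rng, 40)
        tis = random_variants(rng, 40, origin="TIS") + fld[:15]
        shared, fld_only, tis_only = match_variants(fld, tis)
        f = {v.site_key for v in fld}
        t = {v.site_key for v in tis}
        assert shared == f & t
        assert fld_only == f - t
        assert tis_only == t - f
        # conservation: the three parts tile the union
        assert shared | fld_only | tis_only == f | t
        assert not (shared & fld_only or shared & tis_only
                    or fld_only & tis_only)


class TestSummary:
    def test_reported_fractions_reproduce_73_percent_sensitivity(self):
        sens = variant_sensitivity_pct(56.0, 20.3)
        assert round(sens) == 73
        assert round_half_up(sens) == pytest.approx(73.4)

    def test_all_shared_gives_100_0_0(self, rng):
        variants = random_variants(rng, 15)
        summary = concordance_summary([match_variants(variants, variants)])
        assert (summary.shared_pct, summary.fld_only_pct,
                summary.tis_only_pct) == (100.0, 0.0, 0.0)
        assert summary.fld_variant_sensitivity_pct == 100.0

    def test_driver_only_is_a_restriction(self, small_cohort):
        by_patient = {}
        for v in small_cohort.variants:
            if v.origin in ("FLD", "TIS"):
                by_patient.setdefault(v.sample_id, {"FLD": [], "TIS": []})[
                    v.origin].append(v)
        partitions = [match_variants(d["FLD"], d["TIS"])
                      for d in by_patient.values()]
        full = concordance_summary(partitions)
        drivers = concordance_summary(partitions, driver_only=True)
        assert drivers.shared <= full.shared
        assert drivers.fld_only <= full.fld_only
        assert drivers.tis_only <= full.tis_only

    def test_planted_sharing_recovered_from_filtered_calls(self):
        """The pooled shared fraction measured after the full filter cascade
        recovers the generator's planted partition within 3 binomial SE."""
        from pericfdna.filters import run_filter_cascade
        from pericfdna.simulate import SimulationConfig, generate_cohort

        cohort = generate_cohort(SimulationConfig(n_pm=200, n_nonpm=0,
                                                  seed=13))
        grouped = {}
        for v in cohort.variants:
            grouped.setdefault(v.sample_id, {"FLD": [], "TIS": [],
                                             "WBC": []})[v.origin].append(v)
        partitions = []
        for pid in grouped:
            fld, _ = run_filter_cascade(grouped[pid]["FLD"],
                                        grouped[pid]["WBC"], "fluid")
            tis, _ = run_filter_cascade(grouped[pid]["TIS"],
                                        grouped[pid]["WBC"], "tissue")
            partitions.append(match_variants(fld, tis))
        measured = concordance_summary(partitions)
        shared = fld_only = tis_only = 0
        for truth in cohort.truth.patients.values():
            shared += len(truth.shared_keys)
            fld_only += len(truth.fld_somatic_keys - truth.shared_keys)
            tis_only += len(truth.tis_somatic_keys - truth.shared_keys)
        union = shared + fld_only + tis_only
        planted = 100 * shared / union
        se = 100 * np.sqrt((planted / 100) * (1 - planted / 100) / union)
        assert abs(measured.shared_pct - planted) <= 3 * se

    def test_empty_union_rejected(self):
        with pytest.raises(ValidationError):
            concordance_summary([(frozenset(), frozenset(), frozenset())])


class TestPerGene:
    def test_absent_gene_counts_zero(self):
        parts = [match_variants([make_variant()], [make_variant()])]
        assert per_gene_concordance(parts, "NOTAGENE") == (0, 0)

    def test_universally_shared_gene(self):
        parts = [match_variants([make_variant(sample_id=f"P{i}")],
                                [make_variant(sample_id=f"P{i}")])
                 for i in range(8)]
        assert per_gene_concordance(parts, "KRAS") == (8, 0)

    def test_counts_match_per_patient_enumeration(self, small_cohort):
        by_patient = {}
        for v in small_cohort.variants:
            if v.origin in ("FLD", "TIS"):
                by_patient.setdefault(v.sample_id, {"FLD": [], "TIS": []})[
                    v.origin].append(v)
        partitions = [match_variants(d["FLD"], d["TIS"])
                      for d in by_patient.values()]
        for gene in ("KRAS", "TP53"):
            n_shared, n_discordant = per_gene_concordance(partitions, gene)
            expected_shared = expected_discordant = 0
            for shared, fld_only, tis_only in partitions:
                if any(k[0] == gene for k in shared):
                    expected_shared += 1
                elif any(k[0] == gene for k in fld_only | tis_only):
                    expected_discordant += 1
            assert (n_shared, n_discordant) == (expected_shared,
                                                expected_discordant)


class TestKappa:
    def test_perfect_agreement(self):
        calls = [True, False, True, True, False]
        assert cohens_kappa_unweighted(calls, calls) == pytest.approx(1.0)

    def test_chance_level_agreement_is_zero(self):
        # p_o = 0.5 and matching marginals 0.5/0.5 give p_e = 0.5, kappa 0
        a = [True, True, False, False]
        b = [True, False, True, False]
        assert cohens_kappa_unweighted(a, b) == pytest.approx(0.0)

    def test_matches_hand_formula_on_random_fixture(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 40))
            a = list(rng.random(n) < 0.4)
            b = list(rng.random(n) < 0.6)
            pa, pb = sum(a) / n, sum(b) / n
            p_e = pa * pb + (1 - pa) * (1 - pb)
            if p_e >= 1.0:
                continue
            p_o = sum(x == y for x, y in zip(a, b)) / n
            assert cohens_kappa_unweighted(a, b) == pytest.approx(
                (p_o - p_e) / (1 - p_e))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score
        a = list(rng.random(50) < 0.5)
        b = list(rng.random(50) < 0.5)
        assert cohens_kappa_unweighted(a, b) == pytest.approx(
            cohen_kappa_score(a, b))

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2,
                    max_size=60))
    def test_symmetric_and_bounded(self, pairs):
        a = [x for x, _ in pairs]
        b = [y for _, y in pairs]
        try:
            k_ab = cohens_kappa_unweighted(a, b)
        except UndefinedStatisticError:
            assert len(set(a)) == 1 and len(set(b)) == 1
            return
        assert k_ab == pytest.approx(cohens_kappa_unweighted(b, a))
        assert -1.0 - 1e-12 <= k_ab <= 1.0 + 1e-12

    def test_constant_raters_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cohens_kappa_unweighted([True, True], [True, True])
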