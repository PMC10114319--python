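"""Depth-ratio CNV caller: normalization, GC correction, reference panel,
copy-number calls and chr20q classification."""

import numpy as np
import pytest
from dataclasses import replace

from pericfdna.cnv import (build_reference, call_copy_number, call_sample,
                           classify_chr20q, gc_correct, normalize_coverage,
                           prepare_profile)
from pericfdna.errors import ValidationError
from pericfdna.models import CaptureRegion, CnvCall, CoverageProfile
from pericfdna.simulate import generate_coverage_panel, plant_cnv


def profile_from(depths, gcs=None, sample_id="S1"):
    gcs = gcs if gcs is not None else [0.5] * len(depths)
    regions = tuple(
        CaptureRegion(region_id=f"R{i:04d}", chrom="chr1", start=i * 1000,
                      end=i * 1000 + 300, gc_fraction=g, depth=float(d))
        for i, (d, g) in enumerate(zip(depths, gcs)))
    return CoverageProfile(sample_id=sample_id, regions=regions)


class TestNormalize:
    def test_uniform_depth_maps_to_one(self):
        out = normalize_coverage(profile_from([500.0] * 8))
        assert all(r.depth == pytest.approx(1.0) for r in out.regions)

    def test_two_region_arithmetic(self):
        out = normalize_coverage(profile_from([100.0, 300.0]))
        assert [r.depth for r in out.regions] == [0.5, 1.5]

    def test_mean_is_one_within_fp(self, rng):
        out = normalize_coverage(profile_from(rng.uniform(10, 5000, 200)))
        assert np.mean(out.depths()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_coverage_rejected(self):
        with pytest.raises(ValidationError, match="depth"):
            normalize_coverage(profile_from([0.0, 0.0]))


class TestGcCorrect:
    def test_gc_flat_profile_is_noop(self, rng):
        prof = normalize_coverage(profile_from(rng.uniform(100, 900, 50)))
        out = gc_correct(prof)
        assert np.allclose(out.depths(), prof.depths(), atol=1e-12)

    def test_constant_depth_stays_constant(self, rng):
        prof = profile_from([1.0] * 60, gcs=list(rng.uniform(0.3, 0.7, 60)))
        out = gc_correct(prof)
        assert np.allclose(out.depths(), 1.0, atol=1e-12)

    def test_planted_high_gc_inflation_corrected(self, rng):
        gcs = list(rng.uniform(0.30, 0.45, 100)) + \
            list(rng.uniform(0.55, 0.70, 100))
        depths = list(rng.normal(1.0, 0.02, 100)) + \
            list(rng.normal(2.0, 0.04, 100))  # high-GC bins inflated 2x
        out = gc_correct(normalize_coverage(profile_from(depths, gcs)))
        corrected = np.array(out.depths())
        ratio = (np.median(corrected[100:]) / np.median(corrected[:100]))
        assert ratio == pytest.approx(1.0, rel=0.05)


class TestReference:
    def test_identical_profiles_reproduce_one(self, rng):
        depths = rng.uniform(200, 2000, 40)
        gcs = rng.uniform(0.3, 0.7, 40)
        panel = [profile_from(depths, gcs, sample_id=f"S{i}")
                 for i in range(50)]
        reference = build_reference(panel)
        prepared = prepare_profile(panel[0])
        assert np.allclose(reference.depths, prepared.depths(), atol=1e-12)

    def test_small_panel_rejected_citing_minimum(self, rng):
        panel = [profile_from(rng.uniform(200, 2000, 10), sample_id=f"S{i}")
                 for i in range(49)]
        with pytest.raises(ValidationError, match="50"):
            build_reference(panel)

    def test_region_mismatch_rejected(self, rng):
        panel = [profile_from(rng.uniform(200, 2000, 10), sample_id=f"S{i}")
                 for i in range(50)]
        bad = profile_from(rng.uniform(200, 2000, 9), sample_id="S49")
        with pytest.raises(ValidationError, match="region set"):
            build_reference(panel[:-1] + [bad])

    def test_reference_is_per_region_mean(self, rng):
        panel = [profile_from(rng.uniform(200, 2000, 12), sample_id=f"S{i}")
                 for i in range(50)]
        reference = build_reference(panel)
        prepared = np.array([prepare_profile(p).depths() for p in panel])
        assert np.allclose(reference.depths, prepared.mean(axis=0))


class TestCallCopyNumber:
    @pytest.fixture
    def panel_and_reference(self):
        panel = generate_coverage_panel(60, n_regions=80, seed=11)
        return panel, build_reference(panel)

    def test_sample_equal_to_reference_is_neutral(self, rng):
        depths = rng.uniform(200, 2000, 30)
        panel = [profile_from(depths, sample_id=f"S{i}") for i in range(50)]
        reference = build_reference(panel)
        calls = call_copy_number(prepare_profile(panel[0]), reference)
        assert all(c.state == "neutral" for c in calls)
        assert all(c.copy_number == pytest.approx(2.0) for c in calls)

    def test_ratio_of_1_5_is_amplification(self, rng):
        depths = np.full(40, 1000.0)
        panel = [profile_from(depths, sample_id=f"S{i}") for i in range(50)]
        reference = build_reference(panel)
        sample = profile_from(depths, sample_id="case")
        sample = plant_cnv(sample, ["R0000"], 1.5)
        # re-normalization shifts the baseline slightly; use raw ratio route
        prepared = normalize_coverage(sample)
        calls = call_copy_number(prepared, reference)
        amped = [c for c in calls if c.region_id == "R0000"]
        assert amped[0].copy_number == pytest.approx(
            2 * 1.5 / np.mean(sample.depths()) * 1000, rel=1e-6)
        assert amped[0].state == "amplification"

    def test_scaling_invariance(self, panel_and_reference):
        panel, reference = panel_and_reference
        sample = panel[0]
        scaled = CoverageProfile(
            sample_id=sample.sample_id,
            regions=tuple(replace(r, depth=r.depth * 37.5)
                          for r in sample.regions))
        calls_a = call_sample(sample, reference)
        calls_b = call_sample(scaled, reference)
        assert [(c.region_id, c.state) for c in calls_a] == \
            [(c.region_id, c.state) for c in calls_b]
        assert np.allclose([c.copy_number for c in calls_a],
                           [c.copy_number for c in calls_b])

    def test_planted_amplification_recovered_end_to_end(self,
                                                        panel_and_reference):
        panel, reference = panel_and_reference
        extra = generate_coverage_panel(61, n_regions=80, seed=11)[60]
        planted = plant_cnv(extra, ["R0004", "R0017"], 1.5)
        calls = {c.region_id: c for c in call_sample(planted, reference)}
        assert calls["R0004"].state == "amplification"
        assert calls["R0004"].copy_number == pytest.approx(3.0, rel=0.1)
        assert calls["R0017"].state == "amplification"

    def test_zero_reference_region_excluded(self, rng):
        depths = rng.uniform(200, 2000, 10)
        panel = [profile_from(depths, sample_id=f"S{i}") for i in range(50)]
        reference = build_reference(panel)
        zeroed = replace(reference, depths=(0.0,) + reference.depths[1:])
        calls = call_copy_number(prepare_profile(panel[0]), zeroed)
        assert len(calls) == 9
        assert all(c.region_id != "R0000" for c in calls)


class TestChr20q:
    def _calls(self, states):
        return [CnvCall(sample_id="S", region_id=f"R{i:04d}",
                        copy_number=3.0 if s == "amplification" else 2.0,
                        state=s) for i, s in enumerate(states)]

    def test_all_neutral_is_mss_n(self):
        calls = self._calls(["neutral"] * 6)
        assert classify_chr20q(calls, [c.region_id for c in calls]) == "MSS-N"

    def test_all_amplified_is_mss_a(self):
        calls = self._calls(["amplification"] * 6)
        assert classify_chr20q(calls, [c.region_id for c in calls]) == "MSS-A"

    def test_half_amplified_is_mss_a_at_default_boundary(self):
        calls = self._calls(["amplification"] * 3 + ["neutral"] * 3)
        assert classify_chr20q(calls, [c.region_id for c in calls]) == "MSS-A"

    def test_no_chr20q_regions_rejected(self):
        with pytest.raises(ValidationError):
            classify_chr20q(self._calls(["neutral"]), [])
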