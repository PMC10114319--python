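"""Depth-ratio copy-number calling against a reference panel.

Coverage for each sample is normalized to its mean region depth, corrected
for GC bias by binned-median scaling, and divided by a reference built the
same way from >= 50 CNV-free samples. Copy number is 2x the depth ratio
(diploid baseline). Calls use the study's detection limits: copy number
<= 1.75 is a deletion and >= 2.75 an amplification (inclusive limits).
Samples are classified MSS-A (chromosome-20q amplified) when at least half
of the chr20q capture regions are called amplified, else MSS-N.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .models import CaptureRegion, CnvCall, CoverageProfile

DELETION_LIMIT = 1.75
AMPLIFICATION_LIMIT = 2.75


def normalize_coverage(profile: CoverageProfile) -> CoverageProfile:
    """Divide every region depth by the sample's mean region depth, so the
    normalized profile has mean 1 (cross-sample comparability)."""
    if not profile.regions:
        raise ValidationError("regions: profile has no regions")
    depths = np.asarray(profile.depths(), dtype=float)
    mean = depths.mean()
    if mean <= 0:
        raise ValidationError("depth: all-zero coverage cannot be normalized")
    regions = tuple(replace(r, depth=r.depth / mean) for r in profile.regions)
    return CoverageProfile(sample_id=profile.sample_id, regions=regions)


def gc_correct(profile: CoverageProfile, n_bins: int = 10) -> CoverageProfile:
    """Binned-median GC correction.

    Regions are binned by GC fraction (equal-width bins over the observed
    GC range); each region's depth is rescaled by global_median/bin_median,
    which is a no-op when every bin's median equals the global median (in
    particular for GC-flat profiles, where all regions share one bin).
    """
    if not profile.regions:
        raise ValidationError("regions: profile has no regions")
    gc = np.asarray([r.gc_fraction for r in profile.regions], dtype=float)
    depths = np.asarray(profile.depths(), dtype=float)
    global_median = float(np.median(depths))
    if global_median <= 0:
        raise ValidationError("depth: non-positive median depth")
    lo, hi = gc.min(), gc.max()
    if hi - lo <= 0 or n_bins < 2:
        return profile
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_index = np.clip(np.digitize(gc, edges[1:-1]), 0, n_bins - 1)
    factors = np.ones_like(depths)
    for b in range(n_bins):
        mask = bin_index == b
        if not mask.any():
            continue  # empty bin: no member regions, nothing to correct
        bin_median = float(np.median(depths[mask]))
        if bin_median > 0:
            factors[mask] = global_median / bin_median
    regions = tuple(replace(r, depth=r.depth * f)
                    for r, f in zip(profile.regions, factors))
    return CoverageProfile(sample_id=profile.sample_id, regions=regions)


def prepare_profile(profile: CoverageProfile,
                    n_bins: int = 10) -> CoverageProfile:
    """Normalization followed by GC correction (the caller's input contract)."""
    return gc_correct(normalize_coverage(profile), n_bins=n_bins)


@dataclass(frozen=True)
class ReferencePanel:
    """Per-region mean of normalized, GC-corrected depths over a CNV-free
    panel; the denominator of the copy-number ratio."""

    region_ids: tuple[str, ...]
    depths: tuple[float, ...]
    regions: tuple[CaptureRegion, ...]
    n_samples: int

    def depth_of(self, region_id: str) -> float:
        return dict(zip(self.region_ids, self.depths))[region_id]


def build_reference(panel: Sequence[CoverageProfile], min_panel: int = 50,
                    n_bins: int = 10) -> ReferencePanel:
    """Average >= ``min_panel`` CNV-free profiles into a per-region reference.

    All profiles must share the same region set; raw profiles are
    normalized and GC-corrected before averaging.
    """
    if len(panel) < min_panel:
        raise ValidationError(
            f"panel: {len(panel)} samples < required minimum {min_panel}")
    region_ids = panel[0].region_ids
    id_set = set(region_ids)
    for profile in panel[1:]:
        if set(profile.region_ids) != id_set:
            raise ValidationError(
                f"panel: sample {profile.sample_id} region set differs "
                "from the first panel sample")
    prepared = [prepare_profile(p, n_bins=n_bins) for p in panel]
    by_id = []
    for profile in prepared:
        depth_map = {r.region_id: r.depth for r in profile.regions}
        by_id.append([depth_map[rid] for rid in region_ids])
    means = np.asarray(by_id, dtype=float).mean(axis=0)
    return ReferencePanel(region_ids=tuple(region_ids),
                          depths=tuple(float(m) for m in means),
                          regions=panel[0].regions,
                          n_samples=len(panel))


def call_copy_number(sample: CoverageProfile, reference: ReferencePanel,
                     deletion_limit: float = DELETION_LIMIT,
                     amplification_limit: float = AMPLIFICATION_LIMIT,
                     ) -> list[CnvCall]:
    """Per-region copy number = 2 x (sample depth / reference depth) from a
    normalized, GC-corrected sample profile.

    Regions with zero reference depth are uncallable and excluded.
    """
    ref_map = dict(zip(reference.region_ids, reference.depths))
    missing = [r.region_id for r in sample.regions if r.region_id not in ref_map]
    if missing:
        raise ValidationError(
            f"reference: no reference depth for region(s) {missing[:5]}")
    calls: list[CnvCall] = []
    for region in sample.regions:
        ref_depth = ref_map[region.region_id]
        if ref_depth <= 0:
            continue  # uncallable
        copy_number = 2.0 * region.depth / ref_depth
        if copy_number <= deletion_limit:
            state = "deletion"
        elif copy_number >= amplification_limit:
            state = "amplification"
        else:
            state = "neutral"
        calls.append(CnvCall(sample_id=sample.sample_id,
                             region_id=region.region_id,
                             copy_number=copy_number, state=state))
    return calls


def call_sample(raw_profile: CoverageProfile, reference: ReferencePanel,
                deletion_limit: float = DELETION_LIMIT,
                amplification_limit: float = AMPLIFICATION_LIMIT,
                n_bins: int = 10) -> list[CnvCall]:
    """Convenience: prepare a raw profile, then call copy number."""
    return call_copy_number(prepare_profile(raw_profile, n_bins=n_bins),
                            reference, deletion_limit, amplification_limit)


def classify_chr20q(calls: Sequence[CnvCall],
                    chr20q_region_ids: Sequence[str],
                    min_fraction: float = 0.5) -> str:
    """Arm-level chromosome-20q call: "MSS-A" when at least ``min_fraction``
    of the chr20q regions are amplified (inclusive at the boundary), else
    "MSS-N"."""
    wanted = set(chr20q_region_ids)
    if not wanted:
        raise ValidationError("chr20q_region_ids: empty region set")
    arm_calls = [c for c in calls if c.region_id in wanted]
    if not arm_calls:
        raise ValidationError(
            "calls: no calls cover the chr20q regions")
    amplified = sum(1 for c in arm_calls if c.state == "amplification")
    return "MSS-A" if amplified / len(arm_calls) >= min_fraction else "MSS-N"
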