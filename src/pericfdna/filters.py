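"""Post-calling variant filter cascade and tumor mutational burden.

The cascade reproduces the study's analysis-ready filtering of called
variants, applied in a fixed order (the rules commute on the final set;
the order only affects per-rule attribution in the report):

1. depth — loci with depth < 100 are removed;
2. supporting reads — SNVs need >= 8 supporting reads; indels need >= 2
   in fluid (lavage cfDNA) and >= 5 in tissue; fusion/CNV/LGR calls pass
   through unchanged;
3. population frequency — variants above 0.1% in population databases are
   treated as SNPs and removed (an unknown frequency, stored as 0, is kept);
4. matched normal — variants whose (chrom, pos, ref, alt) also appears in
   the patient's white-blood-cell calls are removed as germline or clonal
   hematopoiesis.

Each filter is idempotent and order-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .models import MAXAF_ELIGIBLE_CLASSES, FilterReport, VariantCall

ORIGIN_TYPES = ("fluid", "tissue")

#: structural classes not subject to the supporting-read rule
PASSTHROUGH_CLASSES = ("Fusion", "CNV", "LGR")


@dataclass(frozen=True)
class FilterParams:
    """Cascade thresholds; defaults are the study's stated rules."""

    min_depth: int = 100
    snv_min_support: int = 8
    indel_min_support_fluid: int = 2
    indel_min_support_tissue: int = 5
    max_population_frequency: float = 0.001


def apply_depth_filter(variants: Sequence[VariantCall],
                       min_depth: int = 100) -> list[VariantCall]:
    """Keep variants with depth >= min_depth (strict '< min_depth' removal)."""
    return [v for v in variants if v.depth >= min_depth]


def apply_support_filter(variants: Sequence[VariantCall], origin_type: str,
                         snv_min: int = 8, indel_min_fluid: int = 2,
                         indel_min_tissue: int = 5) -> list[VariantCall]:
    """Supporting-read rule. ``origin_type`` is "fluid" for lavage cfDNA and
    "tissue" for tumor/WBC DNA; it selects the indel minimum."""
    if origin_type not in ORIGIN_TYPES:
        raise ValidationError(
            f"origin_type: {origin_type!r} not one of {ORIGIN_TYPES}")
    indel_min = indel_min_fluid if origin_type == "fluid" else indel_min_tissue
    kept = []
    for v in variants:
        if v.variant_class == "SNV":
            if v.supporting_reads >= snv_min:
                kept.append(v)
        elif v.variant_class == "Indel":
            if v.supporting_reads >= indel_min:
                kept.append(v)
        else:
            kept.append(v)
    return kept


def apply_population_filter(variants: Sequence[VariantCall],
                            max_popfreq: float = 0.001) -> list[VariantCall]:
    """Remove presumed SNPs: population frequency strictly above max_popfreq
    (exactly 0.1% is retained)."""
    return [v for v in variants if v.population_frequency <= max_popfreq]


def subtract_matched_normal(case_variants: Sequence[VariantCall],
                            normal_variants: Sequence[VariantCall],
                            ) -> list[VariantCall]:
    """Remove case variants whose locus key (chrom, pos, ref, alt) occurs in
    the matched-normal (WBC) call set."""
    normal_keys = {v.key for v in normal_variants}
    return [v for v in case_variants if v.key not in normal_keys]


def run_filter_cascade(case_variants: Sequence[VariantCall],
                       normal_variants: Sequence[VariantCall],
                       origin_type: str,
                       params: FilterParams | None = None,
                       ) -> tuple[list[VariantCall], FilterReport]:
    """Apply depth -> support -> population-frequency -> matched-normal and
    account for every removal."""
    params = params or FilterParams()
    stage0 = list(case_variants)
    stage1 = apply_depth_filter(stage0, params.min_depth)
    stage2 = apply_support_filter(
        stage1, origin_type, snv_min=params.snv_min_support,
        indel_min_fluid=params.indel_min_support_fluid,
        indel_min_tissue=params.indel_min_support_tissue)
    stage3 = apply_population_filter(stage2, params.max_population_frequency)
    stage4 = subtract_matched_normal(stage3, normal_variants)
    report = FilterReport(
        input_count=len(stage0),
        removed_by_depth=len(stage0) - len(stage1),
        removed_by_support=len(stage1) - len(stage2),
        removed_by_popfreq=len(stage2) - len(stage3),
        removed_by_matched_normal=len(stage3) - len(stage4),
        output_count=len(stage4),
    )
    return stage4, report


def compute_tmb(variants: Iterable[VariantCall],
                panel_megabases: float = 1.64) -> float:
    """Tumor mutational burden: SNV/Indel count per megabase of panel
    footprint (structural classes are not counted)."""
    if panel_megabases <= 0:
        raise ValidationError(
            f"panel_megabases: must be > 0, got {panel_megabases}")
    count = sum(1 for v in variants
                if v.variant_class in MAXAF_ELIGIBLE_CLASSES)
    return count / panel_megabases
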