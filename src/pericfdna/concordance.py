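"""Lavage-versus-tissue variant concordance.

Matched FLD and TIS variant sets of one patient are partitioned by exact
gene-qualified identity (gene, chrom, pos, ref, alt) into shared,
FLD-only and TIS-only sets. Pooled over patients, the partition yields the
shared/specific percentages of the variant union and a variant-level
sensitivity of the lavage against tissue as truth,
100 * shared / (shared + tis_only). Agreement at the patient-by-gene level
(mutated or not in each compartment) is summarized by unweighted Cohen's
kappa.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .errors import UndefinedStatisticError, ValidationError
from .models import ConcordanceSummary, VariantCall
from .study import DRIVER_GENES
from .utils import round_half_up

SiteKey = tuple[str, str, int, str, str]
Partition = tuple[frozenset, frozenset, frozenset]


def match_variants(fld_variants: Sequence[VariantCall],
                   tis_variants: Sequence[VariantCall],
                   ) -> Partition:
    """Partition one patient's matched variant sets into
    (shared, fld_only, tis_only) sets of site keys."""
    fld_keys = frozenset(v.site_key for v in fld_variants)
    tis_keys = frozenset(v.site_key for v in tis_variants)
    return (fld_keys & tis_keys, fld_keys - tis_keys, tis_keys - fld_keys)


def variant_sensitivity_pct(shared: float, tis_only: float) -> float | None:
    """Lavage variant-level sensitivity with tissue as truth; accepts counts
    or percentages (the ratio is scale-free). None when shared + tis_only
    is 0."""
    denominator = shared + tis_only
    if denominator == 0:
        return None
    return 100.0 * shared / denominator


def concordance_summary(partitions: Iterable[Partition],
                        driver_only: bool = False,
                        driver_genes: Sequence[str] = DRIVER_GENES,
                        ) -> ConcordanceSummary:
    """Pool per-patient partitions into a cohort-level summary.

    ``driver_only`` restricts every set to the configured driver genes
    before counting (a restriction, so counts never exceed the all-gene
    summary).
    """
    drivers = set(driver_genes)

    def _count(keys: frozenset) -> int:
        if driver_only:
            keys = frozenset(k for k in keys if k[0] in drivers)
        return len(keys)

    shared = fld_only = tis_only = 0
    for part in partitions:
        s, f, t = part
        shared += _count(s)
        fld_only += _count(f)
        tis_only += _count(t)
    union = shared + fld_only + tis_only
    if union == 0:
        raise ValidationError("partitions: empty variant union")
    sens = variant_sensitivity_pct(shared, tis_only)
    pcts = _largest_remainder_percents((shared, fld_only, tis_only), union)
    return ConcordanceSummary(
        shared=shared, fld_only=fld_only, tis_only=tis_only,
        shared_pct=pcts[0], fld_only_pct=pcts[1], tis_only_pct=pcts[2],
        fld_variant_sensitivity_pct=(
            None if sens is None else round_half_up(sens)),
    )


def _largest_remainder_percents(counts: Sequence[int], total: int,
                                ) -> tuple[float, ...]:
    """Percentages to one decimal that sum to exactly 100.0: floor to
    tenths, then hand the leftover tenths to the largest remainders."""
    tenths = [1000 * c / total for c in counts]
    floors = [int(t) for t in tenths]
    leftover = 1000 - sum(floors)
    order = sorted(range(len(counts)), key=lambda i: tenths[i] - floors[i],
                   reverse=True)
    for i in order[:leftover]:
        floors[i] += 1
    return tuple(f / 10 for f in floors)


def per_gene_concordance(partitions: Iterable[Partition], gene: str,
                         ) -> tuple[int, int]:
    """Per gene: (patients with >= 1 shared variant, patients whose variants
    in that gene are confined to one compartment). A gene absent everywhere
    yields (0, 0)."""
    n_shared = n_discordant = 0
    for shared, fld_only, tis_only in partitions:
        has_shared = any(k[0] == gene for k in shared)
        has_specific = any(k[0] == gene for k in fld_only | tis_only)
        if has_shared:
            n_shared += 1
        elif has_specific:
            n_discordant += 1
    return n_shared, n_discordant


def cohens_kappa_unweighted(calls_a: Sequence[bool],
                            calls_b: Sequence[bool]) -> float:
    """Unweighted Cohen's kappa between two binary call vectors over the
    same units (here, patient x gene mutation status per compartment).

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and
    chance agreement p_e from the marginals. Undefined (typed error) when
    both raters are constant (p_e = 1).
    """
    if len(calls_a) != len(calls_b):
        raise ValidationError("calls_a/calls_b: unequal lengths")
    n = len(calls_a)
    if n < 2:
        raise ValidationError("calls: need at least 2 units")
    a = [bool(x) for x in calls_a]
    b = [bool(x) for x in calls_b]
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    pa, pb = sum(a) / n, sum(b) / n
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        raise UndefinedStatisticError(
            "kappa undefined: both raters are constant (chance agreement 1)")
    return (p_o - p_e) / (1.0 - p_e)
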