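"""Domain types for the peritoneal cfDNA diagnostic analysis.

Each patient contributes up to three matched sequencing compartments:

* **FLD** — cell-free DNA from peritoneal lavage fluid (the liquid biopsy,
  sequenced ultradeep, ~35,000x),
* **TIS** — DNA from the resected primary tumor (~1,000x), the mutational
  reference for concordance, and
* **WBC** — white blood cells, the matched normal used to subtract germline
  variants and clonal hematopoiesis.

All types validate their invariants at construction and raise
:class:`~pericfdna.errors.ValidationError` naming the offending field, so
that malformed inputs fail loudly rather than propagating silently.

Coordinate conventions: variant positions are 1-based inclusive (VCF
dialect); capture regions are 0-based half-open (BED dialect).
Allele fractions are stored as fractions in [0, 1]; MaxAF values are
reported as percent.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

from .errors import ValidationError

VARIANT_ORIGINS = ("FLD", "TIS", "WBC")
VARIANT_CLASSES = ("SNV", "Indel", "Fusion", "CNV", "LGR")
#: classes eligible for MaxAF (fusions, copy-number and large genomic
#: rearrangements are excluded from the positivity score)
MAXAF_ELIGIBLE_CLASSES = ("SNV", "Indel")

ARMS = ("PM", "nonPM")
COHORTS = ("training", "validation")


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ValidationError(f"{field_name}: {message}")


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one compartment of one patient."""

    sample_id: str
    origin: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    allele_fraction: float
    depth: int
    supporting_reads: int
    population_frequency: float = 0.0
    is_driver: bool = False

    def __post_init__(self) -> None:
        _require(bool(self.sample_id), "sample_id", "must be nonempty")
        _require(self.origin in VARIANT_ORIGINS, "origin",
                 f"{self.origin!r} not one of {VARIANT_ORIGINS}")
        _require(self.variant_class in VARIANT_CLASSES, "variant_class",
                 f"{self.variant_class!r} not one of {VARIANT_CLASSES}")
        _require(int(self.pos) >= 1, "pos", f"must be >= 1, got {self.pos}")
        _require(0.0 <= self.allele_fraction <= 1.0, "allele_fraction",
                 f"must be in [0, 1], got {self.allele_fraction}")
        _require(0.0 <= self.population_frequency <= 1.0, "population_frequency",
                 f"must be in [0, 1], got {self.population_frequency}")
        _require(int(self.depth) >= 0, "depth", "must be non-negative")
        _require(int(self.supporting_reads) >= 0, "supporting_reads",
                 "must be non-negative")
        _require(self.supporting_reads <= self.depth, "supporting_reads",
                 f"{self.supporting_reads} exceeds depth {self.depth}")
        if self.variant_class in MAXAF_ELIGIBLE_CLASSES:
            _require(bool(self.chrom) and bool(self.ref) and bool(self.alt),
                     "chrom/ref/alt",
                     "must be nonempty for SNV/Indel variants")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Locus identity used for matched-normal subtraction."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def site_key(self) -> tuple[str, str, int, str, str]:
        """Gene-qualified identity used for FLD/TIS concordance matching."""
        return (self.gene, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CaptureRegion:
    """One capture interval of the targeted panel, 0-based half-open."""

    region_id: str
    chrom: str
    start: int
    end: int
    gc_fraction: float
    depth: float

    def __post_init__(self) -> None:
        _require(bool(self.region_id), "region_id", "must be nonempty")
        _require(self.start < self.end, "start",
                 f"start {self.start} must be < end {self.end}")
        _require(0.0 <= self.gc_fraction <= 1.0, "gc_fraction",
                 f"must be in [0, 1], got {self.gc_fraction}")
        _require(self.depth >= 0, "depth", "must be non-negative")


@dataclass(frozen=True)
class CoverageProfile:
    """Per-region depth of coverage for one sample over the capture panel."""

    sample_id: str
    regions: tuple[CaptureRegion, ...]

    def __post_init__(self) -> None:
        _require(bool(self.sample_id), "sample_id", "must be nonempty")
        regions = tuple(self.regions)
        object.__setattr__(self, "regions", regions)
        ids = [r.region_id for r in regions]
        _require(len(ids) == len(set(ids)), "regions",
                 "region_ids must be unique within a sample")

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(r.region_id for r in self.regions)

    def depths(self) -> list[float]:
        return [r.depth for r in self.regions]


@dataclass(frozen=True)
class SampleRecord:
    """Clinical metadata for one patient.

    ``cfdna_positive`` is optional: it is unknown until the diagnostics
    stage classifies the patient's lavage MaxAF against the cutoff.
    """

    sample_id: str
    arm: str
    cohort: str
    pci_score: int
    chemo_pretreated: bool
    surgery_date: datetime.date
    recurrence: bool
    recurrence_date: datetime.date | None
    last_followup_date: datetime.date
    cfdna_positive: bool | None = None

    def __post_init__(self) -> None:
        _require(bool(self.sample_id), "sample_id", "must be nonempty")
        _require(self.arm in ARMS, "arm", f"{self.arm!r} not one of {ARMS}")
        _require(self.cohort in COHORTS, "cohort",
                 f"{self.cohort!r} not one of {COHORTS}")
        _require(self.pci_score >= 0, "pci_score", "must be >= 0")
        if self.arm == "PM":
            _require(self.pci_score > 0, "pci_score",
                     "must be > 0 for the PM arm")
        if self.recurrence:
            _require(self.recurrence_date is not None, "recurrence_date",
                     "required when recurrence is true")
        else:
            _require(self.recurrence_date is None, "recurrence_date",
                     "must be absent when recurrence is false")
        if self.recurrence_date is not None:
            _require(self.recurrence_date >= self.surgery_date,
                     "recurrence_date", "must be on/after surgery_date")
        _require(self.last_followup_date >= self.surgery_date,
                 "last_followup_date", "must be on/after surgery_date")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 diagnostic table: positive test = cfDNA positive, condition = PM."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            _require(getattr(self, name) >= 0, name, "must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class RocPoint:
    threshold_pct: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC over the distinct observed MaxAF scores.

    Operating points follow the strict ``score > threshold`` positivity
    rule, so sensitivity is non-increasing in the threshold.
    """

    points: tuple[RocPoint, ...]
    auc: float
    best_cutoff_pct: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        _require(0.0 <= self.auc <= 1.0, "auc", f"must be in [0, 1], got {self.auc}")
        sens = [p.sensitivity for p in self.points]
        _require(all(a >= b - 1e-12 for a, b in zip(sens, sens[1:])),
                 "points", "sensitivity must be non-increasing in threshold")
        thresholds = {p.threshold_pct for p in self.points}
        _require(self.best_cutoff_pct in thresholds, "best_cutoff_pct",
                 "must be one of the candidate thresholds")


@dataclass(frozen=True)
class MaxAfResult:
    """A sample's positivity score: maximum allele fraction (percent) over
    its SNV/Indel calls after filtering."""

    sample_id: str
    maxaf_pct: float
    n_eligible_variants: int
    positive: bool

    def __post_init__(self) -> None:
        _require(0.0 <= self.maxaf_pct <= 100.0, "maxaf_pct",
                 "must be in [0, 100]")
        _require(self.n_eligible_variants >= 0, "n_eligible_variants",
                 "must be >= 0")
        if self.n_eligible_variants == 0:
            _require(self.maxaf_pct == 0.0, "maxaf_pct",
                     "must be 0 when no eligible variants")


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for one run of the filter cascade; counts must conserve."""

    input_count: int
    removed_by_depth: int
    removed_by_support: int
    removed_by_popfreq: int
    removed_by_matched_normal: int
    output_count: int

    def __post_init__(self) -> None:
        for name in ("input_count", "removed_by_depth", "removed_by_support",
                     "removed_by_popfreq", "removed_by_matched_normal",
                     "output_count"):
            _require(getattr(self, name) >= 0, name, "must be non-negative")
        removed = (self.removed_by_depth + self.removed_by_support
                   + self.removed_by_popfreq + self.removed_by_matched_normal)
        _require(self.input_count == self.output_count + removed, "input_count",
                 "must equal output_count plus all removals")


CNV_STATES = ("deletion", "neutral", "amplification")


@dataclass(frozen=True)
class CnvCall:
    """Copy-number call for one capture region (diploid baseline = 2)."""

    sample_id: str
    region_id: str
    copy_number: float
    state: str

    def __post_init__(self) -> None:
        _require(self.copy_number >= 0, "copy_number", "must be >= 0")
        _require(self.state in CNV_STATES, "state",
                 f"{self.state!r} not one of {CNV_STATES}")


@dataclass(frozen=True)
class ConcordanceSummary:
    """Pooled shared / FLD-only / TIS-only partition of matched variant sets.

    ``fld_variant_sensitivity_pct`` treats tissue as truth:
    100 * shared / (shared + tis_only); None when the denominator is 0.
    """

    shared: int
    fld_only: int
    tis_only: int
    shared_pct: float
    fld_only_pct: float
    tis_only_pct: float
    fld_variant_sensitivity_pct: float | None

    def __post_init__(self) -> None:
        for name in ("shared", "fld_only", "tis_only"):
            _require(getattr(self, name) >= 0, name, "must be non-negative")
        total_pct = self.shared_pct + self.fld_only_pct + self.tis_only_pct
        _require(abs(total_pct - 100.0) <= 0.1 or total_pct == 0.0, "shared_pct",
                 "percents must sum to 100 within rounding")


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate over distinct event times."""

    event_times: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]
    survival: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("event_times", "at_risk", "events", "survival"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        n = len(self.event_times)
        _require(len(self.at_risk) == n and len(self.events) == n
                 and len(self.survival) == n, "event_times",
                 "parallel arrays must have equal length")
        _require(all(a < b for a, b in zip(self.event_times, self.event_times[1:])),
                 "event_times", "must be strictly increasing")
        _require(all(a >= b for a, b in zip(self.at_risk, self.at_risk[1:])),
                 "at_risk", "must be non-increasing")
        _require(all(0.0 <= s <= 1.0 for s in self.survival), "survival",
                 "must lie in [0, 1]")
        _require(all(a >= b - 1e-12 for a, b in zip(self.survival, self.survival[1:])),
                 "survival", "must be non-increasing")

    def survival_at(self, time: float) -> float:
        """Step-function evaluation; 1.0 before the first event."""
        value = 1.0
        for t, s in zip(self.event_times, self.survival):
            if t <= time:
                value = s
            else:
                break
        return value


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one gene set."""

    pathway_id: str
    overlap: int
    pathway_size: int
    query_size: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        _require(self.overlap >= 0, "overlap", "must be >= 0")
        _require(self.overlap <= min(self.pathway_size, self.query_size),
                 "overlap", "cannot exceed either set size")
        _require(0.0 < self.p_value <= 1.0, "p_value", "must be in (0, 1]")
        _require(0.0 < self.q_value <= 1.0, "q_value", "must be in (0, 1]")


@dataclass(frozen=True)
class PatientTruth:
    """Planted ground truth for one simulated patient (generator output)."""

    patient_id: str
    arm: str
    cohort: str
    cfdna_positive: bool
    chemo_suppressed: bool
    maxaf_target_pct: float
    germline_keys: frozenset = field(default_factory=frozenset)
    rare_germline_keys: frozenset = field(default_factory=frozenset)
    tis_somatic_keys: frozenset = field(default_factory=frozenset)
    fld_somatic_keys: frozenset = field(default_factory=frozenset)
    shared_keys: frozenset = field(default_factory=frozenset)
    mss_a: bool = False
    amplified_region_ids: tuple[str, ...] = ()
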