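"""Synthetic matched-cohort generator.

Because the motivating study deposited no patient-level data, every
downstream stage is exercised on synthetic cohorts whose statistical
structure mirrors the printed cohort summaries:

* per-gene driver mutation frequencies in tumor tissue, separately for the
  PM and non-PM arms, plus passenger mutations calibrated to the reported
  tissue TMB over the 1.64 Mb panel;
* lavage cfDNA of PM patients carries a configured fraction of the tissue
  variants (plus lavage-private variants), with allele fractions placing
  MaxAF around 40%; non-PM lavages are mostly mutation-free, with a
  configured minority (5/23) carrying tumor variants above the positivity
  cutoff;
* germline SNPs (population frequency > 0.1%, allele fraction ~ 0.5)
  contaminate all three compartments, plus rare germline variants that only
  matched-normal subtraction can remove;
* sequencing depths around 35,000x (lavage) and 1,000x (tissue), with
  supporting reads drawn binomially from (depth, allele fraction);
* chemotherapy-pretreated PM patients can present a mutation-free lavage
  (false negative);
* recurrence follows exponential hazards with a configured hazard ratio
  (7.1) between cfDNA-positive and cfDNA-negative patients;
* tissue coverage profiles over a synthetic capture panel, with a chr20q
  amplification (MSS-A) planted in a configured fraction of non-PM tumors.

Every patient draws from an independent RNG stream keyed by
(seed, arm, patient index), so any subset of the cohort is reproducible
regardless of cohort size; identical seeds give bit-identical output.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np

from . import study
from .errors import ValidationError
from .models import (CaptureRegion, CoverageProfile, PatientTruth,
                     SampleRecord, VariantCall)

_BASES = ("A", "C", "G", "T")

#: approximate hg19 driver hotspot loci used as simulated variant positions
_DRIVER_LOCI = {
    "KRAS": ("chr12", 25_398_284),
    "BRAF": ("chr7", 140_453_136),
    "TP53": ("chr17", 7_577_120),
    "APC": ("chr5", 112_175_000),
    "PIK3CA": ("chr3", 178_936_091),
    "SMAD4": ("chr18", 48_591_918),
}

# position namespaces, disjoint by construction so planted germline loci can
# never collide with somatic loci
_PASSENGER_POS_BASE = 10_000_000
_GERMLINE_POS_BASE = 50_000_000
_RARE_GERMLINE_POS_BASE = 70_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults reproduce the training cohort: 17 PM / 23 non-PM patients,
    tissue driver frequencies as reported per arm, lavage sharing
    calibrated to the 56.0 / 20.3 / 23.7 shared/TIS-only/FLD-only variant
    partition, a 5/23 non-PM positivity rate and a 7.1 recurrence hazard
    ratio.
    """

    n_pm: int = 17
    n_nonpm: int = 23
    cohort: str = "training"
    id_prefix: str = ""
    seed: int = 0

    # tissue mutation structure
    driver_freqs_tis: dict[str, float] = field(
        default_factory=lambda: dict(study.TIS_PM_DRIVER_FREQS))
    driver_freqs_tis_nonpm: dict[str, float] = field(
        default_factory=lambda: dict(study.TIS_NONPM_DRIVER_FREQS))
    driver_freqs_fld_pm: dict[str, float] = field(
        default_factory=lambda: dict(study.FLD_PM_DRIVER_FREQS))
    #: Poisson means for non-driver (passenger) tissue mutations per patient,
    #: calibrated so tissue TMB over 1.64 Mb matches the reported arm means
    passenger_mean_pm: float = 3.5
    passenger_mean_nonpm: float = 8.35
    indel_fraction: float = 0.15
    sv_rate: float = 0.3
    tis_af_mean: float = 0.30

    # lavage structure: drivers (typically truncal) are shared into the
    # lavage more reliably than passengers; 0.92 reproduces the reported
    # driver-level lavage sensitivity and, with the passenger rate below,
    # the 56.0 / 20.3 / 23.7 overall partition
    tis_share_fraction: float = 0.60
    driver_share_fraction: float = 0.92
    fld_private_passenger_mean: float = 1.55
    nonpm_fld_positive_rate: float = 5 / 23
    nonpm_positive_maxaf_mean_pct: float = 18.7
    nonpm_subthreshold_rate: float = 0.3
    pm_maxaf_mean_pct: float = 40.0
    maxaf_beta_concentration: float = 10.0
    positivity_threshold_pct: float = study.POSITIVITY_THRESHOLD_PCT
    chemo_pretreated_rate: float = 0.0
    chemo_false_negative_rate: float = 1.0

    # sequencing model
    fld_depth: int = study.FLD_MEAN_DEPTH
    tis_depth: int = study.TIS_MEAN_DEPTH
    depth_cv: float = 0.10
    germline_snp_rate: float = 30.0
    rare_germline_rate: float = 2.0

    # coverage / CNV model
    n_regions: int = 240
    region_depth_cv: float = 0.015
    mss_a_rate_pm: float = study.MSS_A_RATE_PM
    mss_a_rate_nonpm: float = study.MSS_A_RATE_NONPM
    chr20q_amp_fold: float = 1.5

    # outcome model
    recurrence_hazard_ratio_positive: float = study.RECURRENCE_HR_POSITIVE
    baseline_monthly_hazard_negative: float = 0.0084
    followup_window_months: tuple[float, float] = (9.0, 18.6)
    surgery_start: datetime.date = datetime.date(2021, 1, 4)

    def validate(self) -> None:
        if self.n_pm < 0 or self.n_nonpm < 0:
            raise ValidationError("n_pm/n_nonpm: must be >= 0")
        if self.fld_depth <= 0 or self.tis_depth <= 0:
            raise ValidationError("fld_depth/tis_depth: must be > 0")
        rates = {
            "tis_share_fraction": self.tis_share_fraction,
            "driver_share_fraction": self.driver_share_fraction,
            "nonpm_fld_positive_rate": self.nonpm_fld_positive_rate,
            "nonpm_subthreshold_rate": self.nonpm_subthreshold_rate,
            "indel_fraction": self.indel_fraction,
            "chemo_pretreated_rate": self.chemo_pretreated_rate,
            "chemo_false_negative_rate": self.chemo_false_negative_rate,
            "mss_a_rate_pm": self.mss_a_rate_pm,
            "mss_a_rate_nonpm": self.mss_a_rate_nonpm,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name}: must be in [0, 1], got {value}")
        for name, freqs in (("driver_freqs_tis", self.driver_freqs_tis),
                            ("driver_freqs_tis_nonpm",
                             self.driver_freqs_tis_nonpm),
                            ("driver_freqs_fld_pm", self.driver_freqs_fld_pm)):
            for gene, freq in freqs.items():
                if not 0.0 <= freq <= 1.0:
                    raise ValidationError(
                        f"{name}[{gene}]: must be in [0, 1], got {freq}")
        if self.recurrence_hazard_ratio_positive <= 0:
            raise ValidationError(
                "recurrence_hazard_ratio_positive: must be > 0")
        if not 0 < self.pm_maxaf_mean_pct < 100:
            raise ValidationError("pm_maxaf_mean_pct: must be in (0, 100)")


@dataclass(frozen=True)
class CohortTruth:
    """Planted parameters and per-patient ground truth of one cohort."""

    seed: int
    patients: dict[str, PatientTruth]
    panel_region_ids: tuple[str, ...]
    chr20q_region_ids: tuple[str, ...]


@dataclass(frozen=True)
class SimulatedCohort:
    variants: list[VariantCall]
    coverage: list[CoverageProfile]
    clinical: list[SampleRecord]
    truth: CohortTruth


def _patient_rng(seed: int, arm_code: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(arm_code, index)))


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def _draw_depth(rng: np.random.Generator, mean: int, cv: float) -> int:
    return max(100, int(round(rng.normal(mean, cv * mean))))


def _random_substitution(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _random_indel(rng: np.random.Generator) -> tuple[str, str]:
    anchor = _BASES[rng.integers(4)]
    inserted = "".join(_BASES[rng.integers(4)]
                       for _ in range(int(rng.integers(1, 4))))
    if rng.random() < 0.5:
        return anchor, anchor + inserted  # insertion
    return anchor + inserted, anchor  # deletion


@dataclass
class _PlannedVariant:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    tis_af: float
    in_fld: bool = False
    fld_af: float = 0.0
    in_tis: bool = True


def _emit(planned: _PlannedVariant, patient_id: str, origin: str, af: float,
          depth: int, rng: np.random.Generator,
          population_frequency: float = 0.0,
          is_driver: bool = False) -> VariantCall:
    support = int(rng.binomial(depth, min(af, 1.0)))
    observed_af = support / depth if depth else 0.0
    return VariantCall(
        sample_id=patient_id, origin=origin, gene=planned.gene,
        chrom=planned.chrom, pos=planned.pos, ref=planned.ref,
        alt=planned.alt, variant_class=planned.variant_class,
        allele_fraction=observed_af, depth=depth, supporting_reads=support,
        population_frequency=population_frequency, is_driver=is_driver)


# ---------------------------------------------------------------------------
# capture panel / coverage model
# ---------------------------------------------------------------------------

def make_panel_regions(n_regions: int = 240, seed: int = 0,
                       ) -> tuple[CaptureRegion, ...]:
    """Deterministic synthetic capture panel: ~10% of regions on chr20q, the
    rest cycling over the other autosomes; GC fractions in [0.3, 0.7];
    depth field left at 0 (filled per sample)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    autosomes = [f"chr{i}" for i in range(1, 23) if i != 20]
    regions = []
    for i in range(n_regions):
        if i % 10 == 9:
            chrom = "chr20"
            start = 30_000_000 + i * 5_000  # q arm
        else:
            chrom = autosomes[i % len(autosomes)]
            start = 1_000_000 + i * 5_000
        regions.append(CaptureRegion(
            region_id=f"R{i:04d}", chrom=chrom, start=start, end=start + 300,
            gc_fraction=float(np.round(rng.uniform(0.30, 0.70), 4)), depth=0.0))
    return tuple(regions)


def _panel_expected_factors(regions: tuple[CaptureRegion, ...], seed: int,
                            gc_slope: float = 0.6) -> np.ndarray:
    """Per-region expected depth multiplier: a static probe effect times a
    linear GC bias, normalized to mean 1 so the grand mean depth is the
    configured mean."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(11,)))
    probe_effect = rng.lognormal(mean=0.0, sigma=0.3, size=len(regions))
    gc = np.asarray([r.gc_fraction for r in regions])
    factors = probe_effect * (1.0 + gc_slope * (gc - 0.5))
    return factors / factors.mean()


def _sample_coverage(regions: tuple[CaptureRegion, ...],
                     factors: np.ndarray, sample_id: str, mean_depth: float,
                     cv: float, rng: np.random.Generator) -> CoverageProfile:
    shape = 1.0 / cv ** 2
    noise = rng.gamma(shape, 1.0 / shape, size=len(regions))
    scale = rng.gamma(100.0, 1.0 / 100.0)  # per-sample library size, mean 1
    depths = mean_depth * scale * factors * noise
    filled = tuple(replace(r, depth=float(d))
                   for r, d in zip(regions, depths))
    return CoverageProfile(sample_id=sample_id, regions=filled)


def generate_coverage_panel(n_samples: int, n_regions: int = 240,
                            seed: int = 0, mean_depth: float = 1000.0,
                            depth_cv: float = 0.015,
                            ) -> list[CoverageProfile]:
    """CNV-free coverage profiles (a reference panel) over the synthetic
    capture panel; deterministic per seed."""
    if n_samples < 1:
        raise ValidationError("n_samples: must be >= 1")
    regions = make_panel_regions(n_regions, seed)
    factors = _panel_expected_factors(regions, seed)
    profiles = []
    for s in range(n_samples):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(8, s)))
        profiles.append(_sample_coverage(regions, factors, f"REF{s:03d}",
                                         mean_depth, depth_cv, rng))
    return profiles


def plant_cnv(profile: CoverageProfile, region_ids: list[str] | tuple[str, ...],
              fold_change: float) -> CoverageProfile:
    """Multiply the depths of the selected regions by ``fold_change``
    (e.g. 1.5 for a single-copy gain on a diploid background)."""
    if fold_change <= 0:
        raise ValidationError(f"fold_change: must be > 0, got {fold_change}")
    wanted = set(region_ids)
    known = set(profile.region_ids)
    unknown = sorted(wanted - known)
    if unknown:
        raise ValidationError(f"region_ids: unknown region(s) {unknown[:5]}")
    regions = tuple(
        replace(r, depth=r.depth * fold_change) if r.region_id in wanted else r
        for r in profile.regions)
    return CoverageProfile(sample_id=profile.sample_id, regions=regions)


# ---------------------------------------------------------------------------
# per-patient simulation
# ---------------------------------------------------------------------------

def _plan_tissue_variants(config: SimulationConfig, arm: str,
                          rng: np.random.Generator) -> list[_PlannedVariant]:
    driver_freqs = (config.driver_freqs_tis if arm == "PM"
                    else config.driver_freqs_tis_nonpm)
    tis_a, tis_b = _beta_params(config.tis_af_mean, 8.0)
    planned: list[_PlannedVariant] = []

    def _af() -> float:
        return float(np.clip(rng.beta(tis_a, tis_b), 0.02, 0.95))

    def _alleles(variant_class: str) -> tuple[str, str]:
        return (_random_indel(rng) if variant_class == "Indel"
                else _random_substitution(rng))

    def _class() -> str:
        return "Indel" if rng.random() < config.indel_fraction else "SNV"

    for gene in sorted(driver_freqs):
        if rng.random() >= driver_freqs[gene]:
            continue
        chrom, base = _DRIVER_LOCI.get(gene, ("chr1", 1_000_000))
        vclass = _class()
        ref, alt = _alleles(vclass)
        planned.append(_PlannedVariant(
            gene=gene, chrom=chrom, pos=int(base + rng.integers(0, 2_000)),
            ref=ref, alt=alt, variant_class=vclass, tis_af=_af()))
    passenger_mean = (config.passenger_mean_pm if arm == "PM"
                      else config.passenger_mean_nonpm)
    n_passengers = int(rng.poisson(passenger_mean))
    gene_indices = rng.choice(400, size=min(n_passengers, 400), replace=False)
    for g in gene_indices:
        vclass = _class()
        ref, alt = _alleles(vclass)
        planned.append(_PlannedVariant(
            gene=f"GENE{g + 1:03d}", chrom=f"chr{(int(g) % 22) + 1}",
            pos=int(_PASSENGER_POS_BASE + int(g) * 10_000
                    + rng.integers(0, 10_000)),
            ref=ref, alt=alt, variant_class=vclass, tis_af=_af()))
    # structural events (fusion / CNV / LGR rows) are tumor variants too:
    # they pass the filter cascade and can be shared into the lavage, but
    # are excluded from MaxAF
    for _ in range(int(rng.poisson(config.sv_rate))):
        g = int(rng.integers(1, 401))
        planned.append(_PlannedVariant(
            gene=f"GENE{g:03d}", chrom=f"chr{(g % 22) + 1}",
            pos=int(_PASSENGER_POS_BASE + 5_000_000 + rng.integers(0,
                                                                   4_000_000)),
            ref=".", alt=".",
            variant_class=("Fusion", "CNV", "LGR")[int(rng.integers(3))],
            tis_af=_af()))
    return planned


def _eligible_indices(variants: list[_PlannedVariant]) -> list[int]:
    return [i for i, v in enumerate(variants)
            if v.variant_class in ("SNV", "Indel")]


def _assign_fld_afs(shared: list[_PlannedVariant], max_target: float,
                    rng: np.random.Generator) -> None:
    """Give every lavage variant an allele fraction below the patient's
    target MaxAF, and pin one designated clonal SNV/Indel at the target so
    the sample MaxAF equals it (up to binomial sampling at ~35,000x);
    structural variants never carry the maximum because MaxAF excludes
    them."""
    if not shared:
        return
    eligible = _eligible_indices(shared)
    clonal = int(rng.choice(eligible)) if eligible else -1
    for i, variant in enumerate(shared):
        if i == clonal:
            variant.fld_af = max_target
        else:
            variant.fld_af = float(
                np.clip(max_target * rng.beta(2.0, 1.2), 1e-3, max_target))
        variant.in_fld = True


def _plan_fld_pm(config: SimulationConfig, planned: list[_PlannedVariant],
                 rng: np.random.Generator) -> list[_PlannedVariant]:
    """Share tissue variants into the lavage, add lavage-private variants,
    and guarantee at least one shared variant (PM lavages are positive)."""
    def _share_prob(variant: _PlannedVariant) -> float:
        if variant.gene in config.driver_freqs_fld_pm:
            return config.driver_share_fraction
        return config.tis_share_fraction

    shared = [v for v in planned if rng.random() < _share_prob(v)]
    present_drivers = {v.gene: v for v in planned
                       if v.gene in config.driver_freqs_fld_pm}
    extras: list[_PlannedVariant] = []
    # lavage-private driver mutations top the marginal lavage frequency up to
    # its configured target when sharing alone cannot reach it
    for gene in sorted(config.driver_freqs_fld_pm):
        p_fld = config.driver_freqs_fld_pm[gene]
        p_tis = config.driver_freqs_tis.get(gene, 0.0)
        reach = p_tis * config.driver_share_fraction
        residual = max(0.0, (p_fld - reach) / (1.0 - reach)) if reach < 1 else 0.0
        already = (gene in present_drivers
                   and present_drivers[gene] in shared)
        if not already and rng.random() < residual:
            chrom, base = _DRIVER_LOCI.get(gene, ("chr1", 1_000_000))
            vclass = "Indel" if rng.random() < config.indel_fraction else "SNV"
            ref, alt = (_random_indel(rng) if vclass == "Indel"
                        else _random_substitution(rng))
            extras.append(_PlannedVariant(
                gene=gene, chrom=chrom,
                pos=int(base + 2_000 + rng.integers(0, 2_000)),
                ref=ref, alt=alt, variant_class=vclass, tis_af=0.0,
                in_tis=False))
    n_private = int(rng.poisson(config.fld_private_passenger_mean))
    for _ in range(n_private):
        g = int(rng.integers(400, 600))
        vclass = "Indel" if rng.random() < config.indel_fraction else "SNV"
        ref, alt = (_random_indel(rng) if vclass == "Indel"
                    else _random_substitution(rng))
        extras.append(_PlannedVariant(
            gene=f"GENE{g + 1:03d}", chrom=f"chr{(g % 22) + 1}",
            pos=int(_PASSENGER_POS_BASE + g * 10_000 + rng.integers(0, 10_000)),
            ref=ref, alt=alt, variant_class=vclass, tis_af=0.0,
            in_tis=False))
    # a PM lavage must carry at least one MaxAF-eligible (SNV/Indel) variant
    if not _eligible_indices(shared):
        candidates = _eligible_indices(planned)
        if candidates:
            shared.append(planned[int(rng.choice(candidates))])
    return shared + extras


def _simulate_patient(config: SimulationConfig, arm: str, index: int,
                      regions: tuple[CaptureRegion, ...],
                      factors: np.ndarray,
                      ) -> tuple[list[VariantCall], CoverageProfile,
                                 SampleRecord, PatientTruth]:
    arm_code = 0 if arm == "PM" else 1
    rng = _patient_rng(config.seed, arm_code, index)
    patient_id = (f"{config.id_prefix}{'PM' if arm == 'PM' else 'NP'}"
                  f"{index + 1:03d}")
    threshold_af = config.positivity_threshold_pct / 100.0

    planned = _plan_tissue_variants(config, arm, rng)

    chemo_pretreated = rng.random() < config.chemo_pretreated_rate
    chemo_suppressed = (arm == "PM" and chemo_pretreated
                        and rng.random() < config.chemo_false_negative_rate)

    maxaf_target = 0.0
    fld_plan: list[_PlannedVariant] = []
    if arm == "PM" and not chemo_suppressed:
        mean = config.pm_maxaf_mean_pct / 100.0
        a, b = _beta_params(mean, config.maxaf_beta_concentration)
        maxaf_target = float(np.clip(rng.beta(a, b),
                                     threshold_af + 0.01, 0.98))
        fld_plan = _plan_fld_pm(config, planned, rng)
        _assign_fld_afs(fld_plan, maxaf_target, rng)
    elif arm == "nonPM":
        if rng.random() < config.nonpm_fld_positive_rate:
            mean = config.nonpm_positive_maxaf_mean_pct / 100.0
            a, b = _beta_params(mean, 8.0)
            maxaf_target = float(np.clip(rng.beta(a, b),
                                         threshold_af + 0.01, 0.9))
            shared = [v for v in planned
                      if rng.random() < config.tis_share_fraction]
            if not _eligible_indices(shared):
                candidates = _eligible_indices(planned)
                if candidates:
                    shared.append(planned[int(rng.choice(candidates))])
            _assign_fld_afs(shared, maxaf_target, rng)
            fld_plan = shared
        elif rng.random() < config.nonpm_subthreshold_rate:
            # a trace of tumor DNA below the cutoff: negative but nonzero
            candidates = _eligible_indices(planned)
            if candidates:
                maxaf_target = float(rng.uniform(0.001, 0.9 * threshold_af))
                low = planned[int(rng.choice(candidates))]
                low.in_fld = True
                low.fld_af = maxaf_target
                fld_plan = [low]

    planted_positive = maxaf_target > threshold_af

    variants: list[VariantCall] = []
    drivers = set(study.DRIVER_GENES)

    # germline SNPs (common, population frequency > 0.1%) in all compartments
    germline_keys, rare_germline_keys = set(), set()
    wbc_depth = _draw_depth(rng, config.tis_depth, config.depth_cv)
    tis_depth = _draw_depth(rng, config.tis_depth, config.depth_cv)
    fld_depth = _draw_depth(rng, config.fld_depth, config.depth_cv)
    for rare in (False, True):
        count = int(rng.poisson(config.rare_germline_rate if rare
                                else config.germline_snp_rate))
        base = _RARE_GERMLINE_POS_BASE if rare else _GERMLINE_POS_BASE
        for _ in range(count):
            ref, alt = _random_substitution(rng)
            planned_g = _PlannedVariant(
                gene=f"GENE{int(rng.integers(1, 401)):03d}",
                chrom=f"chr{int(rng.integers(1, 23))}",
                pos=int(base + rng.integers(0, 10_000_000)),
                ref=ref, alt=alt, variant_class="SNV", tis_af=0.0)
            af = float(np.clip(rng.normal(0.5, 0.03), 0.35, 0.65))
            popfreq = 0.0 if rare else float(10 ** rng.uniform(-2.7, -0.3))
            key = (planned_g.chrom, planned_g.pos, planned_g.ref, planned_g.alt)
            (rare_germline_keys if rare else germline_keys).add(key)
            for origin, depth in (("WBC", wbc_depth), ("TIS", tis_depth),
                                  ("FLD", fld_depth)):
                variants.append(_emit(planned_g, patient_id, origin, af,
                                      depth, rng,
                                      population_frequency=popfreq))

    # somatic variants: tissue, then lavage
    tis_keys, fld_keys, shared_keys = set(), set(), set()
    for v in planned:
        if not v.in_tis:
            continue
        tis_keys.add((v.chrom, v.pos, v.ref, v.alt))
        variants.append(_emit(v, patient_id, "TIS", v.tis_af, tis_depth, rng,
                              is_driver=v.gene in drivers))
    for v in fld_plan:
        key = (v.chrom, v.pos, v.ref, v.alt)
        fld_keys.add(key)
        if v.in_tis:
            shared_keys.add(key)
        variants.append(_emit(v, patient_id, "FLD", v.fld_af, fld_depth, rng,
                              is_driver=v.gene in drivers))

    # tissue coverage profile, with a chr20q amplification in MSS-A tumors
    mss_a_rate = (config.mss_a_rate_pm if arm == "PM"
                  else config.mss_a_rate_nonpm)
    profile = _sample_coverage(regions, factors, patient_id,
                               float(config.tis_depth),
                               config.region_depth_cv, rng)
    mss_a = rng.random() < mss_a_rate
    chr20q_ids = tuple(r.region_id for r in regions if r.chrom == "chr20")
    amplified: tuple[str, ...] = ()
    if mss_a and chr20q_ids:
        profile = plant_cnv(profile, chr20q_ids, config.chr20q_amp_fold)
        amplified = chr20q_ids

    # clinical record with exponential recurrence hazards
    surgery_date = config.surgery_start + datetime.timedelta(
        days=int(arm_code * 1000 + index) % 365)
    hazard = config.baseline_monthly_hazard_negative * (
        config.recurrence_hazard_ratio_positive if planted_positive else 1.0)
    event_months = float(rng.exponential(1.0 / hazard)) if hazard > 0 else float("inf")
    censor_months = float(rng.uniform(*config.followup_window_months))
    recurrence = event_months <= censor_months
    followup_months = event_months if recurrence else censor_months
    followup_date = surgery_date + datetime.timedelta(
        days=max(1, round(followup_months * 30.44)))
    record = SampleRecord(
        sample_id=patient_id, arm=arm, cohort=config.cohort,
        pci_score=int(rng.integers(9, 23)) if arm == "PM" else 0,
        chemo_pretreated=chemo_pretreated,
        surgery_date=surgery_date,
        recurrence=recurrence,
        recurrence_date=followup_date if recurrence else None,
        last_followup_date=followup_date,
    )
    truth = PatientTruth(
        patient_id=patient_id, arm=arm, cohort=config.cohort,
        cfdna_positive=planted_positive, chemo_suppressed=chemo_suppressed,
        maxaf_target_pct=100.0 * maxaf_target,
        germline_keys=frozenset(germline_keys),
        rare_germline_keys=frozenset(rare_germline_keys),
        tis_somatic_keys=frozenset(tis_keys),
        fld_somatic_keys=frozenset(fld_keys),
        shared_keys=frozenset(shared_keys),
        mss_a=mss_a, amplified_region_ids=amplified,
    )
    return variants, profile, record, truth


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate one cohort of matched FLD/TIS/WBC variant tables, tissue
    coverage profiles and clinical outcomes, with the planted truth."""
    config.validate()
    regions = make_panel_regions(config.n_regions, config.seed)
    factors = _panel_expected_factors(regions, config.seed)
    variants: list[VariantCall] = []
    coverage: list[CoverageProfile] = []
    clinical: list[SampleRecord] = []
    patients: dict[str, PatientTruth] = {}
    for arm, count in (("PM", config.n_pm), ("nonPM", config.n_nonpm)):
        for index in range(count):
            v, profile, record, truth = _simulate_patient(
                config, arm, index, regions, factors)
            variants.extend(v)
            coverage.append(profile)
            clinical.append(record)
            patients[truth.patient_id] = truth
    chr20q_ids = tuple(r.region_id for r in regions if r.chrom == "chr20")
    return SimulatedCohort(
        variants=variants, coverage=coverage, clinical=clinical,
        truth=CohortTruth(seed=config.seed, patients=patients,
                          panel_region_ids=tuple(r.region_id for r in regions),
                          chr20q_region_ids=chr20q_ids))
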