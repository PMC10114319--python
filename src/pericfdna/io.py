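"""Readers and writers for the package's plain-text table formats.

Three tabular formats are used:

* variant tables — TSV, one row per called variant (or a minimal VCF 4.2
  subset mapped onto the same model),
* coverage tables — TSV, one row per capture region per sample,
* clinical tables — CSV, one row per patient, dates ISO-8601.

Every reader validates each row against the domain invariants and raises
:class:`SchemaError` (missing columns) or :class:`ValidationError`
(naming row and field) — never silent coercion. Writers use a
deterministic column order so write-then-read is the identity.
"""

from __future__ import annotations

import csv
import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError
from .models import CaptureRegion, CoverageProfile, SampleRecord, VariantCall
from .study import DRIVER_GENES

VARIANT_COLUMNS = [
    "sample_id", "origin", "gene", "chrom", "pos", "ref", "alt",
    "variant_class", "allele_fraction", "depth", "supporting_reads",
    "population_frequency",
]
COVERAGE_COLUMNS = [
    "sample_id", "region_id", "chrom", "start", "end", "gc_fraction", "depth",
]
CLINICAL_COLUMNS = [
    "sample_id", "arm", "cohort", "pci_score", "chemo_pretreated",
    "surgery_date", "recurrence", "recurrence_date", "last_followup_date",
    "cfdna_positive",
]


def _check_columns(present: Sequence[str], required: Sequence[str],
                   path: Path) -> None:
    missing = [c for c in required if c not in present]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path, dialect: str = "tsv",
                       driver_genes: Sequence[str] = DRIVER_GENES,
                       **vcf_kwargs) -> list[VariantCall]:
    """Read a variant table into validated :class:`VariantCall` records.

    ``dialect="tsv"`` expects the package's 12-column TSV;
    ``dialect="vcf_min"`` accepts a minimal uncompressed VCF 4.2 subset
    (see :func:`read_variant_vcf`). ``is_driver`` is derived from
    ``driver_genes`` on read, not stored in the file.
    """
    if dialect == "tsv":
        return _read_variant_tsv(Path(path), driver_genes)
    if dialect == "vcf_min":
        return read_variant_vcf(path, driver_genes=driver_genes, **vcf_kwargs)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variant_tsv(path: Path,
                      driver_genes: Sequence[str]) -> list[VariantCall]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(frame.columns, VARIANT_COLUMNS, path)
    drivers = set(driver_genes)
    variants: list[VariantCall] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            variants.append(VariantCall(
                sample_id=row.sample_id,
                origin=row.origin,
                gene=row.gene,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                variant_class=row.variant_class,
                allele_fraction=float(row.allele_fraction),
                depth=int(row.depth),
                supporting_reads=int(row.supporting_reads),
                population_frequency=float(row.population_frequency),
                is_driver=row.gene in drivers,
            ))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return variants


def write_variant_table(variants: Iterable[VariantCall],
                        path: str | Path) -> Path:
    """Write variants as TSV in the canonical column order (header always
    present, so an empty list round-trips to an empty list)."""
    path = Path(path)
    rows = [{c: getattr(v, c) for c in VARIANT_COLUMNS} for v in variants]
    frame = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_variant_vcf(path: str | Path,
                     driver_genes: Sequence[str] = DRIVER_GENES,
                     default_origin: str = "FLD") -> list[VariantCall]:
    """Minimal VCF 4.2 subset reader.

    Per record and per alternate allele (multi-allelic rows are split), the
    allele fraction comes from a per-sample ``AF`` FORMAT field when present,
    else is computed as AD_alt/DP. ``GENE``, ``ORIGIN``, ``CLASS`` and
    ``POPFREQ`` INFO keys map onto the model; an absent population frequency
    is treated as 0 (only variants known to be common are germline-filtered),
    and the class defaults to SNV/Indel by allele length.
    """
    from cyvcf2 import VCF  # deferred: only needed for this dialect

    vcf = VCF(str(path))
    samples = vcf.samples or ["sample"]
    drivers = set(driver_genes)
    variants: list[VariantCall] = []

    def _format(record, key):
        try:
            return record.format(key)
        except KeyError:
            return None

    for record in vcf:
        info = dict(record.INFO)
        gene = str(info.get("GENE", "."))
        origin = str(info.get("ORIGIN", default_origin))
        popfreq = float(info.get("POPFREQ", 0.0))
        af_field = _format(record, "AF")
        ad_field = _format(record, "AD")
        dp_field = _format(record, "DP")
        for alt_index, alt in enumerate(record.ALT):
            vclass = info.get(
                "CLASS",
                "SNV" if len(record.REF) == 1 and len(alt) == 1 else "Indel")
            for s_index, sample in enumerate(samples):
                if dp_field is not None:
                    depth = int(dp_field[s_index][0])
                else:
                    depth = int(info.get("DP", 0))
                if ad_field is not None:
                    support = int(ad_field[s_index][alt_index + 1])
                else:
                    support = 0
                if af_field is not None:
                    af = float(af_field[s_index][alt_index])
                elif depth > 0:
                    af = support / depth
                else:
                    af = 0.0
                if ad_field is None and depth > 0:
                    support = round(af * depth)
                variants.append(VariantCall(
                    sample_id=sample,
                    origin=origin,
                    gene=gene,
                    chrom=str(record.CHROM),
                    pos=int(record.POS),
                    ref=str(record.REF),
                    alt=str(alt),
                    variant_class=str(vclass),
                    allele_fraction=af,
                    depth=depth,
                    supporting_reads=min(support, depth),
                    population_frequency=popfreq,
                    is_driver=gene in drivers,
                ))
    return variants


# ---------------------------------------------------------------------------
# coverage tables
# ---------------------------------------------------------------------------

def read_coverage_table(path: str | Path) -> list[CoverageProfile]:
    """Read a coverage TSV into one :class:`CoverageProfile` per sample
    (sample order and region order as on disk)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(frame.columns, COVERAGE_COLUMNS, path)
    profiles: list[CoverageProfile] = []
    for sample_id, group in frame.groupby("sample_id", sort=False):
        regions = []
        for i, row in enumerate(group.itertuples(index=False), start=2):
            try:
                regions.append(CaptureRegion(
                    region_id=row.region_id,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    gc_fraction=float(row.gc_fraction),
                    depth=float(row.depth),
                ))
            except (ValidationError, ValueError) as exc:
                raise ValidationError(
                    f"{path} sample {sample_id} row {i}: {exc}") from exc
        profiles.append(CoverageProfile(sample_id=str(sample_id),
                                        regions=tuple(regions)))
    return profiles


def write_coverage_table(profiles: Iterable[CoverageProfile],
                         path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for profile in profiles:
        for region in profile.regions:
            rows.append({
                "sample_id": profile.sample_id,
                "region_id": region.region_id,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "gc_fraction": region.gc_fraction,
                "depth": region.depth,
            })
    pd.DataFrame(rows, columns=COVERAGE_COLUMNS).to_csv(
        path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def _parse_bool(value: str, field: str) -> bool:
    if value in ("true", "True", "TRUE", "1"):
        return True
    if value in ("false", "False", "FALSE", "0"):
        return False
    raise ValidationError(f"{field}: cannot parse boolean from {value!r}")


def _parse_date(value: str, field: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(value)
    except ValueError as exc:
        raise ValidationError(f"{field}: {exc}") from exc


def read_clinical_table(path: str | Path) -> list[SampleRecord]:
    path = Path(path)
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        _check_columns(reader.fieldnames or [], CLINICAL_COLUMNS, path)
        records: list[SampleRecord] = []
        for i, row in enumerate(reader, start=2):
            try:
                records.append(SampleRecord(
                    sample_id=row["sample_id"],
                    arm=row["arm"],
                    cohort=row["cohort"],
                    pci_score=int(row["pci_score"]),
                    chemo_pretreated=_parse_bool(row["chemo_pretreated"],
                                                 "chemo_pretreated"),
                    surgery_date=_parse_date(row["surgery_date"],
                                             "surgery_date"),
                    recurrence=_parse_bool(row["recurrence"], "recurrence"),
                    recurrence_date=(
                        _parse_date(row["recurrence_date"], "recurrence_date")
                        if row["recurrence_date"] else None),
                    last_followup_date=_parse_date(row["last_followup_date"],
                                                   "last_followup_date"),
                    cfdna_positive=(
                        _parse_bool(row["cfdna_positive"], "cfdna_positive")
                        if row["cfdna_positive"] else None),
                ))
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path} line {i}: {exc}") from exc
    return records


def write_clinical_table(records: Iterable[SampleRecord],
                         path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(CLINICAL_COLUMNS)
        for r in records:
            writer.writerow([
                r.sample_id, r.arm, r.cohort, r.pci_score,
                "true" if r.chemo_pretreated else "false",
                r.surgery_date.isoformat(),
                "true" if r.recurrence else "false",
                r.recurrence_date.isoformat() if r.recurrence_date else "",
                r.last_followup_date.isoformat(),
                "" if r.cfdna_positive is None
                else ("true" if r.cfdna_positive else "false"),
            ])
    return path


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set file: one set per line,
    ``id <tab> description <tab> gene1 <tab> gene2 ...``."""
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(
                    f"{path} line {line_no}: expected id, description and "
                    "at least one gene")
            pathways[parts[0]] = frozenset(g for g in parts[2:] if g)
    return pathways
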