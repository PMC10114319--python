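"""End-to-end orchestration: simulate -> filter -> CNV -> MaxAF/diagnose ->
concordance -> outcomes, producing a single reproducible report bundle.

The positivity cutoff is either fixed or fitted on the training cohort only
(ROC + Youden's J) and applied unchanged to the validation cohort, so no
information leaks from validation into threshold selection. The bundle is a
pure function of (config, seed): identical inputs give byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__, study
from .cnv import build_reference, call_sample, classify_chr20q
from .concordance import (cohens_kappa_unweighted, concordance_summary,
                          match_variants, per_gene_concordance)
from .diagnostics import (build_contingency, compute_maxaf,
                          diagnostic_metrics, fisher_exact_two_sided,
                          roc_curve)
from .errors import PipelineError, UndefinedStatisticError, ValidationError
from .filters import FilterParams, run_filter_cascade
from .models import VariantCall
from .outcomes import compute_rfs, km_estimate, logrank_test, recurrence_summary
from .simulate import SimulationConfig, generate_cohort, generate_coverage_panel

logger = logging.getLogger("pericfdna.pipeline")

#: sentinel for "estimate the cutoff on the training cohort"
FIT_FROM_TRAINING = "fit-from-training"


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one end-to-end run over synthetic cohorts."""

    seed: int = 0
    threshold_pct: float | str = FIT_FROM_TRAINING
    training: SimulationConfig | None = None
    validation: SimulationConfig | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    deletion_limit: float = 1.75
    amplification_limit: float = 2.75
    driver_genes: tuple[str, ...] = study.DRIVER_GENES
    n_reference_panel: int = 60

    def resolved_training(self) -> SimulationConfig:
        if self.training is not None:
            return self.training
        return SimulationConfig(seed=self.seed, cohort="training",
                                id_prefix="T")

    def resolved_validation(self) -> SimulationConfig | None:
        if self.validation is not None:
            return self.validation
        return SimulationConfig(
            n_pm=6, n_nonpm=5, cohort="validation", id_prefix="V",
            seed=self.seed + 1_000_003, chemo_pretreated_rate=1 / 6,
            nonpm_fld_positive_rate=0.0)

    def to_dict(self) -> dict[str, Any]:
        def _convert(value):
            if dataclasses.is_dataclass(value) and not isinstance(value, type):
                return {k: _convert(v)
                        for k, v in dataclasses.asdict(value).items()}
            if isinstance(value, (list, tuple)):
                return [_convert(v) for v in value]
            if hasattr(value, "isoformat"):
                return value.isoformat()
            return value
        return {f.name: _convert(getattr(self, f.name))
                for f in dataclasses.fields(self)}


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            start = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except (ValidationError, UndefinedStatisticError) as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name,
                        time.perf_counter() - start)
            return result
        return wrapper
    return decorator


def _group_by_patient(variants: list[VariantCall],
                      ) -> dict[str, dict[str, list[VariantCall]]]:
    grouped: dict[str, dict[str, list[VariantCall]]] = {}
    for v in variants:
        grouped.setdefault(v.sample_id, {"FLD": [], "TIS": [], "WBC": []})[
            v.origin].append(v)
    return grouped


@_stage("filter")
def _filter_cohort(cohort, params: FilterParams):
    """Filter each patient's FLD and TIS against the matched WBC calls."""
    grouped = _group_by_patient(cohort.variants)
    filtered: dict[str, dict[str, list[VariantCall]]] = {}
    reports: dict[str, dict[str, Any]] = {}
    for patient_id in sorted(grouped):
        compartments = grouped[patient_id]
        wbc = compartments["WBC"]
        fld, fld_report = run_filter_cascade(compartments["FLD"], wbc,
                                             "fluid", params)
        tis, tis_report = run_filter_cascade(compartments["TIS"], wbc,
                                             "tissue", params)
        filtered[patient_id] = {"FLD": fld, "TIS": tis}
        reports[patient_id] = {"FLD": dataclasses.asdict(fld_report),
                               "TIS": dataclasses.asdict(tis_report)}
    return filtered, reports


@_stage("diagnose")
def _diagnose_cohort(cohort, filtered, threshold_pct: float):
    maxaf = {pid: compute_maxaf(filtered[pid]["FLD"], sample_id=pid,
                                threshold_pct=threshold_pct)
             for pid in sorted(filtered)}
    predictions = {pid: r.positive for pid, r in maxaf.items()}
    truth = {r.sample_id: r.arm == "PM" for r in cohort.clinical}
    table = build_contingency(predictions, truth)
    metrics = diagnostic_metrics(table)
    return maxaf, {
        "contingency": dataclasses.asdict(table),
        "metrics": metrics,
        "fisher_p": fisher_exact_two_sided(table),
        "maxaf_pct": {pid: r.maxaf_pct for pid, r in maxaf.items()},
        "positive": predictions,
    }


@_stage("cnv")
def _cnv_cohort(cohort, config: PipelineConfig, sim: SimulationConfig):
    panel = generate_coverage_panel(
        config.n_reference_panel, n_regions=sim.n_regions, seed=sim.seed,
        mean_depth=float(sim.tis_depth), depth_cv=sim.region_depth_cv)
    reference = build_reference(panel, min_panel=50)
    chr20q_ids = cohort.truth.chr20q_region_ids
    arms = {r.sample_id: r.arm for r in cohort.clinical}
    per_sample = {}
    mss_counts = {"PM": {"MSS-A": 0, "MSS-N": 0},
                  "nonPM": {"MSS-A": 0, "MSS-N": 0}}
    for profile in cohort.coverage:
        calls = call_sample(profile, reference,
                            deletion_limit=config.deletion_limit,
                            amplification_limit=config.amplification_limit)
        label = classify_chr20q(calls, chr20q_ids)
        per_sample[profile.sample_id] = {
            "chr20q": label,
            "n_amplified": sum(1 for c in calls if c.state == "amplification"),
            "n_deleted": sum(1 for c in calls if c.state == "deletion"),
        }
        mss_counts[arms[profile.sample_id]][label] += 1
    return {"per_sample": per_sample, "mss_counts": mss_counts}


@_stage("concordance")
def _concordance_cohort(cohort, filtered, driver_genes):
    pm_ids = sorted(r.sample_id for r in cohort.clinical if r.arm == "PM")
    all_ids = sorted(filtered)
    pm_partitions = [match_variants(filtered[pid]["FLD"], filtered[pid]["TIS"])
                     for pid in pm_ids]
    out: dict[str, Any] = {}
    try:
        summary = concordance_summary(pm_partitions)
        out["all_variants"] = dataclasses.asdict(summary)
        out["driver_variants"] = dataclasses.asdict(
            concordance_summary(pm_partitions, driver_only=True,
                                driver_genes=driver_genes))
    except ValidationError:
        out["all_variants"] = None
        out["driver_variants"] = None
    partitions_all = [match_variants(filtered[pid]["FLD"],
                                     filtered[pid]["TIS"])
                      for pid in all_ids]
    out["per_gene"] = {
        gene: dict(zip(("n_shared_patients", "n_discordant_patients"),
                       per_gene_concordance(partitions_all, gene)))
        for gene in driver_genes}
    # patient x gene mutation status per compartment
    calls_fld, calls_tis = [], []
    for pid in all_ids:
        fld_genes = {v.gene for v in filtered[pid]["FLD"]}
        tis_genes = {v.gene for v in filtered[pid]["TIS"]}
        for gene in driver_genes:
            calls_fld.append(gene in fld_genes)
            calls_tis.append(gene in tis_genes)
    try:
        out["kappa_patient_gene"] = cohens_kappa_unweighted(calls_fld,
                                                            calls_tis)
    except (ValidationError, UndefinedStatisticError):
        out["kappa_patient_gene"] = None
    return out


@_stage("outcomes")
def _outcomes_cohort(cohort, maxaf):
    nonpm = [r for r in cohort.clinical if r.arm == "nonPM"]
    if not nonpm:
        return None
    rfs = {r.sample_id: compute_rfs(r) for r in nonpm}
    groups: dict[str, Any] = {}
    split = {}
    for label, positive in (("positive", True), ("negative", False)):
        members = [r for r in nonpm if maxaf[r.sample_id].positive is positive]
        times = [rfs[r.sample_id][0] for r in members]
        events = [rfs[r.sample_id][1] for r in members]
        split[label] = (times, events)
        if members:
            curve = km_estimate(times, events)
            groups[label] = {
                "n": len(members),
                "event_times": list(curve.event_times),
                "survival": list(curve.survival),
            }
        else:
            groups[label] = {"n": 0, "event_times": [], "survival": []}
    logrank: dict[str, float] | None
    try:
        chi_square, p = logrank_test(split["positive"], split["negative"])
        logrank = {"chi_square": chi_square, "p": p}
    except (ValidationError, UndefinedStatisticError):
        logrank = None
    summary = recurrence_summary(nonpm, maxaf)
    return {
        "km": groups,
        "logrank": logrank,
        "recurrence": {label: dataclasses.asdict(g)
                       for label, g in summary.items()},
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage over the simulated training (and optional validation)
    cohort and return the JSON-serializable report bundle."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(levelname)s %(message)s")
    train_sim = config.resolved_training()
    training = generate_cohort(train_sim)
    filtered_train, reports_train = _filter_cohort(training,
                                                   config.filter_params)

    # cutoff: fitted on training only, or fixed
    if config.threshold_pct == FIT_FROM_TRAINING:
        arm_of = {r.sample_id: r.arm for r in training.clinical}
        scores = [(compute_maxaf(filtered_train[pid]["FLD"],
                                 sample_id=pid).maxaf_pct,
                   arm_of[pid] == "PM")
                  for pid in sorted(filtered_train)]
        curve = roc_curve(scores)
        threshold_pct = curve.best_cutoff_pct
        roc_summary = {
            "auc": curve.auc,
            "points": [dataclasses.asdict(p) for p in curve.points],
            "fitted_cutoff_pct": threshold_pct,
        }
    else:
        threshold_pct = float(config.threshold_pct)
        roc_summary = None

    maxaf_train, diag_train = _diagnose_cohort(training, filtered_train,
                                               threshold_pct)
    bundle: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "threshold_pct": threshold_pct,
        "roc": roc_summary,
        "training": {
            "n": len(training.clinical),
            "filter_reports": reports_train,
            "diagnostics": diag_train,
            "cnv": _cnv_cohort(training, config, train_sim),
            "concordance": _concordance_cohort(training, filtered_train,
                                               config.driver_genes),
            "outcomes": _outcomes_cohort(training, maxaf_train),
        },
    }

    val_sim = config.resolved_validation()
    if val_sim is None or (val_sim.n_pm + val_sim.n_nonpm) == 0:
        bundle["validation"] = None
        return bundle
    validation = generate_cohort(val_sim)
    filtered_val, reports_val = _filter_cohort(validation,
                                               config.filter_params)
    maxaf_val, diag_val = _diagnose_cohort(validation, filtered_val,
                                           threshold_pct)
    bundle["validation"] = {
        "n": len(validation.clinical),
        "filter_reports": reports_val,
        "diagnostics": diag_val,
        "outcomes": _outcomes_cohort(validation, maxaf_val),
    }
    return bundle


def bundle_to_json(bundle: dict[str, Any]) -> str:
    return json.dumps(bundle, sort_keys=True, indent=2, allow_nan=False)


def make_report(bundle: dict[str, Any], format: str,
                out_dir: str | Path) -> list[Path]:
    """Serialize a report bundle as json, tsv or markdown files with stable
    field ordering."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "json":
        path = out_dir / "report.json"
        path.write_text(bundle_to_json(bundle) + "\n")
        return [path]
    if format == "tsv":
        import pandas as pd
        paths = []
        for cohort in ("training", "validation"):
            section = bundle.get(cohort)
            if not section:
                continue
            maxaf = section["diagnostics"]["maxaf_pct"]
            positive = section["diagnostics"]["positive"]
            frame = pd.DataFrame({
                "sample_id": sorted(maxaf),
                "maxaf_pct": [maxaf[s] for s in sorted(maxaf)],
                "positive": [positive[s] for s in sorted(maxaf)],
            })
            path = out_dir / f"maxaf_{cohort}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths.append(path)
        return paths
    if format == "markdown":
        lines = [f"# Peritoneal cfDNA pipeline report",
                 "",
                 f"version {bundle['version']}, config {bundle['config_hash']}",
                 f"positivity cutoff: MaxAF > {bundle['threshold_pct']:.2f}%",
                 ""]
        for cohort in ("training", "validation"):
            section = bundle.get(cohort)
            if not section:
                continue
            lines.append(f"## {cohort.capitalize()} cohort "
                         f"(n = {section['n']})")
            lines.append("")
            metrics = section["diagnostics"]["metrics"]
            for name in ("sensitivity", "specificity", "accuracy",
                         "ppv", "npv"):
                value = metrics[name]
                shown = "undefined" if value is None else f"{value}%"
                lines.append(f"- {name}: {shown}")
            lines.append("")
        path = out_dir / "report.md"
        path.write_text("\n".join(lines))
        return [path]
    raise ValidationError(f"format: unknown report format {format!r}")
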