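"""Shared plumbing for the numbered analysis drivers: locate the synthetic
cohort tables written by 01_simulate_cohort.py, or regenerate them in memory
for standalone runs."""

from __future__ import annotations

import argparse
from pathlib import Path

from pericfdna import io
from pericfdna.simulate import SimulationConfig, generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def make_parser(description: str) -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results-dir", type=Path, default=RESULTS)
    return parser


def training_config(seed: int) -> SimulationConfig:
    return SimulationConfig(seed=seed, cohort="training", id_prefix="T")


def validation_config(seed: int) -> SimulationConfig:
    return SimulationConfig(n_pm=6, n_nonpm=5, cohort="validation",
                            id_prefix="V", seed=seed + 1_000_003,
                            chemo_pretreated_rate=1 / 6,
                            nonpm_fld_positive_rate=0.0)


def load_cohort(results_dir: Path, seed: int, cohort: str):
    """Read the tables 01 wrote when present, else simulate afresh."""
    base = results_dir / "synthetic" / cohort
    if (base / "variants.tsv").exists():
        variants = io.read_variant_table(base / "variants.tsv")
        coverage = io.read_coverage_table(base / "coverage.tsv")
        clinical = io.read_clinical_table(base / "clinical.csv")
        return variants, coverage, clinical
    config = (training_config(seed) if cohort == "training"
              else validation_config(seed))
    simulated = generate_cohort(config)
    return simulated.variants, simulated.coverage, simulated.clinical


def by_patient(variants):
    grouped: dict[str, dict[str, list]] = {}
    for v in variants:
        grouped.setdefault(v.sample_id, {"FLD": [], "TIS": [], "WBC": []})[
            v.origin].append(v)
    return grouped
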