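"""Simulate the study cohorts and write their tables.

Generates a 17 PM / 23 non-PM training cohort and a 6 PM / 5 non-PM
validation cohort (matched FLD/TIS/WBC variant calls, tissue coverage
profiles, clinical outcomes) and writes them under
results/synthetic/<cohort>/ for the downstream drivers.
"""

from pericfdna import io
from pericfdna.simulate import generate_cohort

from _common import make_parser, training_config, validation_config


def main() -> None:
    args = make_parser(__doc__).parse_args()
    for name, config in (("training", training_config(args.seed)),
                         ("validation", validation_config(args.seed))):
        cohort = generate_cohort(config)
        out = args.results_dir / "synthetic" / name
        out.mkdir(parents=True, exist_ok=True)
        io.write_variant_table(cohort.variants, out / "variants.tsv")
        io.write_coverage_table(cohort.coverage, out / "coverage.tsv")
        io.write_clinical_table(cohort.clinical, out / "clinical.csv")
        n_pm = sum(1 for r in cohort.clinical if r.arm == "PM")
        print(f"{name}: {len(cohort.clinical)} patients "
              f"({n_pm} PM / {len(cohort.clinical) - n_pm} non-PM), "
              f"{len(cohort.variants)} variant calls -> {out}")


if __name__ == "__main__":
    main()
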