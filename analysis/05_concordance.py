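"""Lavage-versus-tissue mutation concordance in PM patients.

Partitions each PM patient's filtered FLD and TIS variant sets into
shared / FLD-only / TIS-only, pools the partition across patients (all
variants and driver genes only), tabulates per-gene agreement, and
computes the patient-by-gene unweighted Cohen's kappa.
"""

import dataclasses
import json

import pandas as pd

from pericfdna import study
from pericfdna.concordance import (cohens_kappa_unweighted,
                                   concordance_summary, match_variants,
                                   per_gene_concordance)
from pericfdna.filters import run_filter_cascade

from _common import by_patient, load_cohort, make_parser


def main() -> None:
    args = make_parser(__doc__).parse_args()
    variants, _, clinical = load_cohort(args.results_dir, args.seed,
                                        "training")
    grouped = by_patient(variants)
    filtered = {}
    for pid in sorted(grouped):
        fld, _ = run_filter_cascade(grouped[pid]["FLD"],
                                    grouped[pid]["WBC"], "fluid")
        tis, _ = run_filter_cascade(grouped[pid]["TIS"],
                                    grouped[pid]["WBC"], "tissue")
        filtered[pid] = (fld, tis)

    pm_ids = sorted(r.sample_id for r in clinical if r.arm == "PM")
    pm_parts = [match_variants(*filtered[pid]) for pid in pm_ids]
    summary = concordance_summary(pm_parts)
    driver = concordance_summary(pm_parts, driver_only=True)
    print(f"PM patients, all variants: {summary.shared_pct}% shared, "
          f"{summary.tis_only_pct}% TIS-only, {summary.fld_only_pct}% "
          f"FLD-only; lavage variant-level sensitivity "
          f"{summary.fld_variant_sensitivity_pct}%")
    print(f"driver genes only: {driver.shared_pct}% shared "
          f"(sensitivity {driver.fld_variant_sensitivity_pct}%)")

    all_parts = [match_variants(*filtered[pid]) for pid in sorted(filtered)]
    rows = [{"gene": gene,
             **dict(zip(("n_shared_patients", "n_discordant_patients"),
                        per_gene_concordance(all_parts, gene)))}
            for gene in study.DRIVER_GENES]
    calls_fld, calls_tis = [], []
    for pid in sorted(filtered):
        fld_genes = {v.gene for v in filtered[pid][0]}
        tis_genes = {v.gene for v in filtered[pid][1]}
        for gene in study.DRIVER_GENES:
            calls_fld.append(gene in fld_genes)
            calls_tis.append(gene in tis_genes)
    kappa = cohens_kappa_unweighted(calls_fld, calls_tis)
    print(f"patient x driver-gene agreement: Cohen's kappa {kappa:.2f}")

    out = args.results_dir / "concordance"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "per_gene.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps({
        "all_variants": dataclasses.asdict(summary),
        "driver_variants": dataclasses.asdict(driver),
        "kappa_patient_gene": kappa,
    }, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
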