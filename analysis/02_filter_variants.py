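"""Apply the variant filter cascade to every sample.

Each patient's lavage (FLD) and tissue (TIS) calls are filtered by depth
(>= 100x), supporting reads (SNV >= 8; indel >= 2 in fluid, >= 5 in
tissue), population frequency (<= 0.1%) and matched-normal (WBC)
subtraction. Writes the filtered variant tables plus a per-sample removal
accounting, and prints what the germline filters removed.
"""

import pandas as pd

from pericfdna import io
from pericfdna.filters import run_filter_cascade

from _common import by_patient, load_cohort, make_parser


def main() -> None:
    args = make_parser(__doc__).parse_args()
    for cohort in ("training", "validation"):
        variants, _, _ = load_cohort(args.results_dir, args.seed, cohort)
        grouped = by_patient(variants)
        kept, rows = [], []
        for pid in sorted(grouped):
            for origin, origin_type in (("FLD", "fluid"), ("TIS", "tissue")):
                filtered, report = run_filter_cascade(
                    grouped[pid][origin], grouped[pid]["WBC"], origin_type)
                kept.extend(filtered)
                rows.append({"sample_id": pid, "origin": origin,
                             "input": report.input_count,
                             "depth": report.removed_by_depth,
                             "support": report.removed_by_support,
                             "popfreq": report.removed_by_popfreq,
                             "matched_normal":
                                 report.removed_by_matched_normal,
                             "output": report.output_count})
        out = args.results_dir / "filtered"
        out.mkdir(parents=True, exist_ok=True)
        io.write_variant_table(kept, out / f"{cohort}_variants.tsv")
        frame = pd.DataFrame(rows)
        frame.to_csv(out / f"{cohort}_filter_report.tsv", sep="\t",
                     index=False)
        totals = frame[["input", "popfreq", "matched_normal",
                        "output"]].sum()
        print(f"{cohort}: {totals['input']} calls in, {totals['output']} "
              f"somatic calls out; population-frequency filter removed "
              f"{totals['popfreq']} presumed SNPs and matched-normal "
              f"subtraction a further {totals['matched_normal']}")


if __name__ == "__main__":
    main()
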