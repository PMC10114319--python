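"""MaxAF positivity scoring and diagnostic accuracy.

Scores every lavage by MaxAF over its filtered SNV/Indel calls, fits the
positivity cutoff on the training cohort (ROC, Youden's J), applies it
unchanged to the validation cohort, and reports sensitivity/specificity/
accuracy/PPV/NPV per cohort plus Fisher's exact p. Also prints the metrics
the published contingency counts imply, for comparison with the synthetic
run.
"""

import dataclasses
import json

from pericfdna import study
from pericfdna.diagnostics import (build_contingency, compute_maxaf,
                                   diagnostic_metrics,
                                   fisher_exact_two_sided, roc_curve)
from pericfdna.filters import run_filter_cascade
from pericfdna.models import ContingencyTable

from _common import by_patient, load_cohort, make_parser


def score_cohort(variants, clinical, threshold_pct):
    grouped = by_patient(variants)
    arm_of = {r.sample_id: r.arm for r in clinical}
    maxaf = {}
    for pid in sorted(grouped):
        filtered, _ = run_filter_cascade(grouped[pid]["FLD"],
                                         grouped[pid]["WBC"], "fluid")
        maxaf[pid] = compute_maxaf(filtered, sample_id=pid,
                                   threshold_pct=threshold_pct)
    scores = [(maxaf[pid].maxaf_pct, arm_of[pid] == "PM") for pid in maxaf]
    return maxaf, scores, arm_of


def main() -> None:
    args = make_parser(__doc__).parse_args()
    payload = {}

    train_vars, _, train_clin = load_cohort(args.results_dir, args.seed,
                                            "training")
    maxaf, scores, arm_of = score_cohort(train_vars, train_clin, 100.0)
    curve = roc_curve(scores)
    cutoff = curve.best_cutoff_pct
    print(f"training ROC: AUC {curve.auc:.3f}, fitted cutoff "
          f"MaxAF > {cutoff:.2f}% (Youden)")
    payload["roc"] = {"auc": curve.auc, "fitted_cutoff_pct": cutoff}

    for cohort in ("training", "validation"):
        variants, _, clinical = load_cohort(args.results_dir, args.seed,
                                            cohort)
        maxaf, _, arm_of = score_cohort(variants, clinical, cutoff)
        table = build_contingency({p: r.positive for p, r in maxaf.items()},
                                  {p: arm_of[p] == "PM" for p in maxaf})
        metrics = diagnostic_metrics(table)
        payload[cohort] = {"contingency": dataclasses.asdict(table),
                           "metrics": metrics,
                           "fisher_p": fisher_exact_two_sided(table)}
        print(f"{cohort}: tp={table.tp} fp={table.fp} fn={table.fn} "
              f"tn={table.tn} -> sensitivity {metrics['sensitivity']}%, "
              f"specificity {metrics['specificity']}%, "
              f"accuracy {metrics['accuracy']}%")

    published = diagnostic_metrics(
        ContingencyTable(**study.TRAINING_CONTINGENCY))
    print(f"published training counts imply {published['sensitivity']}/"
          f"{published['specificity']}/{published['accuracy']} "
          "(sensitivity/specificity/accuracy)")

    out = args.results_dir / "diagnostics"
    out.mkdir(parents=True, exist_ok=True)
    (out / "accuracy.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
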