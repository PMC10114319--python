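"""Published cohort summaries from the motivating prospective diagnostic
study of peritoneal lavage cfDNA for colorectal-cancer peritoneal
metastasis.

The study deposited no per-variant or per-patient data, only printed
summary counts. Those counts are the *inputs* to the worked examples
reproduced by this package (diagnostic accuracy, concordance sensitivity,
recurrence summaries) and the calibration anchors for the synthetic
cohort generator's defaults.
"""

from __future__ import annotations

#: driver gene set used for the driver-restricted concordance analysis
DRIVER_GENES = ("KRAS", "BRAF", "TP53", "APC", "PIK3CA", "SMAD4")

#: MaxAF positivity cutoff (percent) selected on the training cohort by ROC
POSITIVITY_THRESHOLD_PCT = 6.29

#: capture panel footprint, megabases (TMB denominator)
PANEL_MEGABASES = 1.64

#: mean target sequencing depths
FLD_MEAN_DEPTH = 35_000
TIS_MEAN_DEPTH = 1_000

# -- training cohort (n = 40: 17 PM, 23 non-PM) -----------------------------

#: 17/17 PM lavages positive; 5/23 non-PM lavages positive
TRAINING_CONTINGENCY = {"tp": 17, "fp": 5, "fn": 0, "tn": 18}

# -- validation cohort (n = 11: 6 PM, 5 non-PM) ------------------------------

#: 5/6 PM positive (one false negative after neoadjuvant chemotherapy),
#: 0/5 non-PM positive
VALIDATION_CONTINGENCY = {"tp": 5, "fp": 0, "fn": 1, "tn": 5}

# -- FLD/TIS variant concordance in PM patients ------------------------------

#: pooled partition of the variant union across PM patients, all classes
POOLED_VARIANT_FRACTIONS = {
    "shared_pct": 56.0, "tis_only_pct": 20.3, "fld_only_pct": 23.7,
    "n_shared": 66,
}
#: same partition restricted to the six driver genes
DRIVER_VARIANT_FRACTIONS = {
    "shared_pct": 83.6, "tis_only_pct": 7.3, "fld_only_pct": 9.1,
    "n_shared": 46,
}

# -- driver mutation frequencies --------------------------------------------

#: per-gene mutation frequency in tumor tissue of PM patients (n = 17)
TIS_PM_DRIVER_FREQS = {
    "KRAS": 0.529, "BRAF": 0.235, "TP53": 0.765,
    "APC": 0.471, "PIK3CA": 0.176, "SMAD4": 0.235,
}
#: per-gene mutation frequency in tumor tissue of non-PM patients (n = 23)
TIS_NONPM_DRIVER_FREQS = {
    "KRAS": 0.522, "BRAF": 0.0, "TP53": 0.826,
    "APC": 0.739, "PIK3CA": 0.174, "SMAD4": 0.130,
}
#: per-gene mutation frequency in lavage cfDNA of PM patients
FLD_PM_DRIVER_FREQS = {
    "KRAS": 0.58, "BRAF": 0.10, "TP53": 0.70,
    "APC": 0.47, "PIK3CA": 0.05, "SMAD4": 0.41,
}

#: tumor mutational burden in tissue, mutations per megabase (mean)
TMB_TIS_PM = 3.93
TMB_TIS_NONPM = 6.55

# -- outcomes among the 23 non-PM training patients ---------------------------

#: MaxAF (percent) of the three cfDNA-positive non-PM patients who recurred
RECURRENT_POSITIVE_MAXAF_PCT = (31.3, 13.6, 11.4)
#: days by which cfDNA positivity preceded radiographic recurrence
LEAD_TIME_DAYS = (409, 184, 25)
#: recurrences among cfDNA-positive / cfDNA-negative non-PM patients
POSITIVE_GROUP_RECURRENCE = (3, 5)
NEGATIVE_GROUP_RECURRENCE = (2, 18)
#: recurrence hazard ratio, cfDNA-positive vs negative non-PM patients
RECURRENCE_HR_POSITIVE = 7.1
#: median follow-up, months
MEDIAN_FOLLOWUP_MONTHS = 13.8

#: chr20q amplification (MSS-A) rates in tissue: 0/17 PM, 4/22 non-PM
MSS_A_RATE_PM = 0.0
MSS_A_RATE_NONPM = 4 / 22
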