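"""Diagnostic accuracy of ICD-code capture on the fixture cohort.

Prints the histopathology-vs-index-of-suspicion 2x2 table and the PPV /
sensitivity estimates with exact (Clopper-Pearson) 95% CIs.  The PPV of
codes alone is the fraction of coded patients with a high index of
suspicion (0.79 here); adding the high-index requirement raises the PPV to
1.00 because chart-review adjudication and the index coincide by design.
"""

from sarcphen import build_fixture_cohort, classify_cohort, validation_report

rep = validation_report(classify_cohort(build_fixture_cohort()))

print("2x2 table (rows: histopathology; cols: index of suspicion)")
for label, row in zip(rep["table"]["row_labels"], rep["table"]["counts"]):
    print(f"  {label:20s} {row}")

for key in ("ppv_icd_alone", "ppv_icd_confirmed", "ppv_icd_plus_index",
            "sensitivity_histopathology"):
    e = rep[key]
    print(f"{key}: {e['estimate']:.4f} ({e['numerator']}/{e['denominator']}, "
          f"95% CI {e['ci_low']:.4f}-{e['ci_high']:.4f})")
print(f"specificity: {rep['specificity']}")
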