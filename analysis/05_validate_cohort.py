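"""Reproduce the clinical validation arithmetic on the 56-patient cohort.

Computes confusion counts and diagnostic metrics from the packaged
per-patient table, with and without the three patients whose chemotherapy
was changed after the prediction was disclosed, plus the cohort summary.
Writes results/validation_metrics.json.
"""

import json
import os

from qusrad.validation import load_cohort, validate_report

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)

records = load_cohort()
report = {
    "all_patients": validate_report(records),
    "excluding_treatment_changed": validate_report(records, exclude_changed=True),
}
with open(os.path.join(OUT, "validation_metrics.json"), "w") as fh:
    json.dump(report, fh, indent=2)

for key, block in report.items():
    m = block["metrics"]
    c = block["counts"]
    print(f"{key} (n={block['summary']['n']}):")
    print(f"  counts TP={c['TP']} FP={c['FP']} FN={c['FN']} TN={c['TN']}")
    print(f"  sensitivity {m['sensitivity']}%  specificity {m['specificity']}%  "
          f"PPV {m['ppv']}%  NPV {m['npv']}%  F1 {m['f1']}%")
s = report["all_patients"]["summary"]
print(f"median age {s['median_age']:.0f} y; median pre-treatment size "
      f"{s['median_pre_size']:.2f} cm; response rate {s['response_rate']}%")
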