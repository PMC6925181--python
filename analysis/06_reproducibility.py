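#!/usr/bin/env python
"""Cross-visit reproducibility: hubs, kappa agreement, ICC.

The healthy cohort's network should be stable across visits (high kappa
and ICC); the disease cohort, whose differential edges change between
visits, less so.
"""

import json

with open("results/analysis/run/report.json") as fh:
    report = json.load(fh)

rep = report["reproducibility"]
print("hub counts:", rep["hub_counts"])
for cohort, sec in rep["kappa_curves"].items():
    print(f"{cohort}: mean hub-agreement kappa across thresholds = "
          f"{sec['mean_kappa']:.3f}")

print("\nICC(1,1) of nodal metrics across visits:")
for cohort, metrics in rep["icc"].items():
    row = ", ".join(f"{m}={v:.2f}" for m, v in metrics.items())
    print(f"  {cohort}: {row}")
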