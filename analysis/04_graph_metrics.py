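#!/usr/bin/env python
"""Global and RSN-level graph metrics per condition.

Summarizes the fitted networks from 03_fit_and_compare.py: density,
within-RSN edge concentration, small-worldedness, and the posterior means
of the global metrics (the quantities compared between cohorts).
"""

import json

with open("results/analysis/run/report.json") as fh:
    report = json.load(fh)

metrics = report["metrics"]
cols = ["edge_count", "density_pct", "within_rsn_pct", "small_worldedness"]
print(f"{'condition':<14}" + "".join(f"{c:>18}" for c in cols))
for cid, row in metrics.items():
    print(
        f"{cid:<14}"
        + "".join(
            f"{row[c]:>18.3f}" if isinstance(row[c], float) else f"{row[c]:>18}"
            for c in cols
        )
    )

print("\nposterior means (ge / cpl / mcc / le):")
for cid, row in metrics.items():
    vals = [row[f"{m}_posterior_mean"] for m in ("ge", "cpl", "mcc", "le")]
    print(f"{cid:<14}" + "".join(f"{v:>10.3f}" for v in vals))
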