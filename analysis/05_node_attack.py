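#!/usr/bin/env python
"""Node-attack rankings: which nodes disrupt information flow the most.

Reads the attack tables written by 03_fit_and_compare.py and prints, per
condition, the nodes whose disconnection causes the largest percent
change in global efficiency (disruptors are expected to be hub nodes).
"""

import json

import pandas as pd

with open("results/analysis/run/report.json") as fh:
    report = json.load(fh)

for cid, sec in report["attack"].items():
    if cid == "max_abs_difference":
        continue
    table = pd.read_csv(f"results/analysis/run/attack_{cid}.tsv", sep="\t")
    ge = table[table.metric_name == "ge"].nsmallest(5, "percent_change")
    tops = ", ".join(
        f"{int(r.node_id) + 1} ({r.percent_change:+.1f}%)" for r in ge.itertuples()
    )
    print(f"{cid}: top GE disruptors (1-based node ids): {tops}")

print("\nlargest |AD - HC| attack differences per metric:")
for key, val in report["attack"]["max_abs_difference"].items():
    print(f"  {key}: {val:.2f} percentage points")
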