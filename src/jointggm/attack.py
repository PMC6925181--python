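"""Node attack: disconnect one node at a time and remeasure global metrics.

The attacked node is retained as an isolated vertex (its row and column
zeroed) rather than deleted, so the node count and efficiency denominators
stay comparable across attacks; CPL averages over reachable pairs, so the
isolated node simply drops out of it.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from jointggm.graph_metrics import BinaryNetwork, compute_metric

DEFAULT_ATTACK_METRICS = ("ge", "cpl", "mcc")


@dataclasses.dataclass
class AttackResult:
    """Percent change of one metric when one node is disconnected."""

    node_id: int
    metric_name: str
    baseline_value: float
    attacked_value: float
    percent_change: float  # 100 * (attacked - baseline) / baseline
    condition_id: str = ""


def attack_node(net: BinaryNetwork, node: int) -> BinaryNetwork:
    """Return a copy of the network with ``node`` isolated."""
    if not 0 <= node < net.node_count:
        raise IndexError(f"invalid node index {node}")
    adj = net.adjacency.copy()
    adj[node, :] = 0
    adj[:, node] = 0
    return BinaryNetwork(adj, list(net.rsn_labels), list(net.node_ids))


def attack_analysis(
    net: BinaryNetwork,
    metrics: tuple[str, ...] = DEFAULT_ATTACK_METRICS,
    top_k: int = 10,
    condition_id: str = "",
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Attack every node, one metric row per node x metric, plus rankings.

    Percent change is relative to the unattacked baseline of the same
    network; a zero baseline yields a missing (NaN) percent change.
    Rankings order nodes by absolute percent change descending, ties broken
    by node id ascending.
    """
    baselines = {m: compute_metric(net, m) for m in metrics}
    records = []
    for node in range(net.node_count):
        attacked = attack_node(net, node)
        for m in metrics:
            base = baselines[m]
            try:
                val = compute_metric(attacked, m)
            except ValueError:
                val = float("nan")
            pct = 100.0 * (val - base) / base if base != 0 else float("nan")
            records.append(
                AttackResult(
                    node_id=node,
                    metric_name=m,
                    baseline_value=base,
                    attacked_value=val,
                    percent_change=pct,
                    condition_id=condition_id,
                )
            )
    table = pd.DataFrame([dataclasses.asdict(r) for r in records])
    rankings: dict[str, list[int]] = {}
    for m in metrics:
        sub = table[table.metric_name == m].copy()
        sub["abs_pct"] = sub.percent_change.abs()
        sub = sub.sort_values(["abs_pct", "node_id"], ascending=[False, True])
        rankings[m] = sub.node_id.head(top_k).tolist()
    return table, rankings


def attack_difference(
    table_a: pd.DataFrame, table_b: pd.DataFrame, metric: str
) -> pd.DataFrame:
    """Per-node difference in percent change (condition b minus a).

    Mirrors a two-cohort comparison column: positive values mean the
    second condition lost less (or gained more) of the metric.
    """
    a = table_a[table_a.metric_name == metric].set_index("node_id").percent_change
    b = table_b[table_b.metric_name == metric].set_index("node_id").percent_change
    return pd.DataFrame(
        {"pct_change_a": a, "pct_change_b": b, "difference": b - a}
    ).reset_index()
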