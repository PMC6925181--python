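"""Recovery evaluation of fitted posteriors against simulation ground truth."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from jointggm.joint_network import PosteriorSummary
from jointggm.synthetic import GroundTruthNetworks


def edge_recovery_auc(
    summary: PosteriorSummary,
    truth: GroundTruthNetworks,
    condition_id: str,
    edges: str = "all",
) -> float:
    """ROC AUC of posterior inclusion probabilities against the true graph.

    ``edges="all"`` scores every node pair.  ``edges="shared"`` scores only
    the edges common to all conditions against non-edges (the condition's
    own differential edges are excluded from the evaluation set), which
    isolates the benefit of pooling across conditions.
    """
    rows, cols = np.triu_indices(truth.node_count, 1)
    true_edges = truth.edges(condition_id)
    scores = summary.pip[condition_id][rows, cols]
    if edges == "all":
        y = np.array([(int(i), int(j)) in true_edges for i, j in zip(rows, cols)])
        keep = np.ones(len(y), dtype=bool)
    elif edges == "shared":
        y = np.array(
            [(int(i), int(j)) in truth.shared_edges for i, j in zip(rows, cols)]
        )
        diff = truth.differential_edges[condition_id]
        keep = np.array(
            [(int(i), int(j)) not in diff for i, j in zip(rows, cols)]
        )
    else:
        raise ValueError("edges must be 'all' or 'shared'")
    return float(roc_auc_score(y[keep], scores[keep]))
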