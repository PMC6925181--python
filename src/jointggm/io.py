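"""Plain-text dataset and result I/O.

Datasets live as one TSV per subject (T rows x p columns, header = node
ids), a JSON manifest grouping subjects into conditions, and a node
metadata TSV (node_id, rsn_label).  Written tables use 1-based node ids;
indexing is 0-based everywhere in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from jointggm.synthetic import TimeSeriesDataset


def write_dataset(
    dataset: TimeSeriesDataset, rsn_labels: list[str], out_dir: str | Path
) -> Path:
    """Write per-subject TSVs, node metadata, and the JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = dataset.node_count
    node_cols = [f"node{j + 1}" for j in range(p)]
    manifest = {
        "ar_coefficient": dataset.ar_coefficient,
        "seed": dataset.seed,
        "conditions": {},
    }
    for cid, sid, x in dataset.records:
        fname = f"{sid}.tsv"
        pd.DataFrame(x, columns=node_cols).to_csv(out / fname, sep="\t", index=False)
        manifest["conditions"].setdefault(cid, []).append(
            {"subject_id": sid, "file": fname}
        )
    pd.DataFrame(
        {"node_id": np.arange(1, p + 1), "rsn_label": rsn_labels}
    ).to_csv(out / "nodes.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out / "manifest.json"


def load_dataset(
    manifest_path: str | Path, metadata_path: str | Path | None = None
) -> tuple[TimeSeriesDataset, list[str]]:
    """Read the manifest/TSV layout back; validates shapes and labels."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    if metadata_path is None:
        metadata_path = base / "nodes.tsv"
    meta = pd.read_csv(metadata_path, sep="\t")
    if meta.node_id.duplicated().any():
        raise ValueError("duplicate node ids in metadata")
    labels = meta.rsn_label.astype(str).tolist()
    records = []
    for cid, subs in sorted(manifest["conditions"].items()):
        for entry in subs:
            f = base / entry["file"]
            if not f.exists():
                raise FileNotFoundError(f"missing subject file: {f}")
            x = pd.read_csv(f, sep="\t", float_precision="round_trip").to_numpy(
                dtype=float
            )
            if x.shape[1] != len(labels):
                raise ValueError(
                    f"{f}: {x.shape[1]} columns but {len(labels)} node labels"
                )
            records.append((cid, entry["subject_id"], x))
    ds = TimeSeriesDataset(
        records=records,
        ar_coefficient=float(manifest.get("ar_coefficient", 0.0)),
        seed=int(manifest.get("seed", 0)),
    )
    ds.validate()
    return ds, labels


def write_matrix_csv(matrix: np.ndarray, path: str | Path, node_ids=None) -> None:
    """Square matrix as CSV with 1-based node-id headers."""
    p = matrix.shape[0]
    ids = node_ids if node_ids is not None else [f"node{j + 1}" for j in range(p)]
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path)


def read_matrix_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)


def write_tidy_metrics(rows: list[dict], path: str | Path) -> None:
    """Tidy TSV (condition, metric, scope, value), stably sorted."""
    df = pd.DataFrame(rows)
    df = df.sort_values(list(df.columns)).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def dump_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
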