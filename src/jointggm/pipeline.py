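"""End-to-end orchestration: dataset -> joint fit -> full result set.

``run_pipeline`` chains the stages: simulate (optional) -> prewhiten ->
joint MCMC fit -> graph metrics and metric posteriors -> node attack ->
hubs / kappa / ICC -> significance comparisons -> separate graphical-lasso
arm.  Every stage writes plain-text artifacts under the output directory
and contributes a section to a JSON report; re-running with the same
config and seed reproduces all numeric outputs bit-identically (the report
carries a hash over its numeric content).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from jointggm import io as jio
from jointggm.attack import attack_analysis, attack_difference
from jointggm.glasso import density_matched_fit
from jointggm.graph_metrics import (
    BinaryNetwork,
    betweenness,
    clustering_coefficients,
    local_efficiency,
    metric_posterior,
    network_summaries,
    participation_coefficient,
    rsn_subnetwork_metrics,
    small_worldedness,
    compute_metric,
)
from jointggm.inference import (
    bonferroni_alpha,
    credible_interval_comparison,
    edge_difference_rate,
    wilcoxon_signed_rank,
)
from jointggm.joint_network import JointGGMConfig, call_edges, run_mcmc
from jointggm.preprocess import prepare_condition
from jointggm.reproducibility import icc_oneway, identify_hubs, kappa_curve
from jointggm.synthetic import (
    DEFAULT_CONDITIONS,
    generate_ground_truth,
    sample_time_series,
)

_ALL_STAGES = (
    "simulate",
    "prewhiten",
    "fit_joint",
    "metrics",
    "attack",
    "reproducibility",
    "inference",
    "glasso",
)


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML or JSON."""

    seed: int = 1
    out_dir: str = "results/run"
    manifest: str | None = None
    node_metadata: str | None = None
    synthetic: dict = dataclasses.field(
        default_factory=lambda: {
            "node_count": 20,
            "rsn_sizes": [10, 10],
            "within_density": 0.4,
            "between_density": 0.02,
            "shared_fraction": 0.7,
            "condition_ids": list(DEFAULT_CONDITIONS),
            "subjects_per_condition": 10,
            "T": 200,
            "ar_coefficient": 0.3,
        }
    )
    prewhiten: dict = dataclasses.field(
        default_factory=lambda: {"max_order": 1, "order_selection": "fixed"}
    )
    joint: dict = dataclasses.field(default_factory=dict)
    global_metrics: list = dataclasses.field(
        default_factory=lambda: ["ge", "cpl", "mcc", "le", "density"]
    )
    null_config: dict = dataclasses.field(
        default_factory=lambda: {"n_nulls": 20, "rewires_per_edge": 10}
    )
    max_posterior_draws: int = 200
    attack_metrics: list = dataclasses.field(default_factory=lambda: ["ge", "cpl", "mcc"])
    attack_top_k: int = 10
    hub_c: float = 1.5
    alpha: float = 0.01
    m_comparisons: int = 15
    glasso_tol_density: float = 0.5
    stages: dict = dataclasses.field(
        default_factory=lambda: {s: True for s in _ALL_STAGES}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for s in cfg.stages:
            if s not in _ALL_STAGES:
                raise ValueError(f"unknown stage toggle: {s}")
        return cfg

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def _require(report: dict, section: str, needed_by: str):
    if section not in report:
        raise RuntimeError(
            f"stage '{needed_by}' requires '{section}', which is disabled or failed"
        )


def _cohort_visits(condition_ids: list[str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for cid in condition_ids:
        cohort = cid.split("-", 1)[0]
        groups.setdefault(cohort, []).append(cid)
    return groups


def report_hash(report: dict) -> str:
    """SHA-256 over the canonical JSON of the numeric result sections.

    'meta' (timings) and 'config' (contains machine-local paths) are
    excluded, so equal seeds on equal inputs give equal hashes anywhere.
    """
    payload = {k: v for k, v in report.items() if k not in ("meta", "config")}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns (and writes) the run report."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config)}
    rng_seed = int(config.seed)

    # --- data -------------------------------------------------------------
    truth = None
    if config.manifest is not None:
        dataset, labels = jio.load_dataset(config.manifest, config.node_metadata)
    elif config.enabled("simulate"):
        syn = dict(config.synthetic)
        subjects = syn.pop("subjects_per_condition")
        T = syn.pop("T")
        phi = syn.pop("ar_coefficient")
        truth = generate_ground_truth(seed=rng_seed, **syn)
        dataset = sample_time_series(
            truth, subjects, T, ar_coefficient=phi, seed=rng_seed + 1
        )
        labels = truth.rsn_labels
        jio.write_dataset(dataset, labels, out / "dataset")
        report["simulate"] = {
            "condition_ids": truth.condition_ids,
            "n_shared_edges": len(truth.shared_edges),
            "n_differential_edges": {
                c: len(e) for c, e in truth.differential_edges.items()
            },
        }
    else:
        raise RuntimeError("no data source: supply a manifest or enable 'simulate'")
    condition_ids = dataset.condition_ids()

    # --- prewhiten --------------------------------------------------------
    if config.enabled("prewhiten"):
        cond_data = [
            prepare_condition(dataset, cid, **config.prewhiten)
            for cid in condition_ids
        ]
        report["prewhiten"] = {
            cd.condition_id: {"n_rows": cd.n_rows} for cd in cond_data
        }

    # --- joint fit ---------------------------------------------------------
    if config.enabled("fit_joint"):
        _require(report, "prewhiten", "fit_joint")
        jcfg = JointGGMConfig(seed=rng_seed + 2, **config.joint)
        summary = run_mcmc(cond_data, jcfg)
        nets = call_edges(summary, rsn_labels=labels)
        for cid in condition_ids:
            jio.write_matrix_csv(summary.pip[cid], out / f"pip_{cid}.csv")
            jio.write_matrix_csv(
                summary.partial_mean[cid], out / f"partial_mean_{cid}.csv"
            )
            jio.write_matrix_csv(
                nets[cid].adjacency, out / f"adjacency_{cid}.csv"
            )
        report["fit_joint"] = {
            "n_kept": summary.n_kept,
            "edge_counts": {cid: nets[cid].edge_count for cid in condition_ids},
        }

    # --- metrics ------------------------------------------------------------
    if config.enabled("metrics"):
        _require(report, "fit_joint", "metrics")
        sec: dict = {}
        tidy_rows = []
        posteriors: dict[str, dict] = {}
        # thin the stored draws for the metric posteriors
        step = max(1, summary.n_kept // config.max_posterior_draws)
        thin_summary = dataclasses.replace(
            summary,
            z_draws=summary.z_draws[::step],
            partial_draws=summary.partial_draws[::step],
        )
        for cid in condition_ids:
            net = nets[cid]
            summ = network_summaries(net)
            try:
                sigma = small_worldedness(net, seed=rng_seed + 3, **config.null_config)[0]
            except ValueError:
                sigma = float("nan")  # degenerate null (e.g. zero clustering)
            sec[cid] = {
                "edge_count": summ["edge_count"],
                "density_pct": summ["density_pct"],
                "within_rsn_pct": summ["within_rsn_pct"],
                "small_worldedness": sigma,
                "global": {
                    m: compute_metric(net, m) for m in config.global_metrics
                },
                "rsn_ge": rsn_subnetwork_metrics(net, "ge"),
                "rsn_cpl": rsn_subnetwork_metrics(net, "cpl"),
            }
            posteriors[cid] = {
                m: metric_posterior(thin_summary, m, cid, labels)
                for m in config.global_metrics
            }
            for m, post in posteriors[cid].items():
                tidy_rows.append(
                    {
                        "condition": cid,
                        "metric": m,
                        "scope": "posterior_mean",
                        "value": float(post.values.mean()),
                    }
                )
                sec[cid][f"{m}_posterior_mean"] = float(post.values.mean())
        jio.write_tidy_metrics(tidy_rows, out / "metric_posteriors.tsv")
        report["metrics"] = sec

    # --- attack -------------------------------------------------------------
    if config.enabled("attack"):
        _require(report, "fit_joint", "attack")
        sec = {}
        attack_tables = {}
        for cid in condition_ids:
            table, ranking = attack_analysis(
                nets[cid],
                metrics=tuple(config.attack_metrics),
                top_k=config.attack_top_k,
                condition_id=cid,
            )
            attack_tables[cid] = table
            table.to_csv(out / f"attack_{cid}.tsv", sep="\t", index=False)
            sec[cid] = {"top_nodes": ranking}
        cohorts = _cohort_visits(condition_ids)
        diffs = {}
        cohort_names = list(cohorts)
        if len(cohort_names) == 2:
            a, b = cohort_names
            for va, vb in zip(cohorts[a], cohorts[b]):
                for m in config.attack_metrics:
                    d = attack_difference(attack_tables[va], attack_tables[vb], m)
                    key = f"{m}:{vb}-minus-{va}"
                    diffs[key] = float(d.difference.abs().max())
                    d.to_csv(out / f"attack_diff_{m}_{va}_vs_{vb}.tsv", sep="\t", index=False)
        sec["max_abs_difference"] = diffs
        report["attack"] = sec

    # --- reproducibility ----------------------------------------------------
    if config.enabled("reproducibility"):
        _require(report, "fit_joint", "reproducibility")
        bt = {cid: betweenness(nets[cid]) for cid in condition_ids}
        hubs = {
            cid: sorted(identify_hubs(bt[cid], config.hub_c))
            for cid in condition_ids
        }
        sec = {"hubs": hubs, "hub_counts": {c: len(h) for c, h in hubs.items()}}
        cohorts = _cohort_visits(condition_ids)
        icc_metrics = {
            "betweenness": bt,
            "participation": {
                cid: participation_coefficient(nets[cid]) for cid in condition_ids
            },
            "degree": {cid: nets[cid].degrees().astype(float) for cid in condition_ids},
            "local_efficiency": {
                cid: local_efficiency(nets[cid])[0] for cid in condition_ids
            },
            "clustering": {
                cid: clustering_coefficients(nets[cid])[0] for cid in condition_ids
            },
        }
        sec["kappa_curves"] = {}
        sec["icc"] = {}
        for cohort, visits in cohorts.items():
            if len(visits) < 2:
                continue
            v1, v2 = visits[:2]
            curve = kappa_curve(bt[v1], bt[v2])
            sec["kappa_curves"][cohort] = {
                "mean_kappa": float(
                    np.nanmean([k for _, k in curve]) if curve else np.nan
                )
            }
            with open(out / f"kappa_curve_{cohort}.tsv", "w") as fh:
                fh.write("threshold\tkappa\n")
                for t, k in curve:
                    fh.write(f"{t:.8g}\t{k:.8g}\n")
            sec["icc"][cohort] = {}
            for mname, per_cond in icc_metrics.items():
                mat = np.column_stack([per_cond[v1], per_cond[v2]])
                try:
                    sec["icc"][cohort][mname] = icc_oneway(mat)
                except ValueError:
                    sec["icc"][cohort][mname] = float("nan")
        jio.dump_json(sec["icc"], out / "icc.json")
        report["reproducibility"] = sec

    # --- inference ----------------------------------------------------------
    if config.enabled("inference"):
        _require(report, "metrics", "inference")
        _require(report, "reproducibility", "inference")
        adj_alpha = bonferroni_alpha(config.alpha, config.m_comparisons)
        sec = {"adjusted_alpha": adj_alpha, "metric_comparisons": {}}
        n_draws = next(iter(posteriors.values()))["ge"].values.size
        resolvable = n_draws >= int(np.ceil(2.0 / adj_alpha))
        compare_alpha = adj_alpha if resolvable else max(adj_alpha, 2.0 / n_draws)
        sec["comparison_alpha"] = compare_alpha
        pairs = []
        cohorts = _cohort_visits(condition_ids)
        for cohort, visits in cohorts.items():
            if len(visits) >= 2:
                pairs.append((visits[0], visits[1]))
        names = list(cohorts)
        if len(names) == 2:
            for va, vb in zip(cohorts[names[0]], cohorts[names[1]]):
                pairs.append((va, vb))
        for ca, cb in pairs:
            for m in config.global_metrics:
                res = credible_interval_comparison(
                    posteriors[ca][m], posteriors[cb][m], compare_alpha
                )
                sec["metric_comparisons"][f"{m}:{ca}-vs-{cb}"] = {
                    "interval_a": res.interval_a,
                    "interval_b": res.interval_b,
                    "significant": res.significant,
                }
        if len(names) == 2:
            va, vb = cohorts[names[0]][0], cohorts[names[1]][0]
            try:
                stat, pval = wilcoxon_signed_rank(bt[va], bt[vb])
                sec["wilcoxon_betweenness_baseline"] = {"statistic": stat, "p": pval}
            except ValueError:
                # too few nonzero paired differences at toy scale
                sec["wilcoxon_betweenness_baseline"] = None
            _, rate = edge_difference_rate(summary, va, vb, adj_alpha)
            sec["edge_difference_rate_pct"] = rate
        jio.dump_json(sec, out / "inference.json")
        report["inference"] = sec

    # --- separate (graphical lasso) arm -------------------------------------
    if config.enabled("glasso"):
        _require(report, "metrics", "glasso")
        sec = {}
        gl_nets = {}
        for k, cid in enumerate(condition_ids):
            target = report["metrics"][cid]["density_pct"]
            target = min(max(target, 0.5), 99.5)
            fit = density_matched_fit(
                cond_data[k], target, tol_density=config.glasso_tol_density
            )
            gl_nets[cid] = BinaryNetwork(fit.adjacency, labels)
            jio.write_matrix_csv(fit.adjacency, out / f"glasso_adjacency_{cid}.csv")
            try:
                gl_sigma = small_worldedness(
                    gl_nets[cid], seed=rng_seed + 4, **config.null_config
                )[0]
            except ValueError:
                gl_sigma = float("nan")
            sec[cid] = {
                "penalty": fit.penalty,
                "density_pct": fit.density_pct,
                "within_rsn_pct": network_summaries(gl_nets[cid])["within_rsn_pct"],
                "small_worldedness": gl_sigma,
            }
        cohorts = _cohort_visits(condition_ids)
        sec["icc"] = {}
        for cohort, visits in cohorts.items():
            if len(visits) < 2:
                continue
            v1, v2 = visits[:2]
            mat = np.column_stack(
                [betweenness(gl_nets[v1]), betweenness(gl_nets[v2])]
            )
            try:
                sec["icc"][cohort] = {"betweenness": icc_oneway(mat)}
            except ValueError:
                sec["icc"][cohort] = {"betweenness": float("nan")}
        report["glasso"] = sec

    report["meta"] = {"elapsed_s": time.time() - t0, "seed": config.seed}
    report["hash"] = report_hash(report)
    jio.dump_json(report, out / "report.json")
    return report
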