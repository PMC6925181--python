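# jointggm

Joint Bayesian estimation of longitudinal brain networks, with a
multiscale graph-theoretic comparison toolkit.

## The problem

Resting-state fMRI connectivity studies routinely estimate one brain
network per cohort and visit — a sparse Gaussian graphical model whose
precision matrix `Ω` encodes conditional dependencies (edges) between
atlas nodes — and then compare the networks. Estimating each network
*separately* wastes the information that most edges are common across
visits and cohorts, inflating variance and hurting test-retest
reproducibility. This package implements the alternative: **joint
estimation** of K condition-specific precision matrices whose
edge-inclusion probabilities share a common component,

    ω_ijk | z_ijk ~ z N(0, v1²) + (1−z) N(0, v0²),
    logit P(z_ijk = 1) = θ_ij + δ_ijk,   Σ_k δ_ijk = 0,

sampled by MCMC (column-wise block Gibbs for each `Ω_k`, kept positive
definite by construction, with Polya-Gamma-augmented updates for the
shared effects `θ` and differential effects `δ`). The posterior delivers
edge probabilities, partial correlations `ρ_ij = −ω_ij/√(ω_ii ω_jj)`
with credible intervals, and per-iteration sampled networks.

On the estimated binary networks the package computes the standard
comparison battery: global efficiency (GE), characteristic path length
(CPL), mean clustering (MCC), local efficiency (LE), small-worldedness
σ against degree-preserving nulls, betweenness and participation
coefficients, RSN-level submetrics, node-attack disruption tables,
hub identification (mean + 1.5 sd betweenness rule), cross-visit hub
agreement (Cohen's kappa curves), ICC(1,1) test-retest reliability, and
Bonferroni-adjusted credible-interval comparisons — plus a
density-matched graphical-lasso arm for the separate-estimation
baseline. A synthetic-data module generates ground-truth networks with
RSN block structure and AR(1) subject series, so the whole pipeline is
testable end to end without any data download.

## Worked example

```python
from jointggm import (JointGGMConfig, call_edges, generate_ground_truth,
                      run_mcmc, sample_time_series)
from jointggm.preprocess import prepare_condition
from jointggm.graph_metrics import network_summaries

truth = generate_ground_truth(
    node_count=20, rsn_sizes=[10, 10], within_density=0.4,
    between_density=0.02, shared_fraction=0.7, seed=1)
data = sample_time_series(truth, subjects_per_condition=10, T=200,
                          ar_coefficient=0.3, seed=2)
conds = [prepare_condition(data, c) for c in truth.condition_ids]
summary = run_mcmc(conds, JointGGMConfig(n_iter=2000, burn_in=800, seed=3))
nets = call_edges(summary, rsn_labels=truth.rsn_labels)
for cid, net in nets.items():
    s = network_summaries(net)
    print(cid, len(truth.edges(cid)), s["edge_count"],
          round(s["within_rsn_pct"], 1))
```

prints (true edges, called edges, % of called edges inside RSN blocks):

```
HC-baseline 26 26 92.3
HC-year1 25 25 92.0
AD-baseline 29 29 93.1
AD-year1 27 27 92.6
```

— at this sample size the median-probability model recovers every
planted network exactly, and the called edges concentrate within the RSN
blocks the generator planted.

The full study is the numbered scripts under `analysis/`
(`01_simulate.py` … `08_separate_glasso.py`): simulate, prewhiten, fit
jointly, compare cohorts on global/RSN metrics, attack nodes, measure
cross-visit reproducibility, test significance, and rerun everything
under the separate graphical-lasso arm. On the default synthetic study
the joint fit gives higher cross-visit ICC for the healthy cohort
(e.g. betweenness 0.93 vs 0.87 under the separate arm) and a higher
mean hub-agreement kappa for HC (0.71) than for the cohort with planted
differential edges (0.52) — the qualitative signature the pooling is
designed to produce. The same machinery is exposed as a CLI
(`jointggm all --config cfg.yaml --seed 1 --out results/run`).

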