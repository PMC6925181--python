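# Methods

## The model

Each condition (cohort × visit) is modeled as a Gaussian graphical model:
prewhitened, standardized node series are rows `y ~ N(0, Ω_k^{-1})`, and
the zeros of the precision matrix `Ω_k` encode absent edges. `K`
conditions are estimated **jointly**: each off-diagonal entry `ω_ijk`
carries a continuous spike-and-slab prior,

    ω_ijk | z_ijk = 0  ~  N(0, v0²)       (spike: effectively absent)
    ω_ijk | z_ijk = 1  ~  N(0, v1²)       (slab: present)

with an exponential prior (rate `λ_d`) on diagonals, and the edge
indicators are pooled across conditions through a logistic link

    logit π_ijk = θ_ij + δ_ijk,     Σ_k δ_ijk = 0,

where `θ_ij` is the component shared by all conditions and `δ_ijk` the
condition-specific (differential) component. An edge supported by several
conditions raises `θ_ij` and thereby borrows strength for the remaining
conditions, without forcing edge *strengths* to agree.

### Sampler

A Gibbs sweep updates, in order:

1. **Precision columns.** For every condition and column `j`, the
   off-diagonal block `β` has a multivariate-normal full conditional
   `N(−C s_12, C)` with `C = ((s_jj + λ_d) Ω11^{-1} + D^{-1})^{-1}`
   (`D` the spike/slab prior variances), and the Schur complement
   `γ = ω_jj − βᵀΩ11^{-1}β` a Gamma`(n/2 + 1, rate (s_jj + λ_d)/2)`
   conditional; `γ > 0` keeps every accepted `Ω_k` positive definite by
   construction.
2. **Indicators.** `z_ijk` is Bernoulli with odds
   `π N(ω; 0, v1²) : (1−π) N(ω; 0, v0²)`, logits clamped to ±30.
3. **Link effects.** Given `z`, `(θ, δ)` receive conjugate Gaussian
   updates via Polya-Gamma augmentation — auxiliaries `PG(1, ψ_ijk)`
   with `ψ = θ + δ` — after which `δ` is re-centered to sum to zero over
   conditions (hard identifiability constraint).

The Polya-Gamma sampler draws the first 200 terms of the infinite
gamma-sum representation exactly and adds the analytic mean of the
truncated tail; the omitted tail variance is `O(n_terms^{-3})`, far below
the Monte Carlo noise of the group-level logit updates. Correctness is
checked in tests against the closed-form mean `tanh(c/2)/(2c)` and the
variance `1/24` at `c = 0`.

Setting the differential prior sd to infinity frees `δ` completely and
yields independent per-condition fits inside the same code path — the
"separate estimation" arm used in comparisons.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `v0` (spike sd) | 0.02 | of the order of the sampling noise of a null partial correlation at n≈2000 standardized rows |
| `v1` (slab sd) | 1.0 | weakly informative for partial correlations of standardized data |
| `λ_d` (diagonal rate) | 1.0 | weak shrinkage; diagonals are likelihood-dominated |
| `θ` prior | N(−2, 1) | prior edge probability ≈ 0.12 at δ = 0: sparse a priori |
| `δ` prior sd | 1.0 | lets a condition deviate by ±2 logits from the shared component |
| edge call | PIP > 0.5 | median-probability model |
| iterations | 2000 / 800 burn-in (pipeline); 3000 / 1000 (recovery test) | trace plateaus within a few hundred sweeps at p ≤ 40 |

Per-iteration sampled structures (the `z` draws) are retained, so every
downstream metric can be evaluated **per iteration**, giving a posterior
distribution of each graph metric rather than a point value.

## Prewhitening

fMRI-like series are temporally autocorrelated; GGMs assume independent
rows. Each node is AR(q)-prewhitened by OLS (default fixed q = 1, AIC
selection up to q = 5 optional), residuals aligned by dropping the first
`max_order` rows of all columns. Each subject's residuals are
column-standardized before stacking so no subject's variance dominates
the pooled scatter matrix. With a scalar AR coefficient the stationary
law's partial-correlation pattern provably equals that of the innovation
precision, so prewhitening preserves the graph being estimated.

## Graph metrics

All metrics are computed on binary adjacency matrices (unweighted), with
hop-count shortest paths:

- **GE** — mean of `1/d_ij` over distinct pairs (`1/∞ = 0`).
- **CPL** — mean `d_ij` over *reachable* pairs only. Dropping
  unreachable pairs (rather than scoring them infinite) keeps posterior
  samples finite on sparse draws; this is the common toolbox convention.
- **MCC** — mean of `2tᵢ/(kᵢ(kᵢ−1))`, zero for degree < 2.
- **LE** — mean over nodes of the GE of the neighbor-induced subgraph.
- **Betweenness** — Brandes; normalized by `(n−1)(n−2)/2`.
- **Participation coefficient** — `1 − Σ_s (k_is/k_i)²` over RSN
  modules; "unknown" nodes count as a module for their neighbors but are
  excluded from cohort averages.
- **Small-worldedness** — `σ = (C/C_rand)/(L/L_rand)` against 20
  degree-preserving Maslov–Sneppen rewirings (10 swap attempts per
  edge), seeded. A complete graph is its own null (σ = 1); nulls with
  zero clustering make σ undefined and are reported as missing.

RSN-level GE/CPL are computed on induced subgraphs; an RSN too small for
a metric is reported as missing, never fabricated (very small modules
give unstable values).

## Node attack

A node is attacked by zeroing its row and column — the node is retained
as an isolated vertex so `n` and the GE denominator stay comparable
across attacks; under the reachable-pairs convention the isolated node
simply drops out of CPL. Percent change is taken against the same
condition's own baseline; rankings order by |percent change|, ties broken
by node id.

## Reproducibility statistics

Hubs are nodes with normalized betweenness strictly above
mean + 1.5 × sample sd (affine-invariant rule; note that for a score
vector with a single nonzero the threshold falls exactly on the outlier,
which the strict inequality excludes). Hub agreement across visits uses
Cohen's kappa, swept over all observed score thresholds (hub = score ≥
threshold); degenerate thresholds give missing values. Nodal-metric
reliability uses the one-way random-effects ICC(1,1) with nodes as
targets and visits as measures; the two-way consistency form ICC(3,1) is
available behind a flag. The one-way form is the conservative choice
when the visit effect cannot be separated from error with two sessions.

## Significance machinery

Global metric differences: equal-tailed credible intervals of the metric
posteriors at a Bonferroni-adjusted level `α/m` (default m = 15: 10
within-cohort visit comparisons + 5 cohort comparisons across 5 metrics);
significance = non-overlap, touching endpoints counting as overlap
(conservative). Note `0.01/15 = 6.67e-4` exactly. Resolving quantiles at
level `α` needs at least `2/α` retained draws; the pipeline falls back to
the finest resolvable level and records it when a run stores fewer.
Nodal metrics use the Wilcoxon signed-rank test (zero differences
dropped; exact null for n ≤ 25 without ties, tie-corrected normal
approximation otherwise). Edge-level differences flag pairs whose
credible interval of the draw-wise partial-correlation difference
excludes zero, reported as a percentage of all pairs.

## Synthetic data: what it emulates, what it does not

The generator plants block-structured sparse precision matrices — RSN
blocks with dense within-block and sparse between-block candidate edges,
a configurable fraction of edges shared by all conditions, the rest
assigned to single conditions — with edge magnitudes 0.2–0.5, Rademacher
signs, and one weight per shared edge across conditions. Positive
definiteness is enforced by diagonal dominance (diagonal = absolute
off-diagonal row sum + 0.1), which preserves the planted zero pattern
exactly, unlike eigenvalue clipping. Subject series follow
`x_t = φ x_{t−1} + ε_t`, `ε_t ~ N(0, Ω^{-1})`, `x_0` stationary, shared
scalar φ (default 0.3, a realistic single-lag autocorrelation for
node-averaged BOLD at typical sampling rates).

Defaults (p = 20 in two blocks of 10, within-density 0.4,
between-density 0.02, shared fraction 0.7, T = 200, 10
subjects/condition) define the study conditions used by the tests and
the acceptance script. Real resting-state data differ in ways the
generator deliberately omits: no subject-level network heterogeneity
(the model is group-level; an optional precision-jitter knob exists for
robustness experiments), no scanner drift, motion, physiological noise,
or hemodynamic convolution, and true effect sizes/densities of brain
networks are unknown — the defaults are chosen for testability, not
fidelity to any particular dataset. Passing tests therefore demonstrate
correctness of the machinery and the statistical benefit of pooling
under the stated assumptions, not performance on real fMRI.

## Numerical choices and degenerate inputs

- Logits clamped at ±30; divergence guard aborts a run if any |ω|
  exceeds 1e6 (indicates misconfigured `v0`/`λ_d` or broken input).
- Scale: the samplers support p = 264 but all shipped experiments use
  p ≤ 40; the problem sizes used by tests and the acceptance script are
  stated inline in each experiment.
- Graphical-lasso arm: `sklearn` coordinate descent with a LARS-mode
  fallback on hard penalties; support tolerance 1e-6 on off-diagonals;
  density matching by bisection on the penalty (density is monotone
  non-increasing in it), bracket `[1e-4, max|S_ij|]`, 50 iterations,
  tolerance 0.5 percentage points.
- Constant input columns, ragged subject matrices, mismatched label
  counts, empty condition lists, and zero-variance columns all raise
  descriptive errors naming the offender.
- Node ids are 0-based in memory and 1-based in every written table.

## Known limitations

- The joint model pools through edge *probabilities* only; edge
  strengths are never shrunk toward each other across conditions.
- With two visits the one-way ICC cannot distinguish a systematic
  session effect from noise.
- The CI-overlap rule is conservative (type-I error well below nominal),
  so borderline real differences may be missed at desk-scale draw
  counts.
- Metric posteriors inherit MCMC autocorrelation; the pipeline thins to
  ~200 stored structures for metric evaluation, which widens quantile
  resolution accordingly.
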