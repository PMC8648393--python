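# Methods

## Entropy model

A sample is a strictly positive expression vector `x` over the nodes of
an undirected, connected PPI graph with adjacency `A` (0/1, zero
diagonal). Mass action assigns edge `(i, j)` the weight `w_ij ∝ x_i x_j`;
row-normalizing the weights at each node gives the transition matrix
`p_ij = x_j / (Ax)_i`. Because the edge flux `λ_i p_ij = A_ij x_i x_j /
(xᵀAx)` is symmetric in `i, j`, the chain satisfies detailed balance and
its stationary distribution has the closed form `λ_i = x_i (Ax)_i /
(xᵀAx)`. The implementation always uses this closed form; the fixed-point
identity `λP = λ` is asserted only in tests. All entropies use natural
logarithms with the convention `0·log 0 = 0`.

The entropy rate `Sr = −Σ_i λ_i Σ_j p_ij log p_ij` is bounded above by
`maxSr = log λ_max(A)`, attained when `x` is the dominant eigenvector of
`A` (the maximal-entropy random walk). The normalized entropy
`SR = Sr / maxSr` therefore lies in `[0, 1]`, is invariant to rescaling
`x` (all formulas are homogeneous of degree 0), and is base-invariant.

**Local entropy normalization.** The per-node contribution
`−λ_i Σ_j p_ij log p_ij` sums to `Sr`, not `SR`. We report LSR divided by
`maxSr`, so that `Σ_i LSR_i = SR` exactly; this makes local entropies
directly comparable across graphs and is the convention assumed by the
downstream analyses. The unnormalized values are available behind the
`raw_lsr` flag. The LSR *ratio* used in the drug analysis
(`LSR_target / SR`) is identical under either convention, since the
`1/maxSr` factor cancels.

**Numerics.** `maxSr` uses a dense symmetric eigensolve for graphs of
≤16 nodes and a Lanczos solve (`scipy.sparse.linalg.eigsh`, all-ones
start vector, tolerance 1e−10) otherwise. The transition matrix is kept
sparse (`diag(1/Ax)·A·diag(x)`); nothing dense of size n×n is ever
materialized for large graphs.

## Preprocessing

- **Network restriction.** The PPI graph is restricted to genes present
  in the expression matrix and reduced to its largest connected
  component; components smaller than 3 nodes are rejected because the
  entropy of a ≤2-node chain carries no information.
- **Zeros.** `p_ij` is undefined if all of a node's neighbors have zero
  expression, so zeros are replaced by a pseudocount — half the smallest
  positive value in the matrix by default, configurable.
- **Proteomic log-ratios.** TMT-style matrices are per-column centered
  and scaled to unit population SD, per-protein median-imputed, and
  mapped to positive masses by `2^v`. The base-2 exponentiation is this
  package's choice for turning signed log-ratios into the positive
  quantities mass action requires; fully missing proteins are dropped.
- **Duplicate gene rows** keep the row with the highest mean — a
  deterministic, widely used rule. Identifier matching is exact string
  match after whitespace stripping; no alias translation is attempted.

## Differential analysis

Per gene, tumor and normal LSR vectors are compared with the classical
pooled-variance two-sample t-test (`df = n_a + n_b − 2`; Welch available
behind a flag) and Cohen's d with the df-weighted pooled unbiased SD.
Positive d means higher in tumor. Genes with BH-FDR `q < 0.05` and
`d > 1` (resp. `d < −1`) are classed up (resp. down); both thresholds
are arguments. Consensus features are genes reaching the same class in
at least `min_types` cohorts. Over-representation uses the
hypergeometric upper tail `P(X ≥ k)` with set membership intersected
with the chosen universe; the universe defaults to the network's node
set when driven from the CLI.

## Survival analysis

Cox proportional-hazards fits use scikit-survival's partial-likelihood
maximizer with Breslow tie handling by default (Efron behind a flag) and
an optional ridge penalty for separated or ill-conditioned designs.
Designs with `p ≥ n` are rejected outright rather than silently
regularized, mirroring the exclusion of cohorts with fewer samples than
features; no variable selection is performed — all supplied features are
kept. Concordance is Harrell's C over comparable pairs with prediction
ties counted 1/2, oriented so that a higher linear predictor means
higher risk. Note that a binary predictor cannot reach C = 1 under this
definition because within-group pairs are prediction ties. Risk groups
split at the median linear predictor with strict inequality for "high"
(all-equal predictors yield an all-low grouping). Kaplan–Meier and
two-group log-rank come from lifelines. A fitted model serializes to
JSON and re-applies to new feature tables as a linear predictor only,
without refitting.

## Drug-response analysis

ln-IC50 (natural log of μM IC50) vectors are binarized per drug by a
two-component Gaussian mixture with the threshold at the equal-posterior
crossing between the component means. The mixture is accepted only when
it beats a single Gaussian by BIC and neither weight falls below 0.05;
otherwise the split falls back to the median and is flagged in the
output. Sensitive means ln-IC50 below the threshold. Per drug, the SR
difference between classes is summarized as Cohen's d
(resistant − sensitive, so negative d means sensitive lines have the
higher entropy) with a two-sided t-test, BH-corrected across drugs.
LSR ratios are correlated with ln-IC50 by Pearson's r, per (drug,
target), optionally within mutant and wild-type strata of the target;
strata with fewer than 3 pairs or numerically zero variance are skipped.

## Synthetic data

The generators emulate the statistical structure the analyses assume,
not any particular cohort:

- **PPI surrogate** — preferential attachment starting from a single
  edge; each new node attaches to `m = 2` existing nodes with
  probability proportional to degree (edge count `1 + m(n−2)`),
  reproducing the heavy-tailed degree distribution of curated PPI
  networks. Default 1000 genes.
- **Expression** — per-gene log-normal baseline (log-mean drawn from
  N(2, 1), sample noise σ = 0.5 on the log scale), matching the
  positivity and skew of RSEM-like abundances. Tumor samples multiply
  planted up-genes by 4 and down-genes by 1/4; defaults are 20 planted
  up-genes and 50 samples per group. The planted truth is returned
  alongside.
- **Survival** — event times exponential with rate `h0·exp(βᵀz)` on
  internally standardized features (`h0 = 0.01`/day), censored by an
  independent uniform time whose upper bound is solved by bisection to
  approximate the configured censoring rate (default 30%).
- **Drug panel** — `ln-IC50 = 2 − 5·ratio + N(0, 0.5)` across ≥10 cell
  lines; the simulated targeted drug is assigned the gene whose LSR
  ratio varies most across the panel, the setting in which a
  target-level readout is informative. A separate helper emits a
  well-separated bimodal panel (modes ±2, σ = 0.5) with known labels for
  exercising the binarization.

Every generator is a pure function of `(config, seed)` via independent
`numpy` PCG64 streams keyed by generator name, so outputs are identical
across runs and platforms.

**What the synthetic data does not model:** tumor purity and stromal
admixture, batch effects, correlated co-expression modules beyond what
the network induces, non-proportional hazards, informative censoring,
and dose–response curve noise. Passing recovery tests therefore
demonstrates correctness of the estimators under their own assumptions,
not robustness to the full messiness of real cohorts.

## Problem sizes and determinism

The test and acceptance runs use the generator defaults above (1000-gene
networks for the differential analysis, 500 samples for coefficient
recovery, 200 samples × 100 replicates for log-rank detection, 100 cell
lines for the drug panel, and a 10⁶-step walk for the Monte Carlo
entropy check) — sizes at which every planted quantity is comfortably
identifiable while a complete run stays in the seconds-to-minutes range
on a single CPU. All randomness flows from explicit seeds; clustering
(k-means restarts) and mixture fits take seeds as arguments.

## Known limitations

- Undirected, unweighted (0/1) interactions only; no edge confidence
  weights or signed/directed signaling.
- Exact-string gene matching; identifier harmonization across naming
  systems is out of scope.
- The Cox model assumes proportional hazards and uses in-sample
  concordance by default; held-out evaluation is available by applying
  a serialized fit to a new table.
- The IC50 binarization is a pragmatic mixture rule, not a re-derivation
  of any screening consortium's exact thresholding procedure; recorded
  thresholds allow externally supplied values to be substituted.
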