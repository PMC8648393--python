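# sigentropy

Signaling entropy of expression-weighted protein–protein interaction
networks, with the differential, survival and drug-response analyses built
on top of it.

## The problem

Tumor development is accompanied by a loss of differentiation and a gain
of stem-like character, which manifests as increased *disorder* in the
cell's signaling network: signals can propagate in more directions, with
less pathway-specific commitment. `sigentropy` quantifies this disorder
as the entropy rate of a random walk on a PPI network whose transition
probabilities are derived from a sample's expression profile by mass
action. It is aimed at computational biologists who want a quantitative,
feature-selection-free network biomarker from bulk or cell-line
expression data.

## The model

Given a connected PPI graph with 0/1 adjacency `A` and a strictly
positive expression vector `x` (one sample), edge weights follow mass
action, `w_ij ∝ x_i·x_j`. Row-normalizing gives the stochastic matrix

    p_ij = x_j / (Ax)_i

whose stationary distribution has the closed form (by detailed balance,
`λ_i p_ij = λ_j p_ji`)

    λ_i = x_i (Ax)_i / (xᵀAx).

The **signaling entropy rate** (natural logs) is

    Sr = − Σ_i λ_i Σ_j p_ij log p_ij

and is normalized by the maximal entropy rate attainable on the graph,
`maxSr = log λ_max(A)` (the maximal-entropy random walk), to give

    SR = Sr / maxSr ∈ [0, 1].

Each node's contribution, `LSR_i = − λ_i Σ_j p_ij log p_ij / maxSr`, is
the **local signaling entropy**; the LSRs sum to SR.

Downstream analyses:

- **Differential LSR (DLSR)** — per-gene tumor-vs-normal comparison by
  two-sided Student's t-test with BH-FDR and Cohen's d; genes with
  `q < 0.05` and `|d| > 1` are classed up/down, with consensus feature
  selection across cohorts and hypergeometric over-representation against
  GMT gene sets.
- **Survival** — multivariate Cox proportional hazards on LSR features
  (Breslow ties, optional ridge), Harrell's C-index, median split of the
  log relative hazard into high/low risk, Kaplan–Meier and log-rank.
- **Drug response** — per-drug sensitive/resistant binarization of
  ln-IC50 (Gaussian-mixture threshold with median fallback), SR effect
  sizes between response classes, and Pearson correlation of the
  **LSR ratio** (target LSR / SR) with ln-IC50, optionally stratified by
  target mutation status.
- **Synthesis** — seeded generators for a preferential-attachment PPI
  surrogate, two-group expression with planted differential genes,
  survival with a log-linear hazard, and ln-IC50 panels coupled to an
  LSR ratio, each emitting its ground truth.

## Worked example

The triangle graph K3 with expression `x = (1, 2, 3)`:

```python
>>> import numpy as np, pandas as pd
>>> from sigentropy import *
>>> edges = EdgeList([("a", "b"), ("a", "c"), ("b", "c")])
>>> expr = ExpressionMatrix(pd.DataFrame({"s1": [1., 2., 3.]},
...                                      index=["a", "b", "c"]), LINEAR)
>>> net = build_network(edges, expr)
>>> prof = entropy_profile(np.array([1., 2., 3.]), net)
>>> round(prof.sr, 4)
0.8913
>>> [round(v, 4) for v in prof.lsr]
[0.2207, 0.295, 0.3757]
>>> round(prof.lsr[2] / prof.sr, 4)
0.4215
```

Here `maxSr = ln 2` (the dominant eigenvalue of K3's adjacency is 2), the
stationary distribution is `λ = (5, 8, 9)/22`, and the walk attains 89.1%
of the maximal entropy rate. Gene `c`, the most expressed node,
contributes the largest local entropy (0.3757) and would carry an LSR
ratio of 0.4215 if it were a drug target.

A command-line entry point `sigentropy` wraps the same functionality
(`sigentropy sr`, `dlsr`, `ora`, `cluster`, `survival`, `drug`,
`simulate`); every command writes TSV outputs with a provenance header
and a `manifest.json`.

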