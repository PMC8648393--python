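"""Synthetic data generators with the statistical structure the analyses
assume.

Stands in for the pan-cancer cohorts, proteome panels and cell-line drug
screens the real pipeline consumes: a degree-heterogeneous (preferential
attachment) PPI surrogate, two-group log-normal expression with planted
up/down genes, survival times whose hazard is log-linear in chosen LSR
features, and ln-IC50 values linearly coupled to an LSR ratio with
Gaussian noise.  Every generator is a pure function of its config and
seed, and emits the ground truth needed by recovery tests.

Defaults mirror the planted study conditions used throughout the test
suite: 1000 genes, 20 planted up-regulated genes at multiplicative effect
4, 50 tumor and 50 normal samples, log-normal noise sigma 0.5; survival
coefficient 0.8 with ~30% censoring; drug panel ln-IC50 = 2 - 5·ratio +
N(0, 0.5) over 100 cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netio import LINEAR, EdgeList, ClinicalTable, ExpressionMatrix

_SEED_MOD = 2**31 - 1


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults are the planted study conditions."""

    seed: int = 0
    n_genes: int = 1000
    attachment_m: int = 2
    n_tumor: int = 50
    n_normal: int = 50
    n_up: int = 20
    n_down: int = 0
    effect: float = 4.0
    expression_sigma: float = 0.5
    survival_coefs: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.01
    censoring: float = 0.3
    drug_intercept: float = 2.0
    drug_slope: float = 5.0
    drug_noise: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tumor, self.n_normal) <= 0:
            raise ValueError("counts must be positive")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if not 0 <= self.censoring < 1:
            raise ValueError("censoring must lie in [0, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, portable PRNG stream per generator."""
        return np.random.default_rng(
            [self.seed % _SEED_MOD, abs(hash_stream(stream)) % _SEED_MOD])


def hash_stream(name: str) -> int:
    """Stable (platform-independent) small hash for stream names."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % _SEED_MOD
    return h


def simulate_ppi(config: SimulationConfig) -> EdgeList:
    """Connected preferential-attachment graph.

    Starts from a single edge g0-g1; every subsequent node attaches to
    ``attachment_m`` distinct existing nodes chosen with probability
    proportional to degree.  With m=1 the result is a tree; in general the
    edge count is 1 + m·(n - 2).
    """
    n, m = config.n_genes, config.attachment_m
    if n < 10:
        raise ValueError("need at least 10 genes")
    if m < 1:
        raise ValueError("attachment parameter must be >= 1")
    rng = config.rng("ppi")
    names = [f"g{i}" for i in range(n)]
    degree = np.zeros(n)
    edges: list[tuple[str, str]] = [(names[0], names[1])]
    degree[:2] = 1
    for new in range(2, n):
        k = min(m, new)
        probs = degree[:new] / degree[:new].sum()
        partners = rng.choice(new, size=k, replace=False, p=probs)
        for p in partners:
            edges.append((names[new], names[int(p)]))
            degree[int(p)] += 1
        degree[new] = k
    return EdgeList(edges)


def simulate_expression(net_genes: list[str], config: SimulationConfig,
                        ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-group log-normal expression with planted differential genes.

    The first ``n_up`` genes are multiplied by ``effect`` and the next
    ``n_down`` by 1/effect in tumor samples only.  Returns the matrix and
    a truth table recording each gene's planted class.
    """
    if config.n_up + config.n_down > len(net_genes):
        raise ValueError("more planted genes than network genes")
    up = list(net_genes[:config.n_up])
    down = list(net_genes[config.n_up:config.n_up + config.n_down])
    if set(up) & set(down):
        raise ValueError("up and down gene lists overlap")
    rng = config.rng("expression")
    n_genes = len(net_genes)
    n_t, n_n = config.n_tumor, config.n_normal
    base_mu = rng.normal(2.0, 1.0, size=n_genes)  # per-gene log-mean
    log_expr = (base_mu[:, None]
                + rng.normal(0.0, config.expression_sigma,
                             size=(n_genes, n_t + n_n)))
    expr = np.exp(log_expr)
    gene_index = pd.Index(net_genes, name="gene")
    up_mask = gene_index.isin(up)
    down_mask = gene_index.isin(down)
    expr[up_mask, :n_t] *= config.effect
    expr[down_mask, :n_t] /= config.effect
    samples = ([f"tumor_{i}" for i in range(n_t)]
               + [f"normal_{i}" for i in range(n_n)])
    df = pd.DataFrame(expr, index=gene_index, columns=samples)
    truth = pd.DataFrame({"class": np.where(up_mask, "up",
                                            np.where(down_mask, "down",
                                                     "none"))},
                         index=gene_index)
    return ExpressionMatrix(df, LINEAR), truth


def simulate_survival(features: pd.DataFrame, config: SimulationConfig,
                      ) -> tuple[ClinicalTable, pd.Series]:
    """Exponential survival with hazard h0·exp(βᵀz) on standardized
    features, plus independent uniform censoring approximating the
    configured censoring rate.

    ``survival_coefs`` maps feature names to true coefficients; unnamed
    features get coefficient 0.  Returns the clinical table and the true
    β on the standardized scale.
    """
    rng = config.rng("survival")
    beta = pd.Series(0.0, index=features.columns)
    for name, b in config.survival_coefs.items():
        if name not in beta.index:
            raise ValueError(f"unknown survival feature {name!r}")
        beta[name] = b
    z = (features - features.mean()) / features.std(ddof=0).replace(0.0, 1.0)
    lp = z.to_numpy(float) @ beta.to_numpy()
    rate = config.baseline_hazard * np.exp(lp)
    times = rng.exponential(1.0 / rate)
    if config.censoring > 0:
        upper = _censor_upper(times, config.censoring)
        cens = rng.uniform(0.0, upper, size=len(times))
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    else:
        event = np.ones(len(times), dtype=int)
        obs = times
    obs = np.maximum(obs, 1e-8)  # clinical table requires positive times
    clin = pd.DataFrame({"time": obs, "event": event}, index=features.index)
    return ClinicalTable(clin), beta


def _censor_upper(times: np.ndarray, target: float) -> float:
    """Upper bound u for Uniform(0, u) censoring such that the expected
    censored fraction E[min(t/u, 1)] matches ``target`` (bisection)."""
    lo, hi = float(times.min()) * 1e-3, float(times.max()) * 1e3
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        frac = float(np.minimum(times / mid, 1.0).mean())
        if frac > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_drug_panel(ratio: pd.Series, config: SimulationConfig,
                        drug: str = "drug_1") -> pd.DataFrame:
    """ln-IC50 panel linearly coupled to an LSR ratio:
    ln-IC50 = intercept − slope·ratio + N(0, noise), one column per drug."""
    if len(ratio) < 10:
        raise ValueError("need at least 10 cell lines")
    rng = config.rng("drug")
    noise = rng.normal(0.0, config.drug_noise, size=len(ratio))
    ic50 = (config.drug_intercept - config.drug_slope * ratio.to_numpy(float)
            + noise)
    return pd.DataFrame({drug: ic50}, index=ratio.index)


def simulate_bimodal_ic50(n_per_mode: int = 100, mu_sensitive: float = -2.0,
                          mu_resistant: float = 2.0, sigma: float = 0.5,
                          seed: int = 0) -> tuple[pd.Series, pd.Series]:
    """Well-separated bimodal ln-IC50 panel with known component labels,
    for exercising the mixture binarization."""
    rng = np.random.default_rng(seed % _SEED_MOD)
    sens = rng.normal(mu_sensitive, sigma, size=n_per_mode)
    res = rng.normal(mu_resistant, sigma, size=n_per_mode)
    idx = pd.Index([f"line_{i}" for i in range(2 * n_per_mode)])
    values = pd.Series(np.concatenate([sens, res]), index=idx, name="drug")
    truth = pd.Series(["sensitive"] * n_per_mode + ["resistant"] * n_per_mode,
                      index=idx, name="label")
    return values, truth
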