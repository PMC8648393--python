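"""Differential local signaling entropy (DLSR) and over-representation.

Per-gene tumor-vs-normal comparison of LSR by two-sided Student's t-test
with Benjamini-Hochberg FDR and Cohen's d; a gene is classed ``up`` when
q < 0.05 and d > 1, ``down`` when q < 0.05 and d < -1 (thresholds
configurable).  Consensus features are genes sharing a class across a
minimum number of cancer types.  Over-representation of a selected gene
list in user-supplied gene sets uses the hypergeometric upper tail.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netio import GeneSetCollection

logger = logging.getLogger("sigentropy")


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d = (mean(a) - mean(b)) / pooled SD (unbiased variances
    weighted by degrees of freedom).  Zero pooled SD yields 0 with a
    warning."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        logger.warning("zero pooled SD in cohens_d; returning 0")
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def ttest_two_sided(a: np.ndarray, b: np.ndarray,
                    welch: bool = False) -> tuple[float, float]:
    """Classic two-sample t-test (pooled variance, df = n_a + n_b - 2);
    Welch's correction behind a flag.  Degenerate zero-variance input with
    equal means gives (0, 1)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(t):
        return 0.0, 1.0
    return float(t), float(p)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def dlsr(lsr_tumor: pd.DataFrame, lsr_normal: pd.DataFrame,
         q_max: float = 0.05, d_min: float = 1.0,
         welch: bool = False) -> pd.DataFrame:
    """Differential LSR table between tumor and normal sample groups.

    Both inputs are genes × samples on a shared gene index.  Returns one
    row per gene: group means, t, p, q, Cohen's d (tumor minus normal) and
    class in {up, down, none}.
    """
    if not lsr_tumor.index.equals(lsr_normal.index):
        raise ValueError("tumor and normal LSR tables must share gene order")
    if lsr_tumor.shape[1] < 2 or lsr_normal.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    a = lsr_tumor.to_numpy(float)
    b = lsr_normal.to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    pooled_var = (((na - 1) * a.var(axis=1, ddof=1)
                   + (nb - 1) * b.var(axis=1, ddof=1)) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(pooled_var)
    d = np.nan_to_num(d, nan=0.0, posinf=0.0, neginf=0.0)
    q = bh_fdr(p)
    cls = np.full(a.shape[0], "none", dtype=object)
    cls[(q < q_max) & (d > d_min)] = "up"
    cls[(q < q_max) & (d < -d_min)] = "down"
    out = pd.DataFrame({
        "mean_tumor": a.mean(axis=1), "mean_normal": b.mean(axis=1),
        "t": t, "p": p, "q": q, "cohens_d": d, "class": cls,
    }, index=lsr_tumor.index)
    counts = out["class"].value_counts()
    logger.info("DLSR classes: up=%d down=%d none=%d",
                counts.get("up", 0), counts.get("down", 0), counts.get("none", 0))
    return out


def consensus_features(tables: dict[str, pd.DataFrame],
                       min_types: int) -> tuple[list[str], list[str], pd.DataFrame]:
    """Genes classed up (resp. down) in at least ``min_types`` DLSR tables.

    Returns (up, down, membership) where membership records the per-type
    class for every gene that reaches the threshold in either direction.
    """
    if not tables:
        raise ValueError("at least one DLSR table required")
    classes = pd.DataFrame({name: tab["class"] for name, tab in tables.items()})
    classes = classes.fillna("none")
    n_up = (classes == "up").sum(axis=1)
    n_down = (classes == "down").sum(axis=1)
    up = sorted(n_up.index[n_up >= min_types])
    down = sorted(n_down.index[n_down >= min_types])
    if not up and not down:
        logger.info("consensus_features: no gene reaches min_types=%d", min_types)
    keep = sorted(set(up) | set(down))
    return up, down, classes.loc[keep]


def ora(selected: set[str], universe: set[str],
        sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` within each gene
    set, membership intersected with ``universe``; BH correction across
    sets."""
    selected = set(selected)
    universe = set(universe)
    if not selected:
        raise ValueError("selected gene set is empty")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    M, N = len(universe), len(selected)
    rows = []
    for name, members in sets.sets.items():
        in_universe = members & universe
        n = len(in_universe)
        k = len(in_universe & selected)
        # upper tail: P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append({"set": name, "overlap": k, "set_size": n,
                     "selected_size": N, "universe_size": M, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p")
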