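"""Signaling-entropy core: transition model, entropy rate and local entropy.

A sample's expression vector x weights the edges of the PPI graph by mass
action, w_ij ∝ x_i x_j.  Row-normalizing the weights gives the stochastic
matrix

    p_ij = x_j / (Ax)_i          (A the 0/1 adjacency)

whose stationary distribution has the closed form

    λ_i = x_i (Ax)_i / (xᵀ A x)

by detailed balance (λ_i p_ij = A_ij x_i x_j / xᵀAx is symmetric in i,j).
The entropy rate of the walk,

    Sr = −Σ_i λ_i Σ_j p_ij log p_ij      (natural log),

is normalized by the maximal entropy rate attainable on the graph,
maxSr = log λ_max(A) (the maximal-entropy random walk), giving the
signaling entropy SR = Sr / maxSr ∈ [0, 1].  The per-node contribution
−λ_i Σ_j p_ij log p_ij, divided by maxSr, is the local signaling entropy
LSR_i, so that Σ_i LSR_i = SR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .netio import ExpressionMatrix, SignalingNetwork, apply_pseudocount

logger = logging.getLogger("sigentropy")


@dataclass
class TransitionModel:
    """Row-stochastic matrix P and invariant measure λ for one sample."""

    P: sp.csr_matrix
    stationary: np.ndarray  # λ, sums to 1
    x: np.ndarray           # the expression vector used

    def local_entropies(self) -> np.ndarray:
        """−Σ_j p_ij log p_ij per node (nats); 0·log 0 ≡ 0."""
        plogp = self.P.copy()
        plogp.data = plogp.data * np.log(plogp.data)
        return -np.asarray(plogp.sum(axis=1)).ravel()


@dataclass
class EntropyProfile:
    """Global and local signaling entropy of one sample."""

    sample: str
    sr_raw: float              # Sr, nats
    max_sr: float              # maxSr, nats
    sr: float                  # SR = Sr/maxSr, in [0, 1]
    lsr: np.ndarray            # normalized: Σ lsr = SR
    lsr_raw: np.ndarray        # unnormalized: Σ lsr_raw = Sr
    nodes: list[str]

    def lsr_series(self, raw: bool = False) -> pd.Series:
        return pd.Series(self.lsr_raw if raw else self.lsr, index=self.nodes,
                         name=self.sample)


def transition_model(x: np.ndarray, net: SignalingNetwork) -> TransitionModel:
    """Build P and λ from a strictly positive expression vector.

    Sparse throughout: P shares the adjacency sparsity pattern, and λ uses
    the closed form rather than solving λP = λ.
    """
    x = np.asarray(x, float).ravel()
    if x.shape[0] != net.n_nodes:
        raise ValueError("expression vector length does not match node count")
    if not (x > 0).all():
        raise ValueError("expression vector must be strictly positive "
                         "(apply a pseudocount first)")
    A = net.adjacency
    ax = A @ x
    if not (ax > 0).all():
        raise ValueError("a node has zero neighbor mass; network not connected?")
    # p_ij = A_ij x_j / (Ax)_i  ==  diag(1/Ax) · A · diag(x)
    P = sp.diags(1.0 / ax) @ A @ sp.diags(x)
    P = sp.csr_matrix(P)
    lam = x * ax
    lam /= lam.sum()
    return TransitionModel(P=P, stationary=lam, x=x)


def max_entropy_rate(net: SignalingNetwork, tol: float = 1e-10) -> float:
    """maxSr = natural log of the dominant adjacency eigenvalue.

    Uses a sparse Lanczos solve seeded with the all-ones vector; tiny
    graphs fall back to a dense eigendecomposition.
    """
    A = net.adjacency
    n = net.n_nodes
    if n <= 16:
        lam_max = float(np.linalg.eigvalsh(A.toarray())[-1])
    else:
        try:
            vals = spla.eigsh(A, k=1, which="LA", v0=np.ones(n), tol=tol,
                              maxiter=50 * n, return_eigenvectors=False)
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(
                "dominant eigenvalue did not converge; retry with a larger "
                "tol or maxiter") from exc
        lam_max = float(vals[0])
    if lam_max <= 0:
        raise ValueError("non-positive dominant eigenvalue (degenerate graph)")
    return float(np.log(lam_max))


def entropy_profile(x: np.ndarray, net: SignalingNetwork,
                    sample: str = "sample",
                    max_sr: float | None = None) -> EntropyProfile:
    """Compute Sr, maxSr, SR and the LSR vector for one sample."""
    if max_sr is None:
        max_sr = max_entropy_rate(net)
    tm = transition_model(x, net)
    local = tm.local_entropies()          # −Σ_j p_ij log p_ij
    lsr_raw = tm.stationary * local
    sr_raw = float(lsr_raw.sum())
    sr = sr_raw / max_sr
    return EntropyProfile(sample=sample, sr_raw=sr_raw, max_sr=max_sr, sr=sr,
                          lsr=lsr_raw / max_sr, lsr_raw=lsr_raw,
                          nodes=net.nodes)


def entropy_matrix(m: ExpressionMatrix, net: SignalingNetwork,
                   pseudocount: float | str = "auto",
                   raw_lsr: bool = False,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample entropy profiles for a whole expression matrix.

    Returns ``(summary, lsr)``: summary has one row per sample with columns
    ``Sr``, ``maxSr``, ``SR``; lsr is genes × samples (normalized unless
    ``raw_lsr``).  Per-sample failures are collected and reported together.
    """
    if m.scale != "linear-nonnegative":
        raise ValueError("entropy_matrix expects a linear-nonnegative matrix "
                         "(preprocess log-ratio data first)")
    sub = m.values.loc[net.nodes]
    sub = apply_pseudocount(sub, pseudocount)
    max_sr = max_entropy_rate(net)
    rows, lsr_cols, failures = [], {}, []
    for k, sample in enumerate(sub.columns):
        try:
            prof = entropy_profile(sub[sample].to_numpy(), net,
                                   sample=str(sample), max_sr=max_sr)
        except Exception as exc:  # collected, reported once
            failures.append((sample, str(exc)))
            continue
        rows.append({"sample": str(sample), "Sr": prof.sr_raw,
                     "maxSr": prof.max_sr, "SR": prof.sr})
        lsr_cols[str(sample)] = prof.lsr_raw if raw_lsr else prof.lsr
        if (k + 1) % 200 == 0:
            logger.info("entropy: %d/%d samples done", k + 1, sub.shape[1])
    if failures:
        listing = "; ".join(f"{s}: {msg}" for s, msg in failures[:10])
        raise RuntimeError(f"entropy failed for {len(failures)} samples: {listing}")
    summary = pd.DataFrame(rows).set_index("sample")
    lsr = pd.DataFrame(lsr_cols, index=net.nodes)
    return summary, lsr


def simulate_walk_entropy(tm: TransitionModel, n_steps: int,
                          rng: np.random.Generator) -> float:
    """Empirical per-step entropy of a simulated walk started from λ.

    Independent Monte Carlo check of the analytic entropy rate: averages
    −log p_{s_t, s_{t+1}} over a stationary trajectory.  Intended for tiny
    graphs only (the step loop is plain Python).
    """
    P = tm.P.toarray()
    cum = np.cumsum(P, axis=1)
    logp = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    state = int(rng.choice(len(tm.stationary), p=tm.stationary))
    u = rng.random(n_steps)
    total = 0.0
    for t in range(n_steps):
        nxt = int(np.searchsorted(cum[state], u[t]))
        total -= logp[state, nxt]
        state = nxt
    return total / n_steps
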