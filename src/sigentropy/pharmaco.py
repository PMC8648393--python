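"""Drug-response analysis with signaling entropy.

Cell lines are binarized into sensitive/resistant per drug on ln-IC50
(natural log of the half-maximal inhibitory concentration in μM) with a
two-component Gaussian-mixture threshold at equal posterior (median
fallback for unimodal panels).  Per drug, the SR difference between
resistant and sensitive lines is summarized by Cohen's d (positive d =
higher SR in resistant lines) with a two-sided t-test.  For targeted
drugs, the LSR ratio — the target gene's LSR divided by the sample's
total SR — is correlated with ln-IC50 by Pearson's r, optionally
stratified by target mutation status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .differential import bh_fdr, cohens_d, ttest_two_sided

logger = logging.getLogger("sigentropy")


@dataclass
class Binarization:
    """Per-drug ln-IC50 threshold and sensitive/resistant labels."""

    threshold: float
    labels: pd.Series  # cell line -> "sensitive" | "resistant"
    method: str        # "gmm" | "median"


def binarize_ic50(ic50: pd.Series, seed: int = 0) -> Binarization:
    """Split a drug's ln-IC50 vector into sensitive (< threshold) and
    resistant cell lines.

    Default: fit a two-component Gaussian mixture and place the threshold
    where the two posteriors are equal between the component means.  When
    the mixture is not supported by the data (one component fits better by
    BIC, or a component vanishes), fall back to the median and flag it.
    """
    vals = ic50.dropna()
    if len(vals) < 10:
        raise ValueError("need at least 10 non-missing IC50 values")
    arr = vals.to_numpy(float)
    if np.ptp(arr) == 0:
        raise ValueError("degenerate IC50 vector (all values identical)")
    col = arr.reshape(-1, 1)
    gmm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gmm.fit(col)
    single = GaussianMixture(n_components=1, random_state=seed).fit(col)
    means = gmm.means_.ravel()
    weights = gmm.weights_.ravel()
    lo, hi = np.sort(means)
    separated = gmm.bic(col) < single.bic(col) and weights.min() > 0.05
    if separated:
        grid = np.linspace(lo, hi, 2001)
        post = gmm.predict_proba(grid.reshape(-1, 1))
        lo_comp = int(np.argmin(means))
        crossing = np.where(np.diff(np.sign(post[:, lo_comp] - 0.5)))[0]
        if len(crossing):
            threshold = float(grid[crossing[0]])
            method = "gmm"
        else:
            separated = False
    if not separated:
        threshold = float(np.median(arr))
        method = "median"
        logger.info("IC50 binarization for %s fell back to median split",
                    ic50.name or "drug")
    labels = pd.Series(np.where(arr < threshold, "sensitive", "resistant"),
                       index=vals.index, name="label")
    return Binarization(threshold=threshold, labels=labels, method=method)


def sr_drug_effect(sr: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Cohen's d of SR between resistant and sensitive lines (positive d =
    higher SR in resistant lines) with a two-sided t-test p-value."""
    shared = sr.index.intersection(labels.index)
    res = sr.loc[shared[labels.loc[shared] == "resistant"]].to_numpy()
    sen = sr.loc[shared[labels.loc[shared] == "sensitive"]].to_numpy()
    if len(res) < 2 or len(sen) < 2:
        raise ValueError("need at least 2 cell lines per response class")
    d = cohens_d(res, sen)
    _, p = ttest_two_sided(res, sen)
    return d, p


def sr_drug_effect_panel(sr: pd.Series, ic50: pd.DataFrame,
                         seed: int = 0) -> pd.DataFrame:
    """Per-drug SR effect sizes across a cell line × drug ln-IC50 panel.

    Drugs whose binarization or effect computation fails (too few lines in
    a class) are skipped with a warning; p-values are BH-adjusted across
    the drugs that were scored.
    """
    rows = []
    for drug in ic50.columns:
        try:
            b = binarize_ic50(ic50[drug], seed=seed)
            d, p = sr_drug_effect(sr, b.labels)
        except ValueError as exc:
            logger.warning("skipping drug %s: %s", drug, exc)
            continue
        rows.append({"drug": drug, "cohens_d": d, "p": p,
                     "threshold": b.threshold, "method": b.method})
    out = pd.DataFrame(rows).set_index("drug")
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def lsr_ratio(lsr: pd.DataFrame, sr: pd.Series,
              targets: dict[str, list[str]],
              ) -> tuple[pd.DataFrame, list[str]]:
    """LSR ratio = target LSR / total SR per (cell line, drug, target).

    ``lsr`` is genes × cell lines (normalized LSR), ``sr`` the per-line SR,
    ``targets`` maps each drug to its target genes.  Targets absent from
    the network are returned separately, not scored.
    """
    if (sr <= 0).any():
        raise ValueError("SR must be strictly positive")
    rows = []
    unmapped: list[str] = []
    lines = lsr.columns.intersection(sr.index)
    for drug, genes in targets.items():
        for gene in genes:
            if gene not in lsr.index:
                unmapped.append(f"{drug}:{gene}")
                continue
            ratio = (lsr.loc[gene, lines] / sr.loc[lines]).astype(float)
            for line, r in ratio.items():
                rows.append({"cell_line": line, "drug": drug,
                             "target": gene, "lsr_ratio": float(r)})
    if unmapped:
        logger.warning("unmapped drug targets: %s", ", ".join(unmapped))
    scores = pd.DataFrame(rows, columns=["cell_line", "drug", "target",
                                         "lsr_ratio"])
    if not scores.empty and ((scores["lsr_ratio"] < 0).any()
                             or (scores["lsr_ratio"] > 1).any()):
        raise AssertionError("LSR ratio outside [0, 1]")
    return scores, unmapped


def ratio_ic50_correlation(scores: pd.DataFrame, ic50: pd.DataFrame,
                           mutations: pd.DataFrame | None = None,
                           ) -> pd.DataFrame:
    """Pearson correlation of LSR ratio with ln-IC50 per (drug, target).

    With a mutation table (cell line × gene, 0/1) each (drug, target) is
    additionally stratified into mutant and wild-type cell lines.  Strata
    with fewer than 3 pairs or zero variance are skipped with a warning.
    """
    rows = []
    for (drug, target), grp in scores.groupby(["drug", "target"]):
        if drug not in ic50.columns:
            continue
        sub = grp.set_index("cell_line")["lsr_ratio"]
        strata: list[tuple[str, pd.Index]] = [("all", sub.index)]
        if mutations is not None and target in mutations.columns:
            mut = mutations[target].reindex(sub.index)
            strata += [("mutant", sub.index[mut == 1]),
                       ("wild-type", sub.index[mut == 0])]
        for name, lines in strata:
            paired = pd.concat([sub.loc[lines],
                                ic50.loc[lines.intersection(ic50.index), drug]],
                               axis=1, join="inner").dropna()
            if paired.shape[0] < 3:
                logger.warning("%s/%s stratum %s: <3 pairs, skipped",
                               drug, target, name)
                continue
            x = paired.iloc[:, 0].to_numpy(float)
            y = paired.iloc[:, 1].to_numpy(float)
            if (x.std() <= 1e-12 * max(1.0, abs(x.mean()))
                    or y.std() <= 1e-12 * max(1.0, abs(y.mean()))):
                logger.warning("%s/%s stratum %s: zero variance, skipped",
                               drug, target, name)
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"drug": drug, "target": target, "stratum": name,
                         "n": paired.shape[0], "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows, columns=["drug", "target", "stratum", "n",
                                      "r", "p"])
    if not out.empty:
        sig = out[out["p"] < 0.05]
        logger.info("ratio-IC50: %d significant negative, %d significant "
                    "positive of %d correlations",
                    int((sig["r"] < 0).sum()), int((sig["r"] > 0).sum()),
                    len(out))
    return out
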