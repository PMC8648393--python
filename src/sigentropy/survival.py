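"""Cox survival modelling on LSR features.

A single multivariate Cox proportional-hazards model is fitted on a
feature table (typically the consensus LSR features), evaluated by
Harrell's concordance index, and applied to samples by median split of
the linear predictor (log relative hazard) into high- and low-risk
groups compared with Kaplan-Meier curves and the log-rank test.  The
fitted model is serializable and re-appliable to new feature tables
without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .netio import ClinicalTable


@dataclass
class CoxFit:
    """Fitted Cox model: coefficients, per-sample risk and concordance."""

    features: list[str]
    coef: np.ndarray                 # log hazard ratios
    linear_predictor: pd.Series      # per-sample log relative hazard
    c_index: float
    ties: str = "breslow"
    ridge: float = 0.0
    n_samples: int = 0
    n_events: int = 0

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def apply(self, features: pd.DataFrame) -> pd.Series:
        """Linear predictor on a new feature table (no refit)."""
        missing = [f for f in self.features if f not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing[:5]}")
        lp = features[self.features].to_numpy(float) @ self.coef
        return pd.Series(lp, index=features.index, name="linear_predictor")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": self.features,
            "coef": self.coef.tolist(),
            "c_index": self.c_index,
            "ties": self.ties,
            "ridge": self.ridge,
            "n_samples": self.n_samples,
            "n_events": self.n_events,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoxFit":
        payload = json.loads(Path(path).read_text())
        return cls(features=payload["features"],
                   coef=np.asarray(payload["coef"], float),
                   linear_predictor=pd.Series(dtype=float),
                   c_index=payload["c_index"], ties=payload["ties"],
                   ridge=payload["ridge"], n_samples=payload["n_samples"],
                   n_events=payload["n_events"])


@dataclass
class RiskGroups:
    """High/low risk assignment split at the median linear predictor."""

    groups: pd.Series  # sample -> "high" | "low"
    split_value: float

    def samples(self, which: str) -> pd.Index:
        return self.groups.index[self.groups == which]


def fit_cox(features: pd.DataFrame, clinical: ClinicalTable,
            ties: str = "breslow", ridge: float = 0.0) -> CoxFit:
    """Maximize the Cox partial likelihood on aligned samples.

    Breslow tie handling by default (Efron behind ``ties="efron"``), with
    an optional ridge penalty for stability.  Models with at least as many
    features as samples are rejected outright, mirroring the exclusion of
    cohorts with n <= p.
    """
    shared = features.index.intersection(clinical.data.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between features and clinical data")
    X = features.loc[shared]
    n, p = X.shape
    if p >= n:
        raise ValueError(
            f"p={p} features >= n={n} samples; such cohorts are excluded "
            "(reduce features or add samples)")
    clin = clinical.data.loc[shared]
    y = Surv.from_arrays(event=clin["event"].astype(bool),
                         time=clin["time"].astype(float))
    model = CoxPHSurvivalAnalysis(alpha=ridge, ties=ties)
    try:
        model.fit(X.to_numpy(float), y)
    except Exception as exc:
        raise RuntimeError(
            "Cox fit did not converge; consider a ridge penalty "
            "(ridge > 0)") from exc
    coef = np.asarray(model.coef_, float)
    lp = pd.Series(X.to_numpy(float) @ coef, index=shared,
                   name="linear_predictor")
    c = concordance_index(lp.to_numpy(), ClinicalTable(clin))
    return CoxFit(features=list(X.columns), coef=coef, linear_predictor=lp,
                  c_index=c, ties=ties, ridge=ridge, n_samples=n,
                  n_events=int(clin["event"].sum()))


def concordance_index(lp: np.ndarray, clinical: ClinicalTable) -> float:
    """Harrell's C over comparable pairs, higher lp meaning higher risk
    (earlier expected event); tied predictions count 1/2."""
    lp = np.asarray(lp, float)
    time = clinical.time
    event = clinical.event
    if lp.shape[0] != time.shape[0]:
        raise ValueError("linear predictor and clinical table misaligned")
    # lifelines scores concordance of predicted survival times (higher =
    # longer survival), so negate the risk score
    try:
        return float(_lifelines_cindex(time, -lp, event))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs for concordance") from exc


def median_split(fit: CoxFit) -> RiskGroups:
    """High risk = linear predictor strictly greater than the median."""
    lp = fit.linear_predictor
    if lp.empty:
        raise ValueError("fit carries no per-sample linear predictor")
    med = float(lp.median())
    groups = pd.Series(np.where(lp > med, "high", "low"), index=lp.index,
                       name="risk_group")
    return RiskGroups(groups=groups, split_value=med)


def km_curve(samples: pd.Index, clinical: ClinicalTable,
             label: str = "group") -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate for one group of samples."""
    if len(samples) == 0:
        raise ValueError("empty group for Kaplan-Meier estimate")
    clin = clinical.data.loc[samples]
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(clin["time"], clin["event"])
    out = kmf.survival_function_.reset_index()
    out.columns = ["time", "survival"]
    return out


def logrank(groups: RiskGroups, clinical: ClinicalTable) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) between high and low risk."""
    high = groups.samples("high")
    low = groups.samples("low")
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both risk groups must be non-empty")
    ch = clinical.data.loc[high]
    cl = clinical.data.loc[low]
    if ch["event"].sum() == 0 and cl["event"].sum() == 0:
        raise ValueError("no events in either arm")
    res = logrank_test(ch["time"], cl["time"], ch["event"], cl["event"])
    return float(res.test_statistic), float(res.p_value)
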