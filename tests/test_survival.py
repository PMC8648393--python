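"""Cox modelling, concordance, risk splitting and group comparison."""

import numpy as np
import pandas as pd
import pytest

from sigentropy import (
    ClinicalTable,
    CoxFit,
    RiskGroups,
    SimulationConfig,
    concordance_index,
    fit_cox,
    km_curve,
    logrank,
    median_split,
    simulate_survival,
)


def clinical(times, events, index=None) -> ClinicalTable:
    index = index or [f"s{i}" for i in range(len(times))]
    return ClinicalTable(pd.DataFrame({"time": times, "event": events},
                                      index=index))


class TestFitCox:
    def test_perfectly_ordering_feature(self):
        # a feature that perfectly anti-orders the event times gives a
        # positive coefficient and perfect concordance; a small ridge
        # keeps the otherwise-divergent (separated) fit finite
        feats = pd.DataFrame({"z": [6, 5, 4, 3, 2, 1.0]},
                             index=[f"s{i}" for i in range(6)])
        clin = clinical([1, 2, 3, 10, 11, 12], [1] * 6,
                        index=list(feats.index))
        fit = fit_cox(feats, clin, ridge=0.1)
        assert fit.coef[0] > 0
        assert fit.c_index == pytest.approx(1.0)

    def test_binary_risk_factor_concordance(self):
        # carriers all fail before non-carriers: positive coefficient;
        # within-group prediction ties earn 1/2, so Harrell's C on the
        # 6-sample design is (9 + 6·0.5)/15 = 0.8
        feats = pd.DataFrame({"z": [1, 1, 1, 0, 0, 0]},
                             index=[f"s{i}" for i in range(6)])
        clin = clinical([1, 2, 3, 10, 11, 12], [1] * 6,
                        index=list(feats.index))
        fit = fit_cox(feats, clin, ridge=0.1)
        assert fit.coef[0] > 0
        assert fit.c_index == pytest.approx(0.8)

    def test_null_feature_concordance_near_half(self):
        rng = np.random.default_rng(14)
        n = 500
        feats = pd.DataFrame({"z": rng.normal(size=n)},
                             index=[f"s{i}" for i in range(n)])
        clin = clinical(rng.exponential(1.0, n), np.ones(n, int),
                        index=list(feats.index))
        fit = fit_cox(feats, clin)
        assert fit.c_index == pytest.approx(0.5, abs=0.05)

    def test_recovers_planted_coefficient(self):
        cfg = SimulationConfig(seed=9, survival_coefs={"z": 0.8})
        rng = np.random.default_rng(1)
        feats = pd.DataFrame({"z": rng.normal(size=500)},
                             index=[f"s{i}" for i in range(500)])
        clin, _ = simulate_survival(feats, cfg)
        z = (feats - feats.mean()) / feats.std(ddof=0)
        fit = fit_cox(z, clin)
        assert fit.coef[0] == pytest.approx(0.8, abs=0.15)
        assert fit.hazard_ratios[0] == pytest.approx(np.exp(fit.coef[0]))

    def test_p_ge_n_rejected(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.normal(size=(5, 6)),
                             index=[f"s{i}" for i in range(5)])
        clin = clinical([1, 2, 3, 4, 5], [1] * 5, index=list(feats.index))
        with pytest.raises(ValueError, match="excluded"):
            fit_cox(feats, clin)

    def test_feature_scaling_rescales_coefficients(self):
        rng = np.random.default_rng(22)
        feats = pd.DataFrame({"z": rng.normal(size=200)},
                             index=[f"s{i}" for i in range(200)])
        cfg = SimulationConfig(seed=2, survival_coefs={"z": 0.5})
        clin, _ = simulate_survival(feats, cfg)
        fit1 = fit_cox(feats, clin)
        fit2 = fit_cox(feats * 10.0, clin)
        assert fit2.coef[0] == pytest.approx(fit1.coef[0] / 10.0, rel=1e-4)
        # linear predictor ranks unchanged
        assert (fit1.linear_predictor.rank()
                == fit2.linear_predictor.rank()).all()

    def test_efron_ties_flag(self):
        feats = pd.DataFrame({"z": [1.0, 2.0, 3.0, 4.0, 1.5, 2.5]},
                             index=[f"s{i}" for i in range(6)])
        clin = clinical([5, 5, 3, 3, 8, 1], [1] * 6, index=list(feats.index))
        fit_b = fit_cox(feats, clin, ties="breslow")
        fit_e = fit_cox(feats, clin, ties="efron")
        assert fit_b.ties == "breslow" and fit_e.ties == "efron"
        assert fit_b.coef[0] != fit_e.coef[0]  # tied times distinguish them

    def test_serialization_and_apply(self, tmp_path):
        rng = np.random.default_rng(31)
        feats = pd.DataFrame(rng.normal(size=(100, 3)),
                             columns=["a", "b", "c"],
                             index=[f"s{i}" for i in range(100)])
        cfg = SimulationConfig(seed=3, survival_coefs={"a": 0.6})
        clin, _ = simulate_survival(feats, cfg)
        fit = fit_cox(feats, clin)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        loaded = CoxFit.from_json(path)
        new = pd.DataFrame(rng.normal(size=(10, 3)),
                           columns=["c", "a", "b"],  # order-insensitive
                           index=[f"t{i}" for i in range(10)])
        lp = loaded.apply(new)
        expected = new[fit.features].to_numpy() @ fit.coef
        np.testing.assert_allclose(lp.to_numpy(), expected)


class TestConcordance:
    def test_perfect_and_reversed(self):
        clin = clinical([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index(np.array([4, 3, 2, 1.0]), clin) == 1.0
        assert concordance_index(np.array([1, 2, 3, 4.0]), clin) == 0.0

    def test_three_sample_brute_force(self):
        clin = clinical([1, 2, 3], [1, 1, 1])
        # all 3 pairs comparable; lp (3,2,1) orders all correctly
        assert concordance_index(np.array([3, 2, 1.0]), clin) == 1.0
        # lp (3,1,2): pairs (1,2) ok, (1,3) ok, (2,3) wrong -> 2/3
        assert concordance_index(np.array([3, 1, 2.0]), clin) \
            == pytest.approx(2 / 3)

    def test_ties_count_half(self):
        clin = clinical([1, 2], [1, 1])
        assert concordance_index(np.array([1.0, 1.0]), clin) == 0.5

    def test_no_comparable_pairs_errors(self):
        clin = clinical([1, 2], [0, 0])
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(np.array([1.0, 2.0]), clin)


class TestMedianSplit:
    def _fit_with_lp(self, lp: dict) -> CoxFit:
        return CoxFit(features=["z"], coef=np.array([1.0]),
                      linear_predictor=pd.Series(lp), c_index=0.5)

    def test_even_split(self):
        groups = median_split(self._fit_with_lp(
            {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}))
        assert set(groups.samples("high")) == {"c", "d"}
        assert set(groups.samples("low")) == {"a", "b"}
        assert groups.split_value == 2.5

    def test_all_equal_goes_low(self):
        groups = median_split(self._fit_with_lp({"a": 1.0, "b": 1.0}))
        assert len(groups.samples("high")) == 0

    def test_odd_n_strict_inequality(self):
        groups = median_split(self._fit_with_lp({"a": 1.0, "b": 2.0, "c": 3.0}))
        assert set(groups.samples("high")) == {"c"}


class TestKmAndLogrank:
    def test_km_product_limit_no_censoring(self):
        clin = clinical([1, 2, 3], [1, 1, 1])
        curve = km_curve(clin.data.index, clin)
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_identical_groups_statistic_near_zero(self):
        times = [1, 2, 3, 4, 5] * 2
        clin = clinical(times, [1] * 10)
        idx = list(clin.data.index)
        groups = RiskGroups(pd.Series(["high"] * 5 + ["low"] * 5,
                                      index=idx), 0.0)
        # same event-time distribution in both arms
        stat, p = logrank(groups, clin)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p > 0.99

    def test_planted_hazard_ratio_detected(self):
        rng = np.random.default_rng(40)
        t_hi = rng.exponential(1 / 3.0, 100)
        t_lo = rng.exponential(1.0, 100)
        clin = clinical(np.r_[t_hi, t_lo], np.ones(200, int))
        idx = list(clin.data.index)
        groups = RiskGroups(pd.Series(["high"] * 100 + ["low"] * 100,
                                      index=idx), 0.0)
        _, p = logrank(groups, clin)
        assert p < 0.05

    def test_empty_group_errors(self):
        clin = clinical([1, 2], [1, 1])
        groups = RiskGroups(pd.Series(["low", "low"],
                                      index=list(clin.data.index)), 0.0)
        with pytest.raises(ValueError, match="non-empty"):
            logrank(groups, clin)


def test_end_to_end_risk_stratification():
    """Simulate survival from 5 features, fit, median-split: the high-risk
    arm must show significantly worse Kaplan-Meier survival."""
    rng = np.random.default_rng(55)
    n = 300
    feats = pd.DataFrame(rng.normal(size=(n, 5)),
                         columns=[f"f{i}" for i in range(5)],
                         index=[f"s{i}" for i in range(n)])
    cfg = SimulationConfig(seed=8, survival_coefs={"f0": 0.8, "f1": -0.5,
                                                   "f2": 0.3})
    clin, _ = simulate_survival(feats, cfg)
    fit = fit_cox(feats, clin)
    groups = median_split(fit)
    stat, p = logrank(groups, clin)
    assert p < 0.05
    # median survival in the high-risk arm is shorter
    hi = km_curve(groups.samples("high"), clin)
    lo = km_curve(groups.samples("low"), clin)

    def median_time(curve):
        below = curve[curve["survival"] <= 0.5]
        return below["time"].iloc[0]

    assert median_time(hi) < median_time(lo)
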