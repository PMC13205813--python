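"""Survival machinery and drug-response association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hypoxapa.surv_drug import (
    cox_univariate,
    drug_association,
    km_curve,
    logrank_test,
    treatment_stratified_survival,
)


def surv_frame(times, events, **extra):
    idx = [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events, **extra}, index=idx)


def manual_logrank(surv_a, surv_b):
    """Independent O-E/Var computation over the pooled event times."""
    pooled = pd.concat(
        [surv_a.assign(g=0), surv_b.assign(g=1)], ignore_index=True
    ).sort_values("time")
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(pooled.loc[pooled.event == 1, "time"].unique()):
        at_risk = pooled[pooled.time >= t]
        d = int(((pooled.time == t) & (pooled.event == 1)).sum())
        n = len(at_risk)
        n1 = int((at_risk.g == 0).sum())
        d1 = int(((pooled.time == t) & (pooled.event == 1) & (pooled.g == 0)).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_toy_table_matches_hand_computation(self):
        a = surv_frame([1, 3, 5], [1, 1, 0])
        b = surv_frame([2, 4, 6], [1, 0, 1])
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(manual_logrank(a, b), rel=1e-6)
        assert p == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_null_p_values_roughly_uniform(self):
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            t = rng.exponential(10, 80)
            c = rng.uniform(0, 30, 80)
            surv = surv_frame(np.minimum(t, c), (t <= c).astype(int))
            half = len(surv) // 2
            pvals.append(logrank_test(surv.iloc[:half], surv.iloc[half:])[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_no_events_in_group_is_degenerate(self):
        a = surv_frame([1, 2], [1, 1])
        b = surv_frame([0.01, 0.01], [0, 0])
        with pytest.warns(UserWarning):
            chi2, p = logrank_test(a, b)
        assert np.isnan(chi2) and np.isnan(p)

    def test_empty_group_rejected(self):
        a = surv_frame([1], [1])
        with pytest.raises(ValueError):
            logrank_test(a, a.iloc[:0])


class TestKm:
    def test_two_events_no_censoring_closed_form(self):
        km = km_curve(surv_frame([1, 2], [1, 1])).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(0.5)
        assert km.loc[2.0] == pytest.approx(0.0)

    def test_no_events_flat_at_one(self):
        km = km_curve(surv_frame([1, 2, 3], [0, 0, 0]))
        assert (km["survival"] == 1.0).all()

    def test_matches_bruteforce_product_limit(self, rng):
        t = rng.exponential(5, 30).round(1)
        e = rng.integers(0, 2, 30)
        surv = surv_frame(t, e)
        km = km_curve(surv).set_index("time")["survival"]
        s = 1.0
        for tt in sorted(surv.loc[surv.event == 1, "time"].unique()):
            n = int((surv.time >= tt).sum())
            d = int(((surv.time == tt) & (surv.event == 1)).sum())
            s *= 1 - d / n
            assert km.loc[tt] == pytest.approx(s)

    def test_monotone_and_bounded(self, rng):
        surv = surv_frame(rng.exponential(5, 50), rng.integers(0, 2, 50))
        km = km_curve(surv)
        assert (km["survival"].diff().dropna() <= 1e-12).all()
        assert km["survival"].between(0, 1).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_curve(surv_frame([-1, 2], [1, 1]))


class TestCox:
    def test_hazard_ratio_recovery(self):
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 500)
            t = rng.exponential(1 / (0.03 * np.exp(np.log(2.0) * x)))
            c = rng.uniform(0, 80, 500)
            surv = surv_frame(np.minimum(t, c), (t <= c).astype(int))
            hr, (lo, hi), p = cox_univariate(surv, pd.Series(x, index=surv.index))
            hits += 1.7 <= hr <= 2.3
            assert lo < hr < hi
        assert hits >= 7

    def test_null_covariate_beta_near_zero(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 300)
        surv = surv_frame(t, np.ones(300, dtype=int))
        hr, ci, p = cox_univariate(surv, pd.Series(rng.normal(size=300), index=surv.index))
        assert 0.8 < hr < 1.25

    def test_constant_covariate_rejected(self):
        surv = surv_frame([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            cox_univariate(surv, pd.Series(1.0, index=surv.index))


class TestDrug:
    def test_exact_linear_gives_r_one(self):
        v = pd.Series(np.linspace(0, 1, 10), index=[f"s{i}" for i in range(10)])
        out = drug_association(v, 2 * v + 1)
        assert out["r"] == pytest.approx(1.0)
        assert out["group_comparison"]["mean_high"] > out["group_comparison"]["mean_low"]

    def test_independent_vectors_near_zero(self):
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            idx = [f"s{i}" for i in range(50)]
            rs.append(drug_association(
                pd.Series(rng.uniform(0, 1, 50), index=idx),
                pd.Series(rng.normal(size=50), index=idx))["r"])
        assert abs(np.mean(rs)) < 0.1

    def test_planted_negative_coupling_recovered(self, planted_cohort):
        co = planted_cohort
        out = drug_association(co.expression.loc[co.target_gene], co.ic50)
        assert out["r"] < -0.3 and out["p"] < 1e-3

    def test_no_overlap_rejected(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        b = pd.Series([1.0, 2.0, 3.0], index=["x", "y", "z"])
        with pytest.raises(ValueError):
            drug_association(a, b)


class TestTreatmentStratified:
    @staticmethod
    def interaction_data(seed, n=300, protective=True):
        """Low stratifier protective only among treated patients."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, n)
        treated = rng.integers(0, 2, n)
        beta = np.log(3.0) if protective else 0.0
        hz = 0.03 * np.exp(beta * x * treated)
        t = rng.exponential(1 / hz)
        c = rng.uniform(0, 80, n)
        return (surv_frame(np.minimum(t, c), (t <= c).astype(int), treated=treated),
                pd.Series(x, index=[f"s{i}" for i in range(n)]))

    def test_planted_interaction_detected_in_treated_subset(self):
        wins = 0
        for seed in range(5):
            surv, x = self.interaction_data(seed)
            rep = treatment_stratified_survival(surv, x)
            wins += rep["treated"]["logrank_p"] < rep["untreated"]["logrank_p"]
        assert wins >= 4

    def test_all_untreated_skips_treated_comparison(self):
        surv, x = self.interaction_data(0)
        surv["treated"] = 0
        with pytest.warns(UserWarning):
            rep = treatment_stratified_survival(surv, x)
        assert rep["treated"] is None and rep["untreated"] is not None

    def test_null_stratifier_uniformish_p(self):
        pvals = []
        for seed in range(20):
            surv, _ = self.interaction_data(seed, protective=False)
            x = pd.Series(np.random.default_rng(seed + 999).uniform(0, 1, len(surv)),
                          index=surv.index)
            rep = treatment_stratified_survival(surv, x)
            pvals += [rep["treated"]["logrank_p"], rep["untreated"]["logrank_p"]]
        assert np.mean(np.asarray(pvals) < 0.05) < 0.25
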