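"""HSS model: selection, scoring arithmetic, AUC, associations."""

import numpy as np
import pandas as pd
import pytest

from hypoxapa.hss_model import (
    HssModel,
    associate_hss,
    compute_hss,
    evaluate_auc,
    fit_hss,
)
from hypoxapa.syndata import SimConfig, simulate_cohort


def toy_model(events, coefs, means=None):
    return HssModel(
        events=list(events), coefficients=list(coefs), intercept=0.0,
        selection_frequency={e: 1.0 for e in events},
        training_means=means or {e: 0.5 for e in events},
        cv_auc_train=(1.0, 0.0), cv_auc_valid=(1.0, 0.0),
    )


class TestFit:
    def test_perfectly_separating_event_always_selected(self, rng):
        samples = [f"s{i}" for i in range(60)]
        lab = pd.Series(["hypoxic"] * 30 + ["normoxic"] * 30, index=samples)
        sep = np.r_[rng.uniform(0.0, 0.3, 30), rng.uniform(0.7, 1.0, 30)]
        noise = rng.uniform(0, 1, 60)
        pdui = pd.DataFrame([sep, noise], index=["sep", "noise"], columns=samples)
        model = fit_hss(pdui, lab, n_folds=10, seed=0)
        assert model.selection_frequency["sep"] == 1.0
        assert model.cv_auc_valid[0] == 1.0
        assert "sep" in model.events

    def test_planted_events_dominate_selection(self, planted_cohort):
        """38 candidates, 12 with planted signal: recall >= 0.8 at freq >= 0.5."""
        co = planted_cohort
        model = fit_hss(co.pdui_observed, co.labels_true, seed=1)
        selected = {e for e, f in model.selection_frequency.items() if f >= 0.5}
        recall = len(set(co.affected_events) & selected) / len(co.affected_events)
        assert recall >= 0.8
        assert model.cv_auc_valid[0] >= 0.9

    def test_null_candidates_give_chance_auc(self):
        aucs = []
        for seed in range(3):
            co = simulate_cohort(SimConfig(seed=100 + seed, n_events=38, n_affected=12,
                                           pdui_shift=0.0, hypoxia_effect=0.0))
            with pytest.warns(UserWarning):
                m = fit_hss(co.pdui_observed, co.labels_true, seed=seed)
            aucs.append(m.cv_auc_valid[0])
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_sign_consistency_on_planted_data(self, planted_cohort):
        """Events whose PDUI drops under hypoxia get negative weights."""
        co = planted_cohort
        model = fit_hss(co.pdui_observed, co.labels_true, seed=2)
        planted = [e for e in model.events if e in set(co.affected_events)]
        coefs = [model.coefficients[model.events.index(e)] for e in planted]
        assert len(coefs) > 0 and np.mean(np.array(coefs) < 0) >= 0.8

    def test_too_few_samples_per_class_rejected(self, rng):
        samples = [f"s{i}" for i in range(12)]
        lab = pd.Series(["hypoxic"] * 6 + ["normoxic"] * 6, index=samples)
        pdui = pd.DataFrame(rng.uniform(0, 1, (3, 12)), columns=samples)
        with pytest.raises(ValueError):
            fit_hss(pdui, lab, n_folds=10)


class TestComputeHss:
    def test_zero_coefficients_give_zero(self):
        m = toy_model(["e1"], [0.0])
        pdui = pd.DataFrame([[0.3, 0.9]], index=["e1"], columns=["a", "b"])
        assert (compute_hss(m, pdui) == 0).all()

    def test_arithmetic(self):
        m = toy_model(["e1", "e2"], [1.0, -2.0])
        pdui = pd.DataFrame([[0.5], [0.25]], index=["e1", "e2"], columns=["a"])
        assert compute_hss(m, pdui)["a"] == pytest.approx(0.0)

    def test_matches_dot_product_oracle(self, rng):
        events = [f"e{i}" for i in range(8)]
        coefs = rng.normal(size=8)
        m = toy_model(events, coefs)
        pdui = pd.DataFrame(rng.uniform(0, 1, (8, 15)), index=events,
                            columns=[f"s{i}" for i in range(15)])
        got = compute_hss(m, pdui)
        expected = coefs @ pdui.to_numpy()
        np.testing.assert_allclose(got.to_numpy(), expected)

    def test_missing_imputed_with_training_mean(self):
        m = toy_model(["e1"], [2.0], means={"e1": 0.25})
        pdui = pd.DataFrame([[np.nan]], index=["e1"], columns=["a"])
        assert compute_hss(m, pdui)["a"] == pytest.approx(0.5)

    def test_absent_event_rejected(self):
        m = toy_model(["e1", "gone"], [1.0, 1.0])
        pdui = pd.DataFrame([[0.5]], index=["e1"], columns=["a"])
        with pytest.raises(KeyError, match="gone"):
            compute_hss(m, pdui)

    def test_json_roundtrip(self, tmp_path):
        m = toy_model(["e1", "e2"], [1.5, -0.5])
        path = str(tmp_path / "m.json")
        m.to_json(path)
        assert HssModel.from_json(path) == m


class TestAuc:
    def test_perfect_ordering(self):
        assert evaluate_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_matches_pair_enumeration_with_ties(self, rng):
        scores = rng.integers(0, 5, 20).astype(float)  # many ties
        y = rng.integers(0, 2, 20)
        y[0], y[1] = 0, 1  # both classes present
        got = evaluate_auc(scores, y)
        wins = sum(
            1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            for sp in scores[y == 1] for sn in scores[y == 0]
        )
        assert got == pytest.approx(wins / ((y == 1).sum() * (y == 0).sum()))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auc([1, 2], [1, 1])


class TestAssociate:
    def test_planted_cohort_associations(self, planted_cohort):
        co = planted_cohort
        model = fit_hss(co.pdui_observed, co.labels_true, seed=3)
        hss = compute_hss(model, co.pdui_observed)
        rep = associate_hss(hss, co.survival, stage=co.survival["stage"])
        assert rep["survival"]["logrank_p"] < 0.05
        assert rep["stage"]["p"] < 0.05

    def test_constant_hss_flagged_degenerate(self, planted_cohort):
        hss = pd.Series(1.0, index=planted_cohort.survival.index)
        assert associate_hss(hss, planted_cohort.survival).get("degenerate")

    def test_self_correlation_is_one(self, planted_cohort):
        co = planted_cohort
        hss = pd.Series(np.linspace(0, 1, len(co.survival)), index=co.survival.index)
        rep = associate_hss(hss, co.survival, enrichment={"self": hss})
        assert rep["enrichment"]["self"]["r"] == pytest.approx(1.0)

    def test_empty_overlap_rejected(self, planted_cohort):
        hss = pd.Series([1.0], index=["nope"])
        with pytest.raises(ValueError):
            associate_hss(hss, planted_cohort.survival)
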