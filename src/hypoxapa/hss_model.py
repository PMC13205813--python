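"""Hypoxia signature score (HSS) from candidate APA events.

The score is a linear combination of selected events' PDUI values weighted
by logistic-regression coefficients:

    HSS(sample) = sum_k coefficient_k * PDUI_k(sample)

Events are selected by stratified 10-fold cross-validation: within each
fold an L1-penalised logistic regression (penalty strength by inner CV)
picks events; events selected in at least ``freq_min`` of folds enter the
final model, whose coefficients come from an unpenalised refit on all
non-mixed samples.  Higher HSS indicates a greater degree of tumor hypoxia
(coefficients of events whose PDUI drops under hypoxia come out negative).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from . import surv_drug

__all__ = ["HssModel", "fit_hss", "compute_hss", "evaluate_auc", "associate_hss"]

HYPOXIC, NORMOXIC = "hypoxic", "normoxic"


@dataclasses.dataclass
class HssModel:
    events: list[str]
    coefficients: list[float]
    intercept: float
    selection_frequency: dict[str, float]   # all candidates, over CV folds
    training_means: dict[str, float]        # per-event imputation values
    cv_auc_train: tuple[float, float]       # mean, sd over folds
    cv_auc_valid: tuple[float, float]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "HssModel":
        with open(path) as fh:
            d = json.load(fh)
        d["cv_auc_train"] = tuple(d["cv_auc_train"])
        d["cv_auc_valid"] = tuple(d["cv_auc_valid"])
        return cls(**d)


def _design(pdui: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    labels = labels.reindex(pdui.columns)
    keep = labels.isin([HYPOXIC, NORMOXIC])
    sub = pdui.loc[:, keep.to_numpy()]
    y = (labels[keep] == HYPOXIC).to_numpy(dtype=int)
    X = sub.to_numpy(dtype=float).T  # samples x events
    return X, y, list(sub.columns), list(pdui.index)


def _impute(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    X = X.copy()
    idx = np.where(np.isnan(X))
    X[idx] = means[idx[1]]
    return X


def _l1_select(
    X: np.ndarray, y: np.ndarray, Cs: np.ndarray, seed: int, inner_folds: int = 3
) -> LogisticRegression:
    """L1 logistic fit with penalty strength chosen by inner CV (1-SE rule).

    Among the candidate strengths, the strongest penalty whose mean
    validation log-loss lies within one standard error of the best is
    kept — the usual sparse-selection compromise between fit and parsimony.
    """
    skf = StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
    losses = np.zeros((len(Cs), inner_folds))
    for j, (tr, te) in enumerate(skf.split(X, y)):
        for i, C in enumerate(Cs):
            clf = LogisticRegression(C=C, penalty="l1", solver="liblinear", max_iter=2000)
            clf.fit(X[tr], y[tr])
            losses[i, j] = log_loss(y[te], clf.predict_proba(X[te])[:, 1], labels=[0, 1])
    mean = losses.mean(axis=1)
    se = losses.std(axis=1) / np.sqrt(inner_folds)
    best = int(np.argmin(mean))
    idx = int(np.argmax(mean <= mean[best] + se[best]))  # smallest C within 1 SE
    final = LogisticRegression(C=Cs[idx], penalty="l1", solver="liblinear", max_iter=2000)
    final.fit(X, y)
    return final


def fit_hss(
    pdui_candidates: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 10,
    seed: int = 0,
    freq_min: float = 0.5,
    Cs: np.ndarray | None = None,
) -> HssModel:
    """Cross-validated sparse logistic selection + unpenalised refit.

    ``pdui_candidates`` is events x samples; missing PDUI entries are
    imputed with the event's mean over the training samples of each fold
    (and over all samples for the final refit).
    """
    if Cs is None:
        Cs = np.logspace(-2, 2, 10)
    X, y, _, events = _design(pdui_candidates, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < n_folds:
        raise ValueError(
            f"need >= {n_folds} samples per class, got {n_pos} hypoxic / {n_neg} normoxic"
        )
    rng_seed = seed % (2**31)
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed + attempt)
        folds = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2 for tr, te in folds):
            break
    else:
        raise RuntimeError("could not build folds with both classes after 5 attempts")

    sel_counts = np.zeros(len(events))
    auc_tr, auc_va = [], []
    for tr, te in folds:
        means = np.nanmean(X[tr], axis=0)
        means = np.where(np.isnan(means), 0.5, means)
        Xtr, Xte = _impute(X[tr], means), _impute(X[te], means)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = _l1_select(Xtr, y[tr], Cs, rng_seed)
        sel_counts += (np.abs(clf.coef_[0]) > 1e-10).astype(float)
        auc_tr.append(evaluate_auc(clf.decision_function(Xtr), y[tr]))
        auc_va.append(evaluate_auc(clf.decision_function(Xte), y[te]))

    freq = sel_counts / n_folds
    chosen = [i for i, f in enumerate(freq) if f >= freq_min]
    if not chosen:
        # nothing is stably selected (e.g. pure-noise candidates): empty model
        warnings.warn("no event reached the selection-frequency threshold", stacklevel=2)
        return HssModel(
            events=[], coefficients=[], intercept=0.0,
            selection_frequency={e: float(f) for e, f in zip(events, freq)},
            training_means={},
            cv_auc_train=(float(np.mean(auc_tr)), float(np.std(auc_tr))),
            cv_auc_valid=(float(np.mean(auc_va)), float(np.std(auc_va))),
        )
    means_all = np.nanmean(X, axis=0)
    means_all = np.where(np.isnan(means_all), 0.5, means_all)
    Xfull = _impute(X, means_all)[:, chosen]
    refit = LogisticRegression(penalty=None, solver="lbfgs", max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        refit.fit(Xfull, y)
    coefs = refit.coef_[0]
    final = [(events[i], float(c)) for i, c in zip(chosen, coefs) if c != 0.0]
    return HssModel(
        events=[e for e, _ in final],
        coefficients=[c for _, c in final],
        intercept=float(refit.intercept_[0]),
        selection_frequency={e: float(f) for e, f in zip(events, freq)},
        training_means={events[i]: float(means_all[i]) for i in chosen},
        cv_auc_train=(float(np.mean(auc_tr)), float(np.std(auc_tr))),
        cv_auc_valid=(float(np.mean(auc_va)), float(np.std(auc_va))),
    )


def compute_hss(model: HssModel, pdui: pd.DataFrame) -> pd.Series:
    """HSS per sample: coefficient-weighted sum of the model events' PDUI.

    Missing PDUI entries are imputed with the event's training mean.  The
    intercept is not part of the score (it only shifts every sample equally
    and the signature is used as a relative score).
    """
    missing = [e for e in model.events if e not in pdui.index]
    if missing:
        raise KeyError(f"model events absent from PDUI matrix: {missing}")
    X = pdui.loc[model.events].to_numpy(dtype=float)
    means = np.array([model.training_means.get(e, 0.5) for e in model.events])
    idx = np.where(np.isnan(X))
    X[idx] = means[idx[0]]
    hss = np.asarray(model.coefficients) @ X
    return pd.Series(hss, index=pdui.columns, name="hss")


def evaluate_auc(scores, labels) -> float:
    """Rank-based AUC: P(score_hypoxic > score_normoxic), ties count 1/2."""
    s = np.asarray(pd.Series(scores), dtype=float)
    lab = pd.Series(labels)
    if lab.dtype == object:
        y = (lab == HYPOXIC).to_numpy(dtype=int)
    else:
        y = lab.to_numpy(dtype=int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute AUC")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def associate_hss(
    scores: pd.Series,
    survival: pd.DataFrame,
    stage: pd.Series | None = None,
    enrichment: pd.DataFrame | Mapping[str, pd.Series] | None = None,
) -> dict:
    """Clinical and biological associations of the HSS.

    Median-split Kaplan-Meier + log-rank on overlapping samples, Student's
    t-test of HSS between stage groups, and Pearson correlation of HSS with
    each enrichment score.  Degenerate inputs (constant HSS) are flagged.
    """
    common = scores.index.intersection(survival.index)
    if len(common) == 0:
        raise ValueError("no overlap between HSS scores and survival table")
    s = scores.loc[common]
    report: dict = {}
    if s.nunique() <= 1:
        report["degenerate"] = True
        return report
    med = s.median()
    high = s > med
    surv = survival.loc[common]
    chi2, p = surv_drug.logrank_test(
        surv.loc[high.to_numpy()], surv.loc[(~high).to_numpy()]
    )
    report["survival"] = {"logrank_chi2": chi2, "logrank_p": p,
                          "n_high": int(high.sum()), "n_low": int((~high).sum())}
    if stage is not None:
        st = stage.reindex(s.index).dropna()
        groups = st.unique()
        if len(groups) == 2:
            a = s.loc[st.index[st == groups[0]]]
            b = s.loc[st.index[st == groups[1]]]
            t, tp = stats.ttest_ind(a, b)
            report["stage"] = {"groups": list(map(str, groups)),
                               "t": float(t), "p": float(tp)}
    if enrichment is not None:
        if isinstance(enrichment, pd.DataFrame):
            enrichment = {name: enrichment.loc[name] for name in enrichment.index}
        cors = {}
        for name, vec in enrichment.items():
            v = vec.reindex(s.index).astype(float)
            ok = v.notna()
            if v[ok].nunique() > 1 and ok.sum() >= 3:
                r, rp = stats.pearsonr(s[ok], v[ok])
                cors[name] = {"r": float(r), "p": float(rp)}
        report["enrichment"] = cors
    return report
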