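"""Survival and drug-response association machinery.

Kaplan-Meier curves, the two-group log-rank test and univariate Cox
regression are delegated to lifelines behind this module's interface;
dichotomisations (high/low HSS, PDUI, expression) are at the median
throughout.  Drug response is a per-sample IC50 (log scale permitted):
correlation with PDUI/expression plus a median-split group comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "logrank_test",
    "km_curve",
    "cox_univariate",
    "drug_association",
    "treatment_stratified_survival",
]


def _check_surv(surv: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "event"}.issubset(surv.columns):
        raise ValueError("survival table needs 'time' and 'event' columns")
    if (surv["time"] < 0).any():
        raise ValueError("negative survival times")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return surv


def logrank_test(surv_a: pd.DataFrame, surv_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    Both groups must be non-empty; a group with zero observed events makes
    the test degenerate and returns (nan, nan) with a warning.
    """
    a, b = _check_surv(surv_a), _check_surv(surv_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if a["event"].sum() == 0 or b["event"].sum() == 0:
        warnings.warn("log-rank degenerate: a group has no observed events", stacklevel=2)
        return float("nan"), float("nan")
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def km_curve(surv: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate: DataFrame (time, survival)."""
    surv = _check_surv(surv)
    if len(surv) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(surv["time"], surv["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def cox_univariate(
    surv: pd.DataFrame, covariate: pd.Series
) -> tuple[float, tuple[float, float], float]:
    """Univariate Cox proportional-hazards fit.

    Returns (hazard ratio, Wald 95% CI, p).  The covariate must vary and at
    least one event must be observed.
    """
    surv = _check_surv(surv)
    x = covariate.reindex(surv.index).astype(float)
    if x.isna().any():
        keep = x.notna()
        surv, x = surv.loc[keep], x[keep]
    if x.nunique() <= 1:
        raise ValueError("covariate is constant")
    if surv["event"].sum() == 0:
        raise ValueError("no observed events")
    df = pd.DataFrame({"time": surv["time"], "event": surv["event"], "x": x})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["x"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["x"]).to_numpy()
    p = float(cph.summary.loc["x", "p"])
    return hr, (float(lo), float(hi)), p


def drug_association(values: pd.Series, ic50: pd.Series) -> dict:
    """PDUI/expression vs IC50: Pearson r plus a median-split t-test.

    Samples are split at the median of ``values``; IC50 is compared between
    high and low groups by Student's t-test.
    """
    common = values.index.intersection(ic50.index)
    if len(common) < 3:
        raise ValueError("need >= 3 overlapping samples")
    v = values.loc[common].astype(float)
    d = ic50.loc[common].astype(float)
    ok = v.notna() & d.notna()
    v, d = v[ok], d[ok]
    if len(v) < 3 or v.nunique() <= 1 or d.nunique() <= 1:
        raise ValueError("degenerate drug-association input")
    r, p = stats.pearsonr(v, d)
    high = v > v.median()
    if high.sum() >= 2 and (~high).sum() >= 2:
        t, tp = stats.ttest_ind(d[high], d[~high])
        group = {"t": float(t), "p": float(tp),
                 "mean_high": float(d[high].mean()), "mean_low": float(d[~high].mean())}
    else:
        group = None
    return {"r": float(r), "p": float(p), "n": int(len(v)), "group_comparison": group}


def treatment_stratified_survival(
    surv: pd.DataFrame, stratifier: pd.Series
) -> dict:
    """High/low survival comparison within treated and untreated subsets.

    The stratifier (e.g. an event's PDUI) is median-split; within each
    treatment subset a log-rank test compares high vs low, and a Cox model
    of the continuous stratifier is fit within the treated subset.  Empty
    or degenerate cells are skipped with a warning.
    """
    surv = _check_surv(surv)
    if "treated" not in surv.columns:
        raise ValueError("survival table needs a 'treated' column")
    x = stratifier.reindex(surv.index).astype(float)
    keep = x.notna()
    surv, x = surv.loc[keep], x[keep]
    med = x.median()
    high = x > med
    report: dict = {}
    for flag, name in ((1, "treated"), (0, "untreated")):
        sub = surv["treated"] == flag
        hi, lo = sub & high, sub & ~high
        if hi.sum() == 0 or lo.sum() == 0:
            warnings.warn(f"{name}: empty high/low cell; comparison skipped", stacklevel=2)
            report[name] = None
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi2, p = logrank_test(surv.loc[hi.to_numpy()], surv.loc[lo.to_numpy()])
        report[name] = {"logrank_chi2": chi2, "logrank_p": p,
                        "n_high": int(hi.sum()), "n_low": int(lo.sum())}
    treated = surv["treated"] == 1
    if treated.sum() >= 10 and x[treated].nunique() > 1 and surv.loc[treated.to_numpy(), "event"].sum() > 0:
        try:
            hr, ci, p = cox_univariate(surv.loc[treated.to_numpy()], x[treated])
            report["treated_cox"] = {"hr": hr, "ci": ci, "p": p}
        except Exception as exc:  # non-convergence on tiny strata
            warnings.warn(f"treated-subset Cox skipped: {exc}", stacklevel=2)
            report["treated_cox"] = None
    else:
        report["treated_cox"] = None
    return report
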