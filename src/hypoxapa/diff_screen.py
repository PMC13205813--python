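"""Differential PDUI / expression testing and the hypoxia-gene screen.

Two-group comparisons use Student's (equal-variance) t-test between
hypoxic and normoxic samples (mixed samples are excluded); effect size is
log2 of the pseudocounted group-mean ratio.  An event passes the screen
when it is differential AND its PDUI correlates (Pearson, pairwise-complete)
with at least one hypoxia-related gene's expression.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import GeneSet

__all__ = ["differential_table", "screen_candidates", "masked_pearson"]

HYPOXIC, NORMOXIC = "hypoxic", "normoxic"


def _two_groups(values: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(values.columns)
    hyp = values.loc[:, (labels == HYPOXIC).to_numpy()].to_numpy(dtype=float)
    norm = values.loc[:, (labels == NORMOXIC).to_numpy()].to_numpy(dtype=float)
    if hyp.shape[1] == 0 or norm.shape[1] == 0:
        raise ValueError("both hypoxic and normoxic groups must be non-empty")
    return hyp, norm


def differential_table(
    values: pd.DataFrame,
    labels: pd.Series,
    p_max: float = 0.010,
    lfc_min: float = 0.050,
    pseudocount: float = 0.01,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature hypoxic-vs-normoxic t-test with log2 fold change.

    ``labels`` assigns hypoxic/normoxic/mixed per sample; mixed samples and
    missing entries are dropped per feature.  Features with fewer than 2
    observations in either group or zero pooled variance are skipped
    (``flag`` NaN p).  Returns a DataFrame with mean_a (hypoxic), mean_b
    (normoxic), log2fc, p, q (BH), direction and the joint-threshold flag.
    """
    hyp, norm = _two_groups(values, labels)
    n_h = (~np.isnan(hyp)).sum(axis=1)
    n_n = (~np.isnan(norm)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(hyp, norm, axis=1, equal_var=equal_var, nan_policy="omit")
        mean_h = np.nanmean(np.where(np.isnan(hyp), np.nan, hyp), axis=1)
        mean_n = np.nanmean(np.where(np.isnan(norm), np.nan, norm), axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    p[(n_h < 2) | (n_n < 2)] = np.nan
    log2fc = np.log2((mean_h + pseudocount) / (mean_n + pseudocount))
    valid = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    flag = valid & (p < p_max) & (np.abs(log2fc) > lfc_min)
    out = pd.DataFrame(
        {
            "mean_a": mean_h, "mean_b": mean_n, "log2fc": log2fc,
            "p": p, "q": q,
            "direction": np.where(mean_h < mean_n, "down", "up"),
            "flag": flag,
        },
        index=values.index,
    )
    out.index.name = "feature"
    out.attrs["n_skipped"] = int((~valid).sum())
    out.attrs["n_down"] = int((flag & (out["direction"] == "down")).sum())
    out.attrs["n_up"] = int((flag & (out["direction"] == "up")).sum())
    return out


def masked_pearson(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson r and p of vector ``x`` vs rows of ``Y``.

    Missing entries of ``x`` are dropped for every row; rows of ``Y`` are
    assumed complete.  Constant vectors give NaN.
    """
    mask = ~np.isnan(x)
    xv = x[mask]
    Yv = Y[:, mask]
    n = xv.size
    if n < 3:
        return np.full(Y.shape[0], np.nan), np.full(Y.shape[0], np.nan)
    xc = xv - xv.mean()
    Yc = Yv - Yv.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    return r, p


def screen_candidates(
    diff_events: pd.DataFrame,
    expr: pd.DataFrame,
    pdui: pd.DataFrame,
    hypoxia_genes: GeneSet | Iterable[str],
    r_min: float = 0.1,
    p_max: float = 0.010,
) -> pd.DataFrame:
    """Retain differential events correlated with >=1 hypoxia-related gene.

    ``diff_events`` is the output of :func:`differential_table` on PDUI;
    only flagged events are screened.  An event survives when its PDUI
    vector has |r| > ``r_min`` at p < ``p_max`` with at least one gene of
    ``hypoxia_genes`` present in ``expr``.  Returns the flagged subset with
    the best-correlated gene and its r/p.
    """
    members = hypoxia_genes.members if isinstance(hypoxia_genes, GeneSet) else set(hypoxia_genes)
    genes = [g for g in expr.index if g in members]
    if not genes:
        raise ValueError("no hypoxia-related genes present in expression matrix")
    flagged = diff_events.index[diff_events["flag"].astype(bool)]
    if len(flagged) == 0:
        return pd.DataFrame(columns=["best_gene", "r", "p"])
    G = expr.loc[genes].to_numpy(dtype=float)
    samples = expr.columns
    rows = []
    for ev in flagged:
        x = pdui.loc[ev].reindex(samples).to_numpy(dtype=float)
        r, p = masked_pearson(x, G)
        hit = (np.abs(r) > r_min) & (p < p_max)
        if np.any(hit):
            best = int(np.nanargmax(np.where(hit, np.abs(r), -np.inf)))
            rows.append((ev, genes[best], float(r[best]), float(p[best])))
    return pd.DataFrame(rows, columns=["event", "best_gene", "r", "p"]).set_index("event")
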