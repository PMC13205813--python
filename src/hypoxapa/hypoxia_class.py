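"""Hypoxic / normoxic phenotype assignment.

Two complementary classifiers are combined:

* the NC method — a signature-guided rank score: per signature gene, samples
  in the top expression half score +1 and the bottom half -1; the per-sample
  sum's sign gives the label (>0 hypoxic, <0 normoxic, =0 mixed);
* NMF consensus clustering — repeated non-negative matrix factorisations
  aggregated into a sample co-clustering matrix, cut into k groups, with the
  cluster of highest mean hypoxia enrichment labelled hypoxic and the lowest
  normoxic.

The consensus keeps a sample's label only when both methods concordantly
call it hypoxic or normoxic; everything else is mixed.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.decomposition import NMF

from .enrichment import GeneSet

__all__ = [
    "nc_score",
    "nc_classify",
    "nmf_cluster",
    "label_clusters",
    "consensus",
    "classify_samples",
]

HYPOXIC, NORMOXIC, MIXED = "hypoxic", "normoxic", "mixed"


def nc_score(expr: pd.DataFrame, signature: GeneSet) -> pd.Series:
    """Per-sample median-split score summed over signature genes.

    For each signature gene present, samples whose expression ranks in the
    top half contribute +1, the bottom half -1 (ties get average ranks; a
    rank above n/2 counts as top).
    """
    present = expr.index.intersection(signature.members)
    if len(present) == 0:
        raise ValueError(f"no genes of signature {signature.name!r} present")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sub = expr.loc[present].to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, sub)
    contrib = np.where(ranks > sub.shape[1] / 2.0, 1, -1)
    return pd.Series(contrib.sum(axis=0), index=expr.columns, name=signature.name)


def nc_classify(scores: pd.DataFrame, rule: str = "unanimity") -> pd.Series:
    """Combine per-signature scores (signatures x samples) into labels.

    Per signature: score > 0 hypoxic, < 0 normoxic, = 0 mixed.  Signatures
    are combined by ``rule``: 'unanimity' (all agree on hypoxic or normoxic,
    else mixed) or 'majority' (strict majority, else mixed).
    """
    per_sig = np.sign(scores.to_numpy(dtype=float))  # 1, -1, 0
    n_sig = per_sig.shape[0]
    n_hyp = (per_sig > 0).sum(axis=0)
    n_norm = (per_sig < 0).sum(axis=0)
    if rule == "unanimity":
        lab = np.where(n_hyp == n_sig, HYPOXIC, np.where(n_norm == n_sig, NORMOXIC, MIXED))
    elif rule == "majority":
        lab = np.where(
            n_hyp * 2 > n_sig, HYPOXIC, np.where(n_norm * 2 > n_sig, NORMOXIC, MIXED)
        )
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return pd.Series(lab, index=scores.columns, name="nc_label")


def nmf_cluster(
    expr: pd.DataFrame, k: int, restarts: int = 30, seed: int = 0
) -> pd.Series:
    """NMF consensus clustering of samples into k groups.

    Runs NMF (Frobenius objective, multiplicative updates) from ``restarts``
    seeded random initialisations, assigns each sample to its dominant
    factor, accumulates a co-clustering consensus matrix, and cuts its
    average-linkage hierarchical clustering into k groups.  Cluster ids are
    renumbered 0..k-1 by first appearance for determinism.
    """
    X = expr.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("expression matrix must be non-negative")
    n = X.shape[1]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n_samples, got k={k}, n={n}")
    consensus_mat = np.zeros((n, n))
    for r in range(restarts):
        model = NMF(
            n_components=k, init="random", solver="mu", beta_loss="frobenius",
            max_iter=400, tol=1e-5, random_state=(seed + r) % (2**31),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X)
        assign = model.components_.argmax(axis=0)
        consensus_mat += assign[:, None] == assign[None, :]
    consensus_mat /= restarts
    dist = 1.0 - consensus_mat
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.array([remap.setdefault(c, len(remap)) for c in raw])
    return pd.Series(labels, index=expr.columns, name="cluster")


def label_clusters(
    assignment: pd.Series, hypoxia_scores: pd.Series
) -> tuple[pd.Series, bool]:
    """Label clusters by mean hypoxia enrichment.

    Highest mean -> hypoxic, lowest -> normoxic, all others mixed.  Returns
    (labels, tie_flag); ties break toward the lower cluster index.
    """
    clusters = sorted(assignment.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to label")
    means = {
        c: float(hypoxia_scores.loc[assignment.index[assignment == c]].mean())
        for c in clusters
    }
    ordered = sorted(clusters, key=lambda c: (-means[c], c))
    hyp, norm = ordered[0], ordered[-1]
    tie = len({round(v, 12) for v in means.values()}) < len(clusters)
    lab = assignment.map(
        lambda c: HYPOXIC if c == hyp else (NORMOXIC if c == norm else MIXED)
    )
    return lab.rename("nmf_label"), tie


def consensus(nc_labels: pd.Series, nmf_labels: pd.Series) -> pd.DataFrame:
    """Two-method consensus: concordant hypoxic/normoxic kept, else mixed."""
    if set(nc_labels.index) != set(nmf_labels.index):
        raise ValueError("NC and NMF label sample sets differ")
    nmf_labels = nmf_labels.reindex(nc_labels.index)
    agree = (nc_labels == nmf_labels) & nc_labels.isin([HYPOXIC, NORMOXIC])
    lab = np.where(agree, nc_labels, MIXED)
    return pd.DataFrame(
        {"nc_label": nc_labels, "nmf_label": nmf_labels,
         "consensus_label": pd.Series(lab, index=nc_labels.index)}
    )


def classify_samples(
    expr: pd.DataFrame,
    signatures: Sequence[GeneSet] | Mapping[str, Sequence[str]],
    hypoxia_set: GeneSet,
    k: int = 2,
    restarts: int = 30,
    seed: int = 0,
    rule: str = "unanimity",
    nmf_expr: pd.DataFrame | None = None,
    hypoxia_scores: pd.Series | None = None,
) -> pd.DataFrame:
    """End-to-end phenotype assignment (NC + NMF + consensus).

    ``nmf_expr`` optionally supplies a transformed (non-negative) matrix for
    the factorisation, e.g. log2(x+1); NC scoring always uses ``expr``.
    ``hypoxia_scores`` may carry precomputed per-sample enrichment scores;
    otherwise they are computed with the package scorer.
    """
    from .enrichment import score_matrix

    if isinstance(signatures, Mapping):
        signatures = [GeneSet.from_iterable(n, m) for n, m in signatures.items()]
    scores = pd.DataFrame({s.name: nc_score(expr, s) for s in signatures}).T
    nc = nc_classify(scores, rule=rule)
    assign = nmf_cluster(nmf_expr if nmf_expr is not None else expr, k, restarts, seed)
    if hypoxia_scores is None:
        hypoxia_scores = score_matrix(expr, [hypoxia_set]).iloc[0]
    nmf_lab, _ = label_clusters(assign, hypoxia_scores)
    out = consensus(nc, nmf_lab)
    for s in signatures:
        out[f"score_{s.name}"] = scores.loc[s.name]
    out["nmf_cluster"] = assign
    return out
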