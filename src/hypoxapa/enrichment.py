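"""Single-sample gene-set enrichment scoring (ssGSEA-style).

One rank-based scorer serves both bulk phenotype validation and single-cell
hypoxia scoring.  For a sample, genes are ordered by decreasing expression
and the score is the integrated difference between the rank-weighted
cumulative distribution of in-set genes and the uniform cumulative
distribution of out-of-set genes.  Weights are (average) expression ranks
raised to ``exponent``, so the score is exactly invariant to any strictly
monotone transform of the sample's expression values.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["GeneSet", "ssgsea_score", "score_matrix"]


@dataclasses.dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(members))


def _as_gene_set(obj: GeneSet | tuple | Mapping | Iterable) -> GeneSet:
    if isinstance(obj, GeneSet):
        return obj
    if isinstance(obj, tuple) and len(obj) == 2:
        return GeneSet.from_iterable(obj[0], obj[1])
    raise TypeError("expected GeneSet or (name, members)")


def ssgsea_score(
    expr_column: pd.Series | Sequence[float],
    gene_set: GeneSet,
    exponent: float = 0.25,
) -> float:
    """Enrichment score of one gene set in one sample.

    Returns NaN with a warning when fewer than 2 set members are present
    among the scored genes.
    """
    values = pd.Series(expr_column, dtype=float)
    in_set = values.index.isin(gene_set.members)
    n = len(values)
    if in_set.sum() < 2:
        warnings.warn(
            f"gene set {gene_set.name!r}: <2 members present; score undefined",
            stacklevel=2,
        )
        return float("nan")
    ranks = rankdata(values.to_numpy())  # 1 = lowest expression, ties averaged
    # descending order, gene-name tie-break for determinism
    order = np.lexsort((values.index.to_numpy(), -ranks))
    in_ord = in_set[order]
    w = ranks[order] ** exponent
    w_in = np.where(in_ord, w, 0.0)
    cum_in = np.cumsum(w_in) / w_in.sum()
    out = (~in_ord).astype(float)
    cum_out = np.cumsum(out) / out.sum()
    return float(np.sum(cum_in - cum_out) / n)


def score_matrix(
    expr: pd.DataFrame,
    sets: Sequence[GeneSet] | Mapping[str, Iterable[str]],
    exponent: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-sample, per-set enrichment scores (sets x samples).

    When ``normalize`` is set, scores are divided by the overall score
    range across the matrix (the usual ssGSEA normalisation); relative
    comparisons between samples are unchanged.
    """
    if isinstance(sets, Mapping):
        gene_sets = [GeneSet.from_iterable(k, v) for k, v in sets.items()]
    else:
        gene_sets = [_as_gene_set(s) for s in sets]
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        rows = {
            gs.name: [ssgsea_score(expr[c], gs, exponent) for c in expr.columns]
            for gs in gene_sets
        }
    scores = pd.DataFrame(rows, index=expr.columns).T
    if normalize:
        span = np.nanmax(scores.to_numpy()) - np.nanmin(scores.to_numpy())
        if span > 0:
            scores = scores / span
    return scores
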