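"""miRNA-binding-site loss under 3'UTR shortening and competing genes.

When the proximal poly(A) site is used, the 3'UTR sequence distal of the
breakpoint is removed together with any miRNA sites it carries.  Freed
miRNAs may redistribute to other transcripts sharing those sites
("competing genes"), whose expression is expected to move opposite to the
shortened gene's.  The overlap statistic reports what fraction of the lost
miRNAs also target a given competing gene.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .apa_quant import UtrModel
from .diff_screen import masked_pearson

__all__ = ["sites_lost", "find_competing_genes", "shared_mirna_overlap", "OverlapResult"]


def sites_lost(
    sites: pd.DataFrame,
    utr: UtrModel,
    breakpoint: int | None = None,
    wholly_distal: bool = True,
) -> set[str]:
    """miRNAs whose binding is lost upon proximal poly(A)-site usage.

    A miRNA is lost when it has >=1 site wholly distal of the breakpoint
    (site_start >= breakpoint) and no site proximal of it — a site retained
    on the short isoform keeps the miRNA functional.  With
    ``wholly_distal=False`` a site merely straddling the breakpoint
    (truncated on the short isoform) also counts as lost.
    """
    bp = breakpoint if breakpoint is not None else utr.breakpoint
    if bp is None:
        raise ValueError(f"{utr.transcript_id}: breakpoint undefined")
    sub = sites.loc[sites["transcript"] == utr.transcript_id]
    length = len(utr)
    bad = (sub["site_start"] < 0) | (sub["site_end"] > length) | (
        sub["site_start"] >= sub["site_end"]
    )
    if bad.any():
        raise ValueError(
            f"{utr.transcript_id}: {int(bad.sum())} site(s) outside [0, {length})"
        )
    lost: set[str] = set()
    for mirna, grp in sub.groupby("mirna"):
        if wholly_distal:
            distal = grp["site_start"] >= bp
        else:
            distal = grp["site_end"] > bp
        if distal.any() and not (~distal).any():
            lost.add(str(mirna))
    return lost


def find_competing_genes(
    expr: pd.DataFrame,
    target_gene: str,
    event_pdui: pd.Series,
    r_min: float = 0.1,
    p_max: float = 0.010,
) -> pd.DataFrame:
    """Genes anti-correlated with the target and PDUI-positively correlated.

    Returns genes g != target with Pearson r(expr_g, expr_target) < -r_min
    at p < p_max AND r(expr_g, event PDUI) > +r_min at p < p_max
    (pairwise-complete over non-missing PDUI).  Constant genes are skipped.
    """
    if target_gene not in expr.index:
        raise KeyError(f"target gene {target_gene!r} not in expression matrix")
    others = [g for g in expr.index if g != target_gene]
    G = expr.loc[others].to_numpy(dtype=float)
    tgt = expr.loc[target_gene].to_numpy(dtype=float)
    r_t, p_t = masked_pearson(tgt, G)
    x = event_pdui.reindex(expr.columns).to_numpy(dtype=float)
    r_p, p_p = masked_pearson(x, G)
    hit = (
        (r_t < -r_min) & (p_t < p_max) & (r_p > r_min) & (p_p < p_max)
        & ~np.isnan(r_t) & ~np.isnan(r_p)
    )
    out = pd.DataFrame(
        {"gene": np.asarray(others)[hit], "r_expr": r_t[hit], "p_expr": p_t[hit],
         "r_pdui": r_p[hit], "p_pdui": p_p[hit]}
    ).set_index("gene")
    return out.sort_values("r_pdui", ascending=False)


@dataclasses.dataclass(frozen=True)
class OverlapResult:
    n_shared: int
    n_lost: int
    pct: float | None   # None when the lost set is empty (undefined)

    def __iter__(self):
        return iter((self.n_shared, self.n_lost, self.pct))


def shared_mirna_overlap(
    lost: Sequence[str] | set[str],
    targets_of: Mapping[str, set[str]],
    competing_gene: str,
) -> OverlapResult:
    """Fraction of lost miRNAs also predicted to target the competing gene.

    pct = 100 * |lost ∩ targets(competing_gene)| / |lost|, to 2 decimals.
    """
    lost_set = set(lost)
    n_lost = len(lost_set)
    targets = set(targets_of.get(competing_gene, set()))
    n_shared = len(lost_set & targets)
    if n_lost == 0:
        return OverlapResult(0, 0, None)
    return OverlapResult(n_shared, n_lost, round(100.0 * n_shared / n_lost, 2))
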