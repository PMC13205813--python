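"""PDUI quantification from 3'UTR read coverage.

Each 3'UTR is modelled as a mixture of two polyadenylation isoforms: a long
isoform covering the whole 3'UTR at abundance ``alpha_L`` and a short isoform
covering only the region 5' of the proximal poly(A) site (the *breakpoint*)
at abundance ``alpha_S``.  Expected coverage in transcript orientation is

    c(i) = alpha_L + alpha_S * 1[i < breakpoint]

The percentage of distal poly(A)-site usage index is

    PDUI = alpha_L / (alpha_L + alpha_S)   in [0, 1]

Low PDUI means preferential proximal poly(A)-site usage, i.e. 3'UTR
shortening.  The breakpoint is estimated once per event on coverage pooled
across samples; per-sample abundances are then fit with the breakpoint fixed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UtrModel",
    "estimate_breakpoint",
    "estimate_pdui",
    "pdui_matrix",
    "filter_informative_events",
    "filter_expressed_genes",
]


@dataclasses.dataclass
class UtrModel:
    """Strand-aware 3'UTR interval with proximal poly(A)-site geometry.

    Coordinates are genomic, 0-based half-open.  ``breakpoint`` and miRNA
    site offsets are expressed in transcript orientation: offset 0 is the
    3'UTR 5' end, which maps to genomic ``start`` on '+' and to ``end - 1``
    on '-'.
    """

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene: str = ""
    breakpoint: int | None = None
    mirna_sites: list[tuple[str, int, int]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.transcript_id}: empty interval {self.start}-{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if self.breakpoint is not None and not (0 < self.breakpoint < len(self)):
            raise ValueError(
                f"{self.transcript_id}: breakpoint {self.breakpoint} outside (0, {len(self)})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def event_id(self) -> str:
        return f"{self.transcript_id}|{self.gene}|{self.chrom}:{self.start}-{self.end}|{self.strand}"

    def to_transcript(self, genomic_pos: int) -> int:
        """Map a genomic position to a transcript-orientation offset."""
        if not (self.start <= genomic_pos < self.end):
            raise ValueError(f"position {genomic_pos} outside {self.event_id}")
        if self.strand == "+":
            return genomic_pos - self.start
        return self.end - 1 - genomic_pos


def _as_coverage(coverage: Sequence[float]) -> np.ndarray:
    cov = np.asarray(coverage, dtype=float)
    if cov.ndim != 1 or cov.size < 3:
        raise ValueError("coverage must be a 1-D track with >= 3 positions")
    if np.any(cov < 0):
        raise ValueError("coverage contains negative counts")
    return cov


def default_search_window(length: int, edge_frac: float = 0.05) -> tuple[int, int]:
    """Breakpoint search grid excluding ``edge_frac`` of positions per end."""
    pad = max(1, int(round(edge_frac * length)))
    return pad, length - pad


def estimate_breakpoint(
    pooled_coverage: Sequence[float],
    min_offset: int | None = None,
    max_offset: int | None = None,
) -> int | None:
    """Least-squares breakpoint of the two-isoform coverage model.

    Scans every candidate offset ``p`` in ``[min_offset, max_offset)`` and
    returns the one minimising the residual sum of squares of
    ``c(i) ~ alpha_L + alpha_S * 1[i < p]`` with ``alpha_L, alpha_S >= 0``.
    Ties break toward the smallest offset.  Returns None on all-zero
    coverage (no signal to segment).
    """
    cov = _as_coverage(pooled_coverage)
    n = cov.size
    lo, hi = default_search_window(n)
    if min_offset is not None:
        lo = max(lo, int(min_offset))
    if max_offset is not None:
        hi = min(hi, int(max_offset))
    if not (0 < lo < hi <= n):
        raise ValueError(f"invalid search window [{lo}, {hi}) for length {n}")
    total = cov.sum()
    if total == 0:
        return None

    csum = np.cumsum(cov)
    csum2 = np.cumsum(cov * cov)
    p = np.arange(lo, hi)
    s1, s2 = csum[p - 1], csum2[p - 1]           # proximal sums [0, p)
    d1, d2 = total - s1, csum2[-1] - s2           # distal sums [p, n)
    m_prox = s1 / p
    m_dist = d1 / (n - p)
    sse_two = (s2 - s1 * m_prox) + (d2 - d1 * m_dist)
    # alpha_S >= 0 binds when distal mean exceeds proximal: single-mean fit
    sse_one = csum2[-1] - total * total / n
    sse = np.where(m_prox >= m_dist, sse_two, sse_one)
    return int(p[np.argmin(sse)])


def estimate_pdui(
    coverage: Sequence[float],
    breakpoint: int,
    min_total_reads: float = 30,
) -> float:
    """PDUI for one sample at a fixed breakpoint.

    Non-negative least squares on the two-segment design has the closed
    form alpha_L = mean distal coverage, alpha_S = mean proximal − mean
    distal; when the distal mean exceeds the proximal mean the alpha_S >= 0
    constraint binds and the fit collapses to the single long isoform
    (PDUI = 1).  Returns NaN (missing) when total reads < ``min_total_reads``
    or the fitted abundances are both zero.
    """
    cov = _as_coverage(coverage)
    if not (0 < breakpoint < cov.size):
        raise ValueError(f"breakpoint {breakpoint} outside (0, {cov.size})")
    if cov.sum() < min_total_reads:
        return float("nan")
    m_prox = cov[:breakpoint].mean()
    m_dist = cov[breakpoint:].mean()
    if m_dist > m_prox:
        alpha_l, alpha_s = cov.mean(), 0.0
    else:
        alpha_l, alpha_s = m_dist, m_prox - m_dist
    denom = alpha_l + alpha_s
    if denom <= 0:
        return float("nan")
    return float(alpha_l / denom)


def pdui_matrix(
    coverage: Mapping[str, Mapping[str, Sequence[float]]],
    utrs: Mapping[str, UtrModel] | Iterable[UtrModel],
    min_total_reads: float = 30,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Events x samples PDUI matrix from per-sample coverage tracks.

    ``coverage`` maps sample -> transcript_id -> coverage track (transcript
    orientation).  Breakpoints are estimated on coverage summed across
    samples, then PDUI is fit per sample with the shared breakpoint.
    Returns the matrix (index = event id) and the breakpoint per event.
    """
    if not isinstance(utrs, Mapping):
        utrs = {u.transcript_id: u for u in utrs}
    samples = list(coverage)
    rows, index, breakpoints = [], [], {}
    for tid, utr in utrs.items():
        tracks = [np.asarray(coverage[s][tid], dtype=float) for s in samples if tid in coverage[s]]
        if not tracks:
            continue
        pooled = np.sum(tracks, axis=0)
        bp = estimate_breakpoint(pooled)
        if bp is None:
            continue
        breakpoints[utr.event_id] = bp
        vals = [
            estimate_pdui(coverage[s][tid], bp, min_total_reads) if tid in coverage[s] else np.nan
            for s in samples
        ]
        rows.append(vals)
        index.append(utr.event_id)
    mat = pd.DataFrame(rows, index=index, columns=samples, dtype=float)
    mat.index.name = "event"
    return mat, breakpoints


def filter_informative_events(
    pdui: pd.DataFrame,
    max_missing_frac: float = 0.60,
    max_constant_frac: float = 0.40,
) -> pd.DataFrame:
    """Keep informative APA events.

    An event is informative when its missing-value fraction is below
    ``max_missing_frac`` and the fraction of non-missing entries exactly 0
    or 1 (single-isoform calls) is below ``max_constant_frac``.
    """
    if pdui.empty:
        raise ValueError("empty PDUI matrix")
    vals = pdui.to_numpy(dtype=float)
    missing = np.isnan(vals)
    miss_frac = missing.mean(axis=1)
    n_obs = (~missing).sum(axis=1)
    constant = (~missing) & ((vals == 0.0) | (vals == 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        const_frac = np.where(n_obs > 0, constant.sum(axis=1) / np.maximum(n_obs, 1), 1.0)
    keep = (miss_frac < max_missing_frac) & (const_frac < max_constant_frac)
    return pdui.loc[keep]


def filter_expressed_genes(expr: pd.DataFrame, min_mean: float = 1.0) -> pd.DataFrame:
    """Drop lowly expressed genes (row mean strictly below ``min_mean``)."""
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    return expr.loc[expr.mean(axis=1) >= min_mean]
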