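"""Single-cell APA mode: per-cell PDUI, detection filter, group comparison.

Breakpoints are estimated on pseudo-bulk (cell-summed) coverage and shared
across cells; per-cell PDUI then uses the bulk estimator with a low read
floor.  Given the sparsity of 3' end-capture data, conclusions are drawn at
the group level: events detected in more than ``min_cells`` cells in BOTH
the hypoxic and normoxic groups are compared with the Wilcoxon rank-sum
test.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .apa_quant import UtrModel, estimate_breakpoint, estimate_pdui

__all__ = ["per_cell_pdui", "pseudobulk_breakpoints", "filter_sc_events", "compare_group_pdui"]

HYPOXIC, NORMOXIC = "hypoxic", "normoxic"


def pseudobulk_breakpoints(
    coverage: Mapping[str, Mapping[str, np.ndarray]],
    utrs: Mapping[str, UtrModel],
) -> dict[str, int]:
    """Breakpoint per transcript from coverage summed over all cells."""
    bps: dict[str, int] = {}
    for tid, utr in utrs.items():
        tracks = [np.asarray(c[tid], dtype=float) for c in coverage.values() if tid in c]
        if not tracks:
            continue
        bp = estimate_breakpoint(np.sum(tracks, axis=0))
        if bp is not None:
            bps[tid] = bp
    return bps


def per_cell_pdui(
    coverage: Mapping[str, Mapping[str, np.ndarray]],
    utrs: Mapping[str, UtrModel],
    breakpoints: Mapping[str, int],
    min_reads: float = 5,
) -> pd.DataFrame:
    """Events x cells PDUI matrix with the shared per-event breakpoint.

    A cell x event entry is missing (NaN) when the event is absent from the
    cell or its reads fall below ``min_reads``.
    """
    cells = list(coverage)
    rows, index = [], []
    for tid, utr in utrs.items():
        if tid not in breakpoints:
            continue
        bp = breakpoints[tid]
        vals = [
            estimate_pdui(coverage[c][tid], bp, min_reads) if tid in coverage[c] else np.nan
            for c in cells
        ]
        rows.append(vals)
        index.append(utr.event_id)
    mat = pd.DataFrame(rows, index=index, columns=cells, dtype=float)
    mat.index.name = "event"
    return mat


def filter_sc_events(
    matrix: pd.DataFrame, labels: pd.Series, min_cells: int = 20
) -> pd.DataFrame:
    """Keep events detected in MORE than ``min_cells`` cells in both groups.

    Detection means a non-missing PDUI value; the threshold is strict
    (exactly ``min_cells`` cells is not enough).
    """
    labels = labels.reindex(matrix.columns)
    obs = matrix.notna().to_numpy()
    hyp = (labels == HYPOXIC).to_numpy()
    norm = (labels == NORMOXIC).to_numpy()
    n_h = obs[:, hyp].sum(axis=1)
    n_n = obs[:, norm].sum(axis=1)
    return matrix.loc[(n_h > min_cells) & (n_n > min_cells)]


def compare_group_pdui(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-event Wilcoxon rank-sum test, hypoxic vs normoxic cells.

    Returns per-event group means, medians, the rank-sum p-value and group
    cell counts; events with fewer than 2 non-missing cells in a group or
    with all values identical are skipped (NaN p).
    """
    labels = labels.reindex(matrix.columns)
    hyp = matrix.loc[:, (labels == HYPOXIC).to_numpy()]
    norm = matrix.loc[:, (labels == NORMOXIC).to_numpy()]
    rows = []
    for ev in matrix.index:
        a = hyp.loc[ev].dropna().to_numpy()
        b = norm.loc[ev].dropna().to_numpy()
        if a.size < 2 or b.size < 2 or (np.unique(np.concatenate([a, b])).size < 2):
            p = np.nan
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append((
            float(a.mean()) if a.size else np.nan,
            float(b.mean()) if b.size else np.nan,
            float(np.median(a)) if a.size else np.nan,
            float(np.median(b)) if b.size else np.nan,
            p, a.size, b.size,
        ))
    out = pd.DataFrame(
        rows, index=matrix.index,
        columns=["mean_hypoxic", "mean_normoxic", "median_hypoxic",
                 "median_normoxic", "p", "n_hypoxic", "n_normoxic"],
    )
    out.index.name = "event"
    return out
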