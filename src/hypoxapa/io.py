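"""Plain-text readers/writers for the pipeline's exchange formats.

Formats: 4-column bedgraph (0-based half-open) coverage, BED6 3'UTR
annotation, GMT gene sets, TSV matrices (first column feature ID, header =
sample IDs, NA = missing), TSV clinical / miRNA-site / target tables.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .apa_quant import UtrModel

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_bed6",
    "write_bed6",
    "read_bedgraph",
    "write_bedgraph",
    "read_coverage_dir",
    "write_coverage_dir",
    "read_sites_table",
    "read_targets_table",
]


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """TSV matrix: first column feature ID, columns samples, NA = missing."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """GMT: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


def write_bed6(utrs: Iterable[UtrModel], path: str | os.PathLike) -> None:
    """BED6 with name = transcript_id|gene and score = breakpoint offset."""
    with open(path, "w") as fh:
        for u in utrs:
            name = f"{u.transcript_id}|{u.gene}"
            score = u.breakpoint if u.breakpoint is not None else 0
            fh.write(f"{u.chrom}\t{u.start}\t{u.end}\t{name}\t{score}\t{u.strand}\n")


def read_bed6(path: str | os.PathLike) -> dict[str, UtrModel]:
    utrs: dict[str, UtrModel] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.split()[:6]
            tid, _, gene = name.partition("|")
            bp = int(score) or None
            utrs[tid] = UtrModel(tid, chrom, int(start), int(end), strand, gene, bp)
    return utrs


def write_bedgraph(
    coverage: Mapping[str, np.ndarray],
    utrs: Mapping[str, UtrModel],
    path: str | os.PathLike,
) -> None:
    """Per-sample bedgraph; transcript-orientation tracks mapped to genome.

    Adjacent equal-valued positions are merged into one interval.
    """
    with open(path, "w") as fh:
        for tid, track in coverage.items():
            u = utrs[tid]
            vals = np.asarray(track)
            genomic = vals if u.strand == "+" else vals[::-1]
            # run-length encode
            change = np.flatnonzero(np.diff(genomic)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [genomic.size]])
            for s, e in zip(starts, ends):
                v = genomic[s]
                if v == 0:
                    continue
                fh.write(f"{u.chrom}\t{u.start + s}\t{u.start + e}\t{v:g}\n")


def read_bedgraph(
    path: str | os.PathLike, utrs: Mapping[str, UtrModel]
) -> dict[str, np.ndarray]:
    """Read a bedgraph back into transcript-orientation tracks per UTR.

    Intervals are intersected with each annotated 3'UTR; positions not
    covered by any interval get 0.
    """
    tracks = {tid: np.zeros(len(u)) for tid, u in utrs.items()}
    by_chrom: dict[str, list[tuple[str, UtrModel]]] = {}
    for tid, u in utrs.items():
        by_chrom.setdefault(u.chrom, []).append((tid, u))
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split()[:4]
            s, e, v = int(s), int(e), float(v)
            for tid, u in by_chrom.get(chrom, []):
                lo, hi = max(s, u.start), min(e, u.end)
                if lo < hi:
                    tracks[tid][lo - u.start : hi - u.start] = v
    for tid, u in utrs.items():
        if u.strand == "-":
            tracks[tid] = tracks[tid][::-1].copy()
    return tracks


def write_coverage_dir(
    coverage: Mapping[str, Mapping[str, np.ndarray]],
    utrs: Mapping[str, UtrModel],
    directory: str | os.PathLike,
) -> None:
    os.makedirs(directory, exist_ok=True)
    for sample, tracks in coverage.items():
        write_bedgraph(tracks, utrs, os.path.join(directory, f"{sample}.bedgraph"))


def read_coverage_dir(
    directory: str | os.PathLike, utrs: Mapping[str, UtrModel]
) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    for fname in sorted(os.listdir(directory)):
        if fname.endswith(".bedgraph"):
            out[fname[: -len(".bedgraph")]] = read_bedgraph(
                os.path.join(directory, fname), utrs
            )
    return out


def read_sites_table(path: str | os.PathLike) -> pd.DataFrame:
    """miRNA site table: mirna, transcript, site_start, site_end (UTR offsets)."""
    df = pd.read_csv(path, sep="\t")
    required = {"mirna", "transcript", "site_start", "site_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"site table needs columns {sorted(required)}")
    return df


def read_targets_table(path: str | os.PathLike) -> dict[str, set[str]]:
    """Gene -> miRNA target annotation from a two-column TSV (gene, mirna)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "mirna"}.issubset(df.columns):
        raise ValueError("targets table needs columns ['gene', 'mirna']")
    return {g: set(sub["mirna"]) for g, sub in df.groupby("gene")}
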