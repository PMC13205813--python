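"""Synthetic cohort generator with planted hypoxia ground truth.

Emulates every input the analysis consumes: a genes x samples expression
matrix with an upregulated hypoxia program in a planted hypoxic subgroup,
an events x samples PDUI matrix with a downward shift for affected events
in hypoxic samples, per-sample 3'UTR coverage tracks consistent with the
true PDUI, survival/stage/treatment clinical data with worse outcome for
hypoxic samples, miRNA site annotations on the 3'UTRs, IC50 drug response
coupled to a designated gene's expression, and sparse dropout-censored
per-cell coverage for the single-cell mode.

Generative choices: expression is log-normal (base-2 log means ~ N(2, 1),
sample noise sd 0.8) with the hypoxia program shifted by ``hypoxia_effect``
log2 units in hypoxic samples; observed PDUI is Beta-distributed around the
truth with concentration ``noise_concentration``; coverage noise is Poisson
per position; survival is exponential with the hypoxic hazard multiplied by
``hazard_ratio`` and uniform censoring.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .apa_quant import UtrModel

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "SyntheticCells",
    "simulate_cohort",
    "simulate_utr_coverage",
    "simulate_single_cells",
]

HYPOXIC, NORMOXIC = "hypoxic", "normoxic"


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Generator parameters; identical config + seed is bit-reproducible."""

    n_samples: int = 200
    n_genes: int = 1000
    n_events: int = 200
    frac_hypoxic: float = 0.5
    hypoxia_effect: float = 1.0   # log2 shift of the hypoxia program
    pdui_shift: float = 0.3       # mean PDUI decrease for affected events in hypoxia
    depth: float = 50.0           # mean reads per 3'UTR position
    dropout: float = 0.0          # per-cell per-event missing probability
    seed: int = 0
    # secondary structure
    n_affected: int = 12
    n_signature_genes: int = 50
    n_mirnas: int = 60
    utr_length: int = 500
    breakpoint_frac: float = 0.4
    biological_concentration: float = 25.0  # Beta precision of per-sample true PDUI
    noise_concentration: float = 80.0       # Beta precision of observed PDUI
    missing_rate: float = 0.05
    hazard_ratio: float = 2.0
    baseline_hazard: float = 1.0 / 36.0
    censor_max: float = 120.0
    stage_advanced_p: tuple[float, float] = (0.30, 0.60)  # (normoxic, hypoxic)
    ic50_coupling: float = -0.6
    competition_strength: float = 0.6
    make_coverage: bool = False
    n_cells: int = 500
    cell_depth: float = 1.0       # mean reads per position per cell

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_events", "n_affected",
                     "n_signature_genes", "n_mirnas", "utr_length", "n_cells"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_hypoxic", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_affected > self.n_events:
            raise ValueError("n_affected exceeds n_events")
        # gene layout: hypoxia program | EMT | glycolysis | event genes | competitor
        if self.n_genes < self.n_signature_genes + 60 + self.n_events + 1:
            raise ValueError(
                "n_genes too small for signature sets, event genes and competitor"
            )
        if not 0 < self.breakpoint_frac < 1:
            raise ValueError("breakpoint_frac must be in (0, 1)")


@dataclasses.dataclass
class SyntheticCohort:
    config: SimConfig
    expression: pd.DataFrame            # genes x samples, non-negative
    pdui_true: pd.DataFrame             # events x samples, in [0, 1]
    pdui_observed: pd.DataFrame         # Beta-noised, NaN = missing
    labels_true: pd.Series              # hypoxic / normoxic per sample
    survival: pd.DataFrame              # sample, time, event, stage, treated
    ic50: pd.Series
    utrs: dict[str, UtrModel]
    mirna_sites: pd.DataFrame           # mirna, transcript, site_start, site_end
    mirna_targets: dict[str, set[str]]  # gene -> targeting miRNAs
    gene_sets: dict[str, list[str]]
    affected_events: list[str]          # event ids with planted PDUI shift
    target_event: str                   # focal APA event for competition/drug analyses
    target_gene: str
    competitor_gene: str
    coverage: dict[str, dict[str, np.ndarray]] | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)


def simulate_utr_coverage(
    pdui_true: float,
    utr: UtrModel,
    depth: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Poisson coverage track for one sample over one 3'UTR.

    The long isoform (abundance depth * pdui_true) covers the whole 3'UTR;
    the short isoform (depth * (1 - pdui_true)) covers positions proximal
    of the breakpoint, so expected coverage is depth proximally and
    depth * pdui_true distally.
    """
    if not 0.0 <= pdui_true <= 1.0:
        raise ValueError("pdui_true must be in [0, 1]")
    if utr.breakpoint is None:
        raise ValueError(f"{utr.transcript_id}: breakpoint undefined")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    length = len(utr)
    expected = np.full(length, depth * pdui_true)
    expected[: utr.breakpoint] = depth
    return rng.poisson(expected).astype(float)


def _make_utrs(cfg: SimConfig, gene_of_event: list[str]) -> dict[str, UtrModel]:
    utrs = {}
    bp = int(round(cfg.breakpoint_frac * cfg.utr_length))
    for k, gene in enumerate(gene_of_event):
        tid = f"T{k:04d}"
        start = 1000 + k * (cfg.utr_length + 200)
        strand = "+" if k % 2 == 0 else "-"
        utrs[tid] = UtrModel(
            tid, "chr1", start, start + cfg.utr_length, strand, gene=gene, breakpoint=bp
        )
    return utrs


def _mirna_annotation(
    cfg: SimConfig, utrs: Mapping[str, UtrModel], rng: np.random.Generator,
    target_gene: str, competitor_gene: str,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Random miRNA sites along each UTR + a gene->miRNA target map.

    Half the miRNAs of the focal transcript sit wholly distal of the
    breakpoint (lost on shortening); the competitor gene is annotated as a
    target of a subset of those plus background miRNAs.
    """
    mirnas = [f"miR-{i:03d}" for i in range(cfg.n_mirnas)]
    rows = []
    site_len = 7
    focal_tid = next(tid for tid, u in utrs.items() if u.gene == target_gene)
    for tid, utr in utrs.items():
        bp = utr.breakpoint
        if tid == focal_tid:
            # dense annotation on the focal 3'UTR: over half the miRNAs sit
            # wholly distal of the proximal site and are lost on shortening
            chosen = rng.choice(cfg.n_mirnas, size=min(20, cfg.n_mirnas), replace=False)
            for j, m in enumerate(chosen):
                if j % 3 == 2:  # proximal site: retained on the short isoform
                    start = int(rng.integers(0, max(1, bp - site_len)))
                else:
                    start = int(rng.integers(bp, len(utr) - site_len))
                rows.append((mirnas[m], tid, start, start + site_len))
            continue
        n_sites = rng.integers(1, 4)
        for m in rng.choice(cfg.n_mirnas, size=n_sites, replace=False):
            start = int(rng.integers(0, len(utr) - site_len))
            rows.append((mirnas[m], tid, start, start + site_len))
    sites = pd.DataFrame(rows, columns=["mirna", "transcript", "site_start", "site_end"])
    targets: dict[str, set[str]] = {}
    for tid, utr in utrs.items():
        targets.setdefault(utr.gene, set()).update(
            sites.loc[sites.transcript == tid, "mirna"]
        )
    # competitor shares a subset of the focal gene's miRNAs
    focal = sorted(targets.get(target_gene, set()))
    shared = set(rng.choice(focal, size=max(1, len(focal) // 2), replace=False)) if focal else set()
    background = set(rng.choice(mirnas, size=cfg.n_mirnas // 4, replace=False))
    targets[competitor_gene] = shared | background
    return sites, targets


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort with planted hypoxia structure."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    n_hyp = int(round(cfg.frac_hypoxic * cfg.n_samples))
    is_hyp = np.zeros(cfg.n_samples, dtype=bool)
    is_hyp[rng.permutation(cfg.n_samples)[:n_hyp]] = True
    labels = pd.Series(np.where(is_hyp, HYPOXIC, NORMOXIC), index=samples, name="label")

    # ---- gene layout ------------------------------------------------------
    n_sig = cfg.n_signature_genes
    hyp_genes = [f"HYPg{i:03d}" for i in range(n_sig)]
    emt_genes = [f"EMTg{i:03d}" for i in range(30)]
    gly_genes = [f"GLYg{i:03d}" for i in range(30)]
    event_genes = [f"G{i:04d}" for i in range(cfg.n_events)]
    competitor = "COMPET01"
    n_rest = cfg.n_genes - n_sig - 60 - cfg.n_events - 1
    rest = [f"BKGg{i:04d}" for i in range(n_rest)]
    genes = hyp_genes + emt_genes + gly_genes + event_genes + [competitor] + rest

    # ---- expression -------------------------------------------------------
    base = rng.normal(2.0, 1.0, size=len(genes))
    log2e = base[:, None] + rng.normal(0.0, 0.8, size=(len(genes), cfg.n_samples))
    gidx = {g: i for i, g in enumerate(genes)}
    for g in hyp_genes:
        log2e[gidx[g], is_hyp] += cfg.hypoxia_effect
    for g in emt_genes + gly_genes:
        log2e[gidx[g], is_hyp] += 0.5 * cfg.hypoxia_effect

    # ---- PDUI truth and observation --------------------------------------
    event_base = rng.uniform(0.35, 0.85, size=cfg.n_events)
    pdui_mean = np.tile(event_base[:, None], (1, cfg.n_samples))
    affected_idx = np.arange(cfg.n_affected)
    pdui_mean[np.ix_(affected_idx, np.flatnonzero(is_hyp))] -= cfg.pdui_shift
    pdui_mean = np.clip(pdui_mean, 0.05, 0.95)
    # tumors vary continuously in poly(A)-site usage around the group mean:
    # Beta keeps the exact group mean while bounding the fraction in (0, 1)
    nu = cfg.biological_concentration
    pdui_t = rng.beta(pdui_mean * nu, (1.0 - pdui_mean) * nu)
    pdui_t = np.clip(pdui_t, 0.02, 0.98)
    kappa = cfg.noise_concentration
    pdui_o = rng.beta(pdui_t * kappa, (1.0 - pdui_t) * kappa)
    pdui_o[rng.random(pdui_o.shape) < cfg.missing_rate] = np.nan

    utrs = _make_utrs(cfg, event_genes)
    event_ids = [u.event_id for u in utrs.values()]
    pdui_true = pd.DataFrame(pdui_t, index=event_ids, columns=samples)
    pdui_obs = pd.DataFrame(pdui_o, index=event_ids, columns=samples)
    affected_events = [event_ids[i] for i in affected_idx]

    # ---- competition structure (focal event = first affected) ------------
    target_event = event_ids[0]
    target_gene = event_genes[0]
    z = pdui_t[0] - pdui_t[0].mean()
    z = z / (z.std() + 1e-12)
    # proximal usage (low PDUI) raises the focal gene's own expression;
    # the competitor moves with PDUI (miRNAs recaptured by the long isoform)
    log2e[gidx[target_gene]] += -cfg.competition_strength * z
    log2e[gidx[competitor]] += cfg.competition_strength * z
    expression = pd.DataFrame(np.power(2.0, log2e), index=genes, columns=samples)

    # ---- clinical ---------------------------------------------------------
    hazard = cfg.baseline_hazard * np.where(is_hyp, cfg.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, cfg.censor_max, size=cfg.n_samples)
    time = np.minimum(t_event, t_cens)
    observed = (t_event <= t_cens).astype(int)
    p_adv = np.where(is_hyp, cfg.stage_advanced_p[1], cfg.stage_advanced_p[0])
    stage = np.where(rng.random(cfg.n_samples) < p_adv, "advanced", "early")
    treated = rng.integers(0, 2, size=cfg.n_samples)
    survival = pd.DataFrame(
        {"sample": samples, "time": time, "event": observed,
         "stage": stage, "treated": treated}
    ).set_index("sample")

    # ---- drug response ----------------------------------------------------
    ze = log2e[gidx[target_gene]] - log2e[gidx[target_gene]].mean()
    ze = ze / (ze.std() + 1e-12)
    ic50 = pd.Series(
        3.0 + cfg.ic50_coupling * ze + rng.normal(0.0, 0.5, cfg.n_samples),
        index=samples, name="ic50",
    )

    sites, targets = _mirna_annotation(cfg, utrs, rng, target_gene, competitor)

    gene_sets = {
        "HYPOXIA": hyp_genes[: max(2, int(0.8 * n_sig))],
        "EMT": emt_genes,
        "GLYCOLYSIS": gly_genes,
        "WINTER": sorted(rng.choice(hyp_genes, size=min(30, n_sig), replace=False)),
        "BUFFA": sorted(rng.choice(hyp_genes, size=min(30, n_sig), replace=False)),
        "RAGNUM": sorted(rng.choice(hyp_genes, size=min(30, n_sig), replace=False)),
    }

    coverage = None
    if cfg.make_coverage:
        coverage = {}
        tids = list(utrs)
        for j, s in enumerate(samples):
            coverage[s] = {
                tid: simulate_utr_coverage(pdui_t[k, j], utrs[tid], cfg.depth, rng)
                for k, tid in enumerate(tids)
            }

    return SyntheticCohort(
        config=cfg, expression=expression, pdui_true=pdui_true,
        pdui_observed=pdui_obs, labels_true=labels, survival=survival,
        ic50=ic50, utrs=utrs, mirna_sites=sites, mirna_targets=targets,
        gene_sets=gene_sets, affected_events=affected_events,
        target_event=target_event, target_gene=target_gene,
        competitor_gene=competitor, coverage=coverage,
    )


@dataclasses.dataclass
class SyntheticCells:
    coverage: dict[str, dict[str, np.ndarray]]  # cell -> transcript -> track
    labels: pd.Series                           # hypoxic / normoxic per cell
    pdui_true: pd.DataFrame                     # events x {hypoxic, normoxic}
    utrs: dict[str, UtrModel]


def simulate_single_cells(config: SimConfig) -> SyntheticCells:
    """Sparse per-cell coverage with dropout, emulating 3' end-capture data.

    Cells inherit their group's true PDUI (affected events shifted down in
    hypoxic cells); each cell x event track is Poisson at ``cell_depth``
    and entirely absent with probability ``dropout``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    event_genes = [f"G{i:04d}" for i in range(cfg.n_events)]
    utrs = _make_utrs(cfg, event_genes)
    tids = list(utrs)
    base = rng.uniform(0.35, 0.85, size=cfg.n_events)
    p_norm = base
    p_hyp = base.copy()
    p_hyp[: cfg.n_affected] = np.clip(p_hyp[: cfg.n_affected] - cfg.pdui_shift, 0.02, 0.98)
    cells = [f"C{i:05d}" for i in range(cfg.n_cells)]
    n_hyp = int(round(cfg.frac_hypoxic * cfg.n_cells))
    is_hyp = np.zeros(cfg.n_cells, dtype=bool)
    is_hyp[rng.permutation(cfg.n_cells)[:n_hyp]] = True
    labels = pd.Series(np.where(is_hyp, HYPOXIC, NORMOXIC), index=cells, name="label")
    coverage: dict[str, dict[str, np.ndarray]] = {}
    for j, cell in enumerate(cells):
        p = p_hyp if is_hyp[j] else p_norm
        tracks = {}
        for k, tid in enumerate(tids):
            if rng.random() < cfg.dropout:
                continue
            tracks[tid] = simulate_utr_coverage(p[k], utrs[tid], cfg.cell_depth, rng)
        coverage[cell] = tracks
    pdui_true = pd.DataFrame(
        {"hypoxic": p_hyp, "normoxic": p_norm},
        index=[utrs[t].event_id for t in tids],
    )
    return SyntheticCells(coverage=coverage, labels=labels, pdui_true=pdui_true, utrs=utrs)
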