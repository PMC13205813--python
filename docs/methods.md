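# Methods

## Two-isoform coverage model and PDUI

A 3'UTR with one proximal and one distal poly(A) site produces two
isoforms: the long isoform covers the whole 3'UTR at abundance α_L, the
short isoform covers positions 5' of the proximal site (the *breakpoint*)
at abundance α_S. Expected per-position coverage in transcript orientation
is c(i) = α_L + α_S·1[i < breakpoint], and the percentage of distal usage
is PDUI = α_L/(α_L+α_S).

The breakpoint is estimated once per event on coverage **pooled across
samples** (it is a property of the transcript, not the sample, and pooling
stabilises the change point); per-sample abundances are then fit with the
breakpoint fixed. For a fixed breakpoint, the non-negative least-squares
fit has a closed form: α_L = mean distal coverage, α_S = mean proximal −
mean distal, collapsing to the single long isoform (PDUI = 1) when the
distal mean exceeds the proximal mean. Numerical choices:

- the breakpoint search grid excludes 5% of positions at each UTR end,
  avoiding degenerate one-segment fits; ties break to the smallest offset
  so output is deterministic;
- a sample's PDUI is *missing* when the event's total reads fall below
  `min_total_reads` (default 30; the two-component fit is unstable below a
  coverage floor, and missingness is otherwise undefined for this model);
- PDUI is never log-transformed; group effect sizes are handled in the
  differential layer.

Informative events have <60% missing entries and <40% of observed values
exactly 0 or 1 (the constant-fraction is computed over non-missing
entries); genes with mean expression below 1 (UQN-like scale) are dropped,
with retention at exactly 1 since the exclusion is a strict inequality.

## Phenotype assignment

Two classifiers are combined. The signature-guided **NC score** ranks
samples per gene (average ranks on ties; rank > n/2 counts as the top
half, so the rule is deterministic and symmetric) and sums ±1
contributions over the signature; score sign gives hypoxic (>0), normoxic
(<0) or mixed (=0). With several signatures (e.g. Winter/Buffa/Ragnum) the
default combination is **unanimity** — all signatures must agree on
hypoxic or normoxic, anything else is mixed — which is the conservative
choice for a high-confidence consensus; majority voting is available.

The data-driven **NMF method** factorises the non-negative expression
matrix (the pipeline uses log2(x+1), which tames the heavy lognormal tail
while staying non-negative) with multiplicative updates and a Frobenius
objective from `restarts` random initialisations, assigns each sample to
its dominant factor, accumulates a co-clustering consensus matrix, and
cuts its average-linkage dendrogram into k groups. k is a configuration
input (2 for patient-style cohorts, 3 where an intermediate group is
expected); no automatic rank selection is attempted. Clusters are labelled
by their **mean** per-sample hypoxia enrichment score (one scoring engine
everywhere): highest mean → hypoxic, lowest → normoxic, others mixed, ties
broken toward the lower cluster index and flagged.

The final label keeps a sample only when both methods concordantly call
hypoxic or normoxic; everything else is mixed and excluded from two-group
analyses.

## Enrichment scoring

A single ssGSEA-style scorer serves bulk validation and single-cell
scoring: genes are ordered by decreasing expression and the score is the
integrated difference between the rank-weighted (rank^exponent, default
0.25) in-set cumulative distribution and the uniform out-of-set cumulative
distribution, normalised by the score range when scoring a matrix. Because
weights are ranks (average on ties, gene-name tie-break in the ordering),
the score is *exactly* invariant to monotone transforms of a sample's
expression — the property the tests rely on. This deliberately skips the
kernel-density step of GSVA; both uses here are relative comparisons
between samples, for which the rank running-sum is sufficient.

## Differential screen

Per feature, Student's (equal-variance) t-test between hypoxic and
normoxic samples (Welch available), with log2FC defined on PDUI as the
pseudocounted group-mean ratio log2((m_h+0.01)/(m_n+0.01)) — PDUI is a
fraction, so a pseudocount keeps the printed |log2FC| > 0.050 threshold
finite and meaningful. Features with fewer than two observations per group
or zero variance are skipped and counted. BH-adjusted q-values are
reported but the screen itself uses nominal P, matching the genome-wide
exploratory design. Under the null the joint flag rate (P < 0.010 AND
|log2FC| > 0.050) is necessarily at or below the marginal 0.010 — the
effect-size cut only removes flags — so calibration is asserted as
flag rate ≤ 0.010 within binomial error plus KS-uniformity of the
p-values. The candidate screen then keeps differential events whose PDUI
correlates (Pearson, pairwise-complete over non-missing entries) with at
least one hypoxia-related gene at |r| > 0.1, P < 0.010; the
hypoxia-related gene list is a user-supplied set (literature integration
is not a computational step).

## Hypoxia signature score

Candidates enter stratified 10-fold cross-validation. Within each fold an
L1-penalised logistic regression selects events, with the penalty chosen
by inner 3-fold CV under the **1-SE rule** (strongest penalty whose mean
validation log-loss is within one standard error of the best) — the
standard sparse-selection compromise; choosing the loss-minimising penalty
alone tends to keep everything, and AUC-based selection is degenerate once
folds separate. Selection frequency over the outer folds is reported per
event; events at frequency ≥ 0.5 form the final set, refit without penalty
on all non-mixed samples. Missing PDUI is imputed with the event's
training mean (fold-wise during CV, overall for the final refit). The HSS
is the coefficient-weighted sum of the selected events' PDUI values; the
intercept is stored but excluded from the score, which is used as a
relative quantity (its displayed form has no constant). High/low HSS is
split at the median for survival. If nothing is stably selected (null
data), an empty model is returned with its fold-wise AUCs, rather than an
error. The AUC is the rank statistic P(hypoxic sample outranks normoxic),
ties counting ½.

## miRNA-site loss and competing genes

A miRNA is *lost* on 3'UTR shortening when it has at least one site wholly
distal of the breakpoint and none proximal: a site retained on the short
isoform keeps the miRNA functional, and a site merely straddling the
breakpoint is treated as retained by default (truncated sites are of
uncertain function; `wholly_distal=False` switches to counting them as
lost). This rule is monotone: moving the breakpoint proximally never
shrinks the lost set. Competing genes are genes anti-correlated with the
shortened gene's expression (r < −0.1, P < 0.010) and positively
correlated with the event's PDUI (r > +0.1, P < 0.010). The overlap
statistic reports 100 × |lost ∩ targets(competing gene)| / |lost| to two
decimals, undefined (and flagged) on an empty lost set; miRNAs are counted
as distinct identifiers in the input table.

## Survival and drug response

Kaplan–Meier, the two-group log-rank test and univariate Cox regression
are delegated to lifelines behind the module interface; Cox ties are
handled by Efron's method (lifelines' implementation; covariates here are
continuous, so event-time ties in the partial likelihood are rare and the
Efron/Breslow difference is negligible). All high/low dichotomisations use
the median. Drug response is consumed as a per-sample IC50 table
(predicted or measured); association is Pearson correlation plus a
median-split t-test, and treatment-stratified survival runs the high/low
log-rank within treated and untreated subsets separately plus a Cox fit of
the continuous stratifier within the treated subset. Degenerate cells
(empty strata, zero-event groups, constant covariates) are skipped with
warnings or raised as errors, as documented per function.

## Single-cell mode

Breakpoints come from pseudo-bulk (cell-summed) coverage — sparse 3'
end-capture data cannot support per-cell change points — and per-cell
PDUI uses the bulk estimator with a low read floor (default 5 reads).
Events must be detected (non-missing PDUI) in **more than** 20 cells in
both the hypoxic and normoxic groups; detection-by-any-read was the
alternative reading, and the stricter non-missing rule is used. Group
comparison is the Wilcoxon rank-sum test per event; conclusions are drawn
from group-level distributions, not isolated per-cell calls.

## Synthetic cohorts

The generator emulates the structure of a hypoxia-phenotyped NSCLC cohort:

- **Expression** is log-normal (log2 means ~ N(2,1), per-sample noise sd
  0.8 — heavy-tailed like RNA-seq abundances without count modelling). A
  50-gene hypoxia program is shifted up by `hypoxia_effect` (default 1.0
  log2 units) in the hypoxic fraction (default 0.5 of 200 samples); EMT
  and glycolysis programs shift by half that, giving the validation
  signatures something to detect.
- **PDUI**: each event has a baseline distal usage ~ U(0.35, 0.85);
  affected events (default 12) are shifted down by `pdui_shift` (default
  0.3) in hypoxic samples. The per-sample true PDUI is Beta-distributed
  around the group mean (concentration 25, i.e. sd ≈ 0.08–0.10) — tumors
  vary continuously in poly(A)-site usage, and this heterogeneity is why a
  multi-event signature outperforms any single event, as in real cohorts
  where signature AUCs are high but not 1.0. The Beta keeps the exact
  group mean, so the planted difference equals `pdui_shift` without
  clipping bias. Observed PDUI adds Beta measurement noise (concentration
  80, matching the estimator's error at depth ~50) and 5% missingness.
- **Coverage** is Poisson per position (the simplest count model for read
  pile-ups) with the two-isoform expectation, at `depth` reads/position;
  per-cell coverage is the same at `cell_depth` with whole-event dropout.
- **Survival** is exponential with the hypoxic hazard multiplied by
  `hazard_ratio` (default 2.0) and uniform censoring — closed-form
  recovery checks for the log-rank/Cox layer. Advanced stage is more
  likely for hypoxic samples (0.60 vs 0.30); treatment is a fair coin.
- **IC50** is coupled to the focal gene's (log) expression with
  coefficient −0.6 plus noise; the focal gene's expression itself moves
  against its event's PDUI (proximal usage raises expression), and a
  designated competitor gene moves with PDUI, with a dense miRNA site
  annotation on the focal 3'UTR (about two-thirds of its sites wholly
  distal of the breakpoint).

What the generator does **not** emulate: raw reads and alignment
artifacts, batch effects, correlated gene–gene co-expression structure
beyond the planted programs, >2 poly(A) sites per UTR, copy-number or
spatial structure. Passing tests therefore demonstrate the correctness and
calibration of the estimators and the recoverability of planted effects
under realistic noise — not performance on real tumor data.

## Problem sizes and determinism

Default test and acceptance runs use 200 samples, 38–200 events, depth 50,
500-nt UTRs, 300 cells and 10–20 replicate seeds per Monte-Carlo check —
sizes at which every calibration quantity is stable to well within its
asserted tolerance. All randomness flows from a single integer seed; the
pipeline derives per-stage seeds by hashing the stage name, so any stage
can be re-run in isolation from the manifest and reruns are
byte-identical.

## Known limitations

- Exact numerical agreement with GSVA/ssGSEA reference implementations is
  not claimed (different weighting and normalisation details); only
  rank-level behaviour is guaranteed.
- The two-isoform model cannot represent more than one proximal site;
  events with additional sites fold into the nearest breakpoint.
- The competing-gene screen is correlational; it recovers planted
  structure but cannot distinguish direct competition from confounding.
- NMF consensus clustering is quadratic in samples via the consensus
  matrix; for very large cohorts subsampling would be needed.
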