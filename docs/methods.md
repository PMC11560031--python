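# Methods

## Data model and preprocessing

Raw data is a long table of wells: one biological sample (a muscle from one
animal of a strain at an age), one candidate gene, a technical replicate
number and a Cq value.  Missing wells are explicit NaN rows, never silent
zeros, and `(sample, gene, tech_replicate)` must be unique.

Technical duplicates are collapsed to their arithmetic mean Cq — the
geometric mean of the underlying linear quantities, the conventional choice
for cycle-scale data.  A cell whose replicate standard deviation is ≥ 0.8
cycles is discarded (strictly `< 0.8` keeps; the boundary rejects) and
logged with reason `duplicate_sd`.  The SD uses the n−1 (sample) estimator,
matching common qPCR QC practice; singleton replicates pass unconditionally
since no spread is measurable.  Genes or samples left with no retained cells
are pruned with a warning.  Downstream algorithms need complete matrices;
`impute_or_drop` offers `drop_sample` (default), `drop_gene`, or `none`
(error on missing cells).  No value imputation is offered: fabricating Cq
values would bias exactly the variance statistics this package estimates.

Heart-only candidates (HTATSF1, HMBS) are ordinary genes in storage;
completeness is checked per analysis subset, because these genes are absent
from skeletal-muscle samples by design.

## Stability algorithms

All four methods run on the Cq scale assuming 100% amplification efficiency
(one cycle = 2-fold), so Cq differences are log2 expression ratios.  No
efficiency correction is applied anywhere, keeping the methods mutually
consistent; relative quantities accept an efficiency in (1, 2] for the
validation stage only.

**geNorm.**  `V_jk = SD_s(Cq_k − Cq_j)` with the n−1 estimator;
`M_j = mean_{k≠j} V_jk`.  Iterative exclusion removes the max-M gene each
round, recording its M at elimination, down to the terminal best pair, whose
members share the final two-gene M (they are mutually defined and genuinely
of equal rank).  Ties at the maximum are broken against the gene later in
input order, with a warning — deterministic and visible.  Internally the
statistic is computed from log2 relative quantities with a per-gene min-Cq
calibrator; every geNorm quantity is invariant to that calibrator, which is
a convenience only.  The V curve adds genes best pair first, then ascending
elimination-round M; `V(n/n+1)` is the SD over samples of the log2 ratio of
the n- and (n+1)-gene geometric-mean normalisation factors.  Both the
elimination-round M (`m_trace`, what the ranking plots show) and the
full-panel first-round M (`initial_m`) are reported, since either reading is
defensible; `m_trace` is primary.

**BestKeeper.**  Index = per-sample geometric mean of candidate Cq (the
original definition; arithmetic mean available as a sensitivity option);
genes ranked by Pearson r against the index, computed on the Cq scale.
A zero-variance profile leaves r undefined: it is reported as NaN with a
warning and ranked last rather than being assigned a fictitious 1 or 0.
Per-gene Cq SD and CV descriptives are reported but not used for ranking,
and no SD pre-filter is applied.

**deltaCt.**  `score_j = mean_{k≠j} SD_s(Cq_j − Cq_k)` on raw Cq.  This is
algebraically the geNorm first-round M; the two modules reach it through
different code paths (raw differences vs log-RQ ratios) and the test suite
asserts their agreement to 1e−9 on arbitrary matrices — a standing
cross-check on both implementations.

**NormFinder.**  Work on y = −Cq so "up-regulated" is positive.  The model
is y_gs = gene effect + sample loading + ε_gs with Var(ε_gs) = σ²_g, plus a
gene-by-group deviation d_gi in grouped mode.  The per-sample loading is
estimated by the gene average of each sample; that averaging leaks every
gene's noise into the residuals, so naive per-gene residual variances s²_g
(two-way centered residuals, n−1 denominator) are de-biased by solving the
expectation equations, giving

    σ̂²_g = k/(k−2) · (s²_g − Σ_l s²_l / (k(k−1))),

truncated at zero (k = number of genes; the correction is degenerate for
k < 3, which is an error).  Ungrouped stability = σ̂_g.

Grouped mode estimates d̂_gi as the group mean minus grand mean of the
sample-centered data (so deviations sum to zero over genes within each
group), with sampling variance v_gi = σ̂²_gi/n_i from the per-group variance
estimates.  Deviations are shrunk by an empirical-Bayes normal-normal
factor γ̂²/(γ̂² + v_gi), where γ̂² = max(0, Σ d̂²/((k−1)(G−1)) − mean v) is
the method-of-moments prior variance — deviations estimated from small,
noisy groups are damped toward zero.  Gene stability is the group average
of |d*_gi| + √v_gi (magnitude of systematic deviation plus intragroup
uncertainty); a candidate set is scored by averaging its members' shrunken
deviations and pooling their sampling variances, and the best pair minimises
that combined value over all pairs (exhaustive search; the test suite
re-derives the optimum independently).  With identical group means the
intergroup terms vanish exactly and stability reduces to the intragroup
uncertainty.  A planted between-group shift δ is identifiable only up to
the per-sample centering: with k genes the estimable deviation is
δ(k−1)/k, split across groups about the grand mean — parameter-recovery
tests assert against that model-implied value.  Groups are single factors
(age, genotype, muscle, strain) with ≥ 2 groups of ≥ 2 samples; no factor
crossing.

## Subsets and consensus

Fixed subset labels (`entire`, `healthy`, `dystrophic`, `GC`, `DIA`,
`heart`, `heart-extended`, the four strains, `age-{4,8,12,28,52}`) with
design expectations 180/90/60/45/36 keep the four methods' tidy outputs
joinable.  The heart is analysed twice: with the core-8 panel and with the
10-gene extended panel.  Subsets below 36 samples are refused without a
`force` flag, since ranking validity degrades with shrinking N.

For the consensus, BestKeeper r is inverted (1 − r) and every method's
scores divided by their maximum, so all lie in (0, 1] with low = stable and
the worst gene at exactly 1; the aggregate is the per-gene geometric mean,
ranked ascending.  Scores entering the consensus: geNorm M at elimination
(best-pair members share the final pair M — the full-panel M would
double-penalise genes eliminated late), deltaCt mean pair SD, NormFinder
ungrouped stability (the only mode defined for every subset), BestKeeper r.
An exact zero is floored at 1e−6 of the method's maximum (logged) so the
geometric mean stays defined; the aggregate ranking is invariant to positive
rescaling of any method's raw scores.

## Validation stage

RQ = E^(Cq_min,g − Cq) per gene; normalisation factor = geometric mean of
the reference panel's RQs; normalised target = RQ/NF.  Replicate groups are
the (strain x age x muscle) design cells with their 3 animals; CoV = sample
SD / mean on the linear RQ scale, and the summary is the arithmetic mean of
per-group CoVs.  Linear-scale CoV with the n−1 estimator is the
conventional reading of "coefficient of variation"; everything downstream is
invariant to the per-gene calibrator, which cancels in SD/mean and in
ratios.  A target may be normalised to a panel containing itself
(self-normalisation is a conservative check).

## Synthetic-data generator

Each well draws

    Cq = baseline + muscle_shift + age_slope·log2(age/4) + disease_shift
         + loading(sample) + N(0, residual_sd) + N(0, duplicate_sd),

with one shared loading offset per biological sample — the cDNA-content
factor all four algorithms assume — and two technical replicates per well.
The age effect is parameterised on log2(age/4) so the youngest group is the
baseline and trends are monotone; disease shifts apply to dystrophic
animals, keyed by strain background.

Default truth (one choice, fixed): stable genes CSNK2A2 (Cq 25.5) and AP3D1
(25.0) with residual SD 0.2, ACTB (15.8, SD 0.25) ~10–20-fold more abundant,
SDHA (19.5, SD 0.3), PAK1IP1 (26.5, SD 0.3); planted instabilities GAPDH
(16.5, SD 0.45, 1.5 Cq more abundant in GC, +0.3/+0.5 Cq dystrophic shift on
the BL10/D2 backgrounds), HPRT1 (24.0, SD 0.5, −1 Cq in GC, +1 Cq in heart)
and RPL13A (18.0, SD 0.4, −0.4 Cq per age doubling, ≈ 2.8-fold rise from 4
to 52 weeks); heart-only HTATSF1 (26.0, SD 0.2, stable) and HMBS (27.5, SD
0.35).  Loading SD 0.8 Cq and duplicate SD 0.15 Cq.  These magnitudes place
~99% of values inside the 14–30 Cq span, make the shared loading the
dominant variance component (which is what drives uniformly high BestKeeper
correlations and elevated geNorm M in this kind of dataset), and separate
stable from planted-unstable genes by construction.

What the generator does **not** emulate: amplification-efficiency
differences between assays, plate/batch effects, heteroscedastic noise at
high Cq, outlier wells, or correlated biological effects between genes.
Passing recovery tests therefore demonstrates that the algorithms and their
orchestration are correct under the additive log-scale model — not that any
particular gene is a good reference in real tissue.

## Problem sizes and numerics

Tests and the acceptance script run the full pipeline at design size
(180 samples, 8–10 genes), Monte-Carlo recovery at 20 seeded full-design
runs, ungrouped variance recovery at n = 500 and grouped-shift recovery at
n = 50/group — sizes at which sampling noise is far below the planted
effects while the whole suite completes in well under a minute.  All SDs use
the n−1 estimator throughout.  Negative variance estimates truncate to
zero.  Floating-point identities (deltaCt vs geNorm) are asserted at 1e−9.
All randomness flows through `numpy.random.default_rng` seeded explicitly;
the same seed reproduces a dataset byte-for-byte.

## Known limitations

- No efficiency calibration from standard curves and no inter-plate
  calibrators (single-plate design assumed).
- NormFinder grouped mode handles single-factor groupings only.
- Consensus aggregation is score-based; rank-product style aggregation is
  deliberately out of scope.
- Reproduction tests against the published study's raw data require that
  workbook to be supplied locally; it is not redistributed with the
  package.
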