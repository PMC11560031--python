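# refstab

Reference-gene stability analysis for qPCR Cq data.

Quantitative PCR expression measurements are only meaningful relative to
stably expressed internal reference ("housekeeping") genes, and no gene is
universally stable: candidates must be ranked empirically for each tissue,
age range and disease state.  `refstab` implements the four standard
stability algorithms plus a consensus ranking and a normalisation-validation
stage, organised around the natural-history design of dystrophic mouse
studies (the D2-mdx and BL10-mdx models of Duchenne muscular dystrophy with
their wild-type backgrounds): 4 strains x 5 ages (4–52 weeks) x 3 muscles
(gastrocnemius, diaphragm, heart) x 3 animals = 180 samples, scored over a
panel of 8 core candidate genes plus 2 heart-only candidates.  It is aimed
at researchers choosing reference panels for muscle qPCR studies, and at
anyone wanting a tested, scriptable implementation of these algorithms.

## Methods implemented

With Cq the quantification cycle (one cycle ≈ 2-fold abundance at 100%
efficiency), for genes *j, k* over samples *s*:

- **geNorm** — pairwise variation `V_jk = SD_s(Cq_k − Cq_j)` (the SD of the
  log2 expression ratio); stability `M_j = mean_{k≠j} V_jk`; the highest-M
  gene is iteratively excluded down to a terminal **best pair** (equal
  rank).  The pairwise-variation curve `V(n/n+1) = SD_s log2(NF_n/NF_{n+1})`
  between normalisation factors built from the *n* and *n+1* most stable
  genes guides panel size (< 0.2 guideline).
- **BestKeeper** — per-sample consensus index = geometric mean of all
  candidate Cq; genes ranked by Pearson *r* against the index (high *r* =
  stable).
- **deltaCt** — `score_j = mean_{k≠j} SD_s(Cq_j − Cq_k)`; identical to the
  geNorm first-round M vector, computed through raw Cq differences.
- **NormFinder** — additive model `y_gs = gene effect + sample loading +
  ε_gs` on y = −Cq; ungrouped stability is the corrected residual SD of a
  gene; grouped mode decomposes variation into intragroup variance and a
  shrunken intergroup deviation per group, and selects the best two-gene
  combination.
- **Consensus** — BestKeeper r is inverted (1 − r), every method's scores
  are divided by their maximum, and genes are ranked by the geometric mean
  of the four transformed scores.
- **Validation** — relative quantities `RQ = E^(Cq_min − Cq)`, normalisation
  factor = geometric mean of a reference panel's RQs, and the per-replicate-
  group (strain x age x muscle) coefficient of variation of a target gene
  before vs after normalisation.

A seeded synthetic-data generator reproduces the full design with planted
muscle-, age- and disease-specific effects and technical-duplicate noise, so
every stage is testable against known ground truth.

## Worked example

```python
from refstab import (default_truth, simulate_cq, collapse_technical_replicates,
                     standard_subsets, apply_subset, impute_or_drop,
                     ReferenceStabilityModel, validate_panel)

truth = default_truth(seed=1)                      # known planted effects
table = simulate_cq(truth)                         # 3120 wells, 180 samples
matrix = collapse_technical_replicates(table)      # duplicate SD < 0.8 kept
spec = next(s for s in standard_subsets(matrix) if s.label == "entire")
core = impute_or_drop(apply_subset(matrix, spec), "drop_sample")

res = ReferenceStabilityModel(core, label="entire").fit(grouping="age_weeks")
print(res.summary())
```

```
Reference-gene stability summary — subset 'entire'
180 samples, 8 candidate genes

         genorm_m  bestkeeper_r  deltact_sd  normfinder_stability  aggregate  rank
CSNK2A2    0.3229        0.9153      0.5725                0.2483     0.3504     1
AP3D1      0.3229        0.9020      0.5923                0.2953     0.3828     2
ACTB       0.3637        0.8802      0.6116                0.3515     0.4365     3
PAK1IP1    0.3981        0.8767      0.6189                0.3439     0.4486     4
SDHA       0.4153        0.8813      0.6220                0.3533     0.4527     5
RPL13A     0.7264        0.7672      0.8472                0.6932     0.7876     6
GAPDH      0.9540        0.7706      0.9293                0.7849     0.8869     7
HPRT1      1.0047        0.7127      1.0047                0.8898     1.0000     8

geNorm best pair (equal rank): AP3D1, CSNK2A2
NormFinder best pair (grouped by age_weeks): AP3D1, PAK1IP1 (combined stability 0.0821)
geNorm pairwise variation: V2/3=0.109  V3/4=0.086  V4/5=0.069  V5/6=0.114  V6/7=0.128  V7/8=0.114  (guideline < 0.2)
```

The three genes with planted effects (GAPDH: muscle shift; HPRT1: opposed
muscle shifts; RPL13A: age slope) occupy the bottom three consensus ranks;
the stable pair CSNK2A2/AP3D1 is recovered as geNorm's best pair; every
V(n/n+1) sits under the 0.2 guideline, so the best pair plus one further
reference suffices.  Validating the top trio as a panel:

```python
for target, rep in validate_panel(core, ["GAPDH", "HPRT1", "RPL13A"],
                                  ["AP3D1", "CSNK2A2", "ACTB"]).items():
    print(target, round(rep.mean_cov_raw, 3), "->", round(rep.mean_cov_norm, 3))
```

```
GAPDH 0.475 -> 0.304
HPRT1 0.492 -> 0.327
RPL13A 0.453 -> 0.254
```

Mean replicate-group CoV drops for every weak candidate once the shared
sample loading is divided out — the signature of an effective panel.

The same pipeline runs from the shell:

```sh
refstab simulate --outdir sim --seed 1
refstab analyze --input sim/cq_data.csv --outdir out
refstab report --bundle out
```

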