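# remsig

Whole-blood gene-expression signatures that predict clinical remission under
biologic therapy in rheumatoid arthritis — as a tested, reusable pipeline.

Patients starting one of three biologics (an anti-TNF antibody, an IL-6
receptor blocker, a T-cell costimulation blocker; three arms of 140/38/31
patients) are labeled **REM** / **NON-REM** by the Clinical Disease Activity
Index at 6 months (remission: CDAI ≤ 2.8, missing visits resolved by last
observation carried forward). `remsig` takes a baseline genes × samples
intensity matrix and derives, per arm, gene-set signatures separating the two
outcome groups, then turns them into per-patient scores and an 8-group
patient stratification.

## Method

1. **Preprocessing** — rank-based quantile normalization across samples;
   probes kept when called "present" in more than 50 samples and annotated
   with a gene symbol; multi-probe genes collapsed to the probe with the
   highest mean intensity.
2. **Gene set enrichment analysis (GSEA)** — genes ranked by the
   signal-to-noise ratio *s* = (μ_NON-REM − μ_REM)/(σ_NON-REM + σ_REM); a
   weighted Kolmogorov–Smirnov running statistic gives each set an
   enrichment score ES ∈ [−1, 1]; 1000 phenotype permutations calibrate the
   normalized score NES, nominal *p* and FDR *q* (significant: *p* < 0.05
   and *q* < 0.1, set sizes 15–500). The *leading edge* (core genes) is the
   subset at or before the running statistic's extremum.
3. **Signature scores** — each core gene is z-scored over the pooled cohort
   and a patient's score is the mean core-gene z-score; signatures with
   near-duplicate score vectors (Pearson *r* ≥ 0.95) are consolidated.
4. **Association & prediction** — Firth penalized logistic regression
   (ℓ*(β) = ℓ(β) + ½ log det I(β)) links scores to non-remission with
   finite estimates even under separation; profile-likelihood CIs and
   penalized LRT *p* values. ROC analysis (NON-REM positive) picks the
   cutoff maximizing Youden's J and reports sensitivity, specificity, PPV
   and NPV.
5. **Stratification** — three binary signature calls (score above/below its
   cutoff) place every patient into one of 2³ = 8 groups, with per-group
   non-remission rates.

A seeded synthetic-cohort generator (`remsig.simulate`) reproduces the
study design — arm sizes, per-arm remission rates of 30.0/21.1/22.6 %,
log-normal intensities, planted differentially-expressed gene sets of
controllable effect size, early discontinuers with missing month-6 CDAI —
so the whole pipeline is exercisable and testable without any download.

## Worked example

```python
from remsig import (CohortDesign, PlantedSet, GseaParams,
                    generate_cohort, run_pipeline)

design = CohortDesign(
    n_genes=2000,
    planted_sets=(PlantedSet("INFLAMMASOME_LIKE", 30, "IFX", delta=0.8),
                  PlantedSet("CD19_LIKE", 30, "TCZ",
                             direction="REM > NON-REM", delta=0.8),
                  PlantedSet("CD56_LIKE", 30, "ABT", delta=0.8)),
    n_decoy_sets=10, seed=1)
matrix, clinical, gene_sets = generate_cohort(design)
result = run_pipeline(matrix, clinical, gene_sets,
                      GseaParams(n_perm=1000, seed=1))
for arm, a in result.arms.items():
    print(arm, a.signature.set_name, f"NES={a.signature.nes:.2f}",
          f"p={a.signature.p_nominal:.4f}", f"AUC={a.roc.auc:.3f}")
print(result.group_table.to_string(index=False))
```

prints (signatures recovered per arm, then the 8-group table):

```
IFX INFLAMMASOME_LIKE NES=2.55 p=0.0019 AUC=0.997
TCZ CD19_LIKE NES=-2.21 p=0.0020 AUC=1.000
ABT CD56_LIKE NES=2.31 p=0.0021 AUC=1.000
 group  n  nonrem  nonrem_rate_pct
     1  6       0              0.0
     2  2       0              0.0
     3 51      16             31.4
     4 56      42             75.0
     5  0       0              NaN
     6  0       0              NaN
     7 52      52            100.0
     8 42      42            100.0
```

Each arm's planted set is flagged significant with the right direction
(negative NES = higher in REM), the oriented signature scores separate the
outcomes almost perfectly at this clean effect size, and patients called
"above" on all three signatures (group 8) have the highest non-remission
rate while the all-favorable group (group 1) has the lowest.

The same stages are exposed as a CLI:
`remsig simulate | preprocess | gsea | score | associate | roc | stratify |
pipeline` (see `remsig --help`).

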