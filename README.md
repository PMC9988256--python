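# myoatlas

Analysis toolkit for a multi-muscle human skeletal-muscle transcriptome
atlas: bulk RNA-seq profiles of seven leg-muscle tissues (gracilis GR,
semitendinosus mid STM and distal STD, rectus femoris RF, vastus lateralis
VL, vastus medialis VM, gastrocnemius lateralis GL) from 20 individuals,
confirmed by large-scale quantitative immunohistochemistry and in situ
hybridisation. The package implements the full computational chain with
which such an atlas is analysed, plus a seeded synthetic-data generator
that emulates the study design, so every stage is testable without the
controlled-access sequence data.

## What it computes

**Preprocessing** (`myoatlas.preprocess`) — sample QC (> 5 M assigned
reads), expression filtering (≥ 10 reads in ≥ 16 samples), trimmed mean of
M-values (TMM) normalisation, log2-CPM, and a per-gene Type-II ANOVA
variance decomposition over muscle, individual and technical factors.

**Cell-type composition** (`myoatlas.celltype`) — the expression of genes
marking each cell type is summarised by its first principal component
across samples ("eigenvector"); per cell type the score is tested with the
atlas mixed model

    score ~ muscle + (1 | individual)

(REML; Wald F with containment df; Tukey pairwise contrasts; BH-FDR over
cell types), and muscles are clustered on their mean scores.

**Differential expression** (`myoatlas.diffexpr`) — per-observation
precision weights from the fitted mean–variance trend (the voom approach),
the same mixed model per gene with those weights, BH-FDR across genes, and
the cell-type-driver filter: a DEG whose expression tracks a cell-type
eigenvector (Pearson r > 0.5 at FDR < 0.05) is flagged as driven by
composition rather than muscle-intrinsic regulation. The identical
machinery runs on transcript-level counts.

**Consensus co-expression network** (`myoatlas.network`) — per individual,
biweight midcorrelation (bicor) → signed-hybrid adjacency (cor^β for
positive correlations, β = 8) → topological overlap matrix (TOM);
per-individual TOMs are calibrated by matching their 0.95 quantile to the
median across individuals; the consensus TOM is the elementwise 40th
percentile; modules come from average-linkage clustering of 1 − TOM with a
dynamic hybrid tree cut (min module size 20, deep split 0) and are merged
at eigengene dissimilarity 0.2. Parameters are selected by a grid sweep
scored with the enrichment factor against pathway knowledge,

    EF = (n1 · n4) / (n2 · n3),

where every gene pair is classed by same-module × same-pathway membership.
Module eigengenes are tested for muscle association with the mixed model;
modules with ≥ 5 markers of one cell type are flagged as
composition-driven; hub genes are the top 10% by intramodular
connectivity; top modules satisfy Q3 of member-gene DE F-values > 5.5.

**Quantitative histology** (`myoatlas.histology`) — myofiber quality
filters (percentile rules on segmentation certainty, per-muscle
cross-sectional area, circularity), per-sample RMS scaling and natural-log
transform of the three myosin-heavy-chain mean fluorescence intensities,
mean-shift fiber typing (bandwidth h = 0.02, clusters < 1% of fibers
removed), capillary scoring (CD31⁺ ∧ ENG⁺, 3 < area < 51 µm²,
circularity > 0.5, density per µm²), and RNA-foci counting
(area < 3.5 µm², circularity > 0.98, average per myofiber).

**Pipeline** (`myoatlas.pipeline`, CLI `myoatlas`) — runs the stages end
to end from a YAML config with per-stage seeding and a checksummed output
manifest; re-running with the same seed is bit-identical.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic atlas (2,000 genes, 20 individuals × 7 muscles in 3 latent
groups, 5 planted co-expression modules, ~9% missing biopsies):

```bash
python analysis/01_simulate_atlas.py          # writes scratch/analysis/*
python analysis/02_preprocess.py
python analysis/03_celltype_composition.py
python analysis/04_differential_expression.py
python analysis/05_consensus_network.py
python analysis/06_histology.py
```

Output of `02`–`05` on seed 1 (abridged):

```
median % variance explained per gene:
muscle         5.93
individual    56.04
batch          0.92
residual      34.17

muscle clusters at k=3:
  cluster 1: GR, STM, STD
  cluster 2: RF, VM, VL
  cluster 3: GL

1124 DEGs at FDR<0.05 (87 cell-type driven, 1037 intrinsic)

5 modules (1696 genes unassigned); enrichment factor vs pathway
knowledge: 192.99 (n1=8091, n2=1259, n3=1144, n4=34356)
muscle-related modules: 1/5; top by DE F-rule: 1
```

Reading this: per-gene variance is dominated by the individual rather than
the muscle (as the atlas design anticipates); the muscles cluster into the
three anatomical groups (hamstrings / quadriceps / lower leg) from
cell-type scores alone; roughly half the genes respond to muscle, of which
~8% merely track cell-type composition; the consensus network recovers the
five planted modules with a strongly positive enrichment factor, and
exactly the module planted with a group-differential latent factor is
called muscle-related and survives the DE F-value selection. The histology
step recovers the three planted fiber-type clusters with per-sample
proportions matching the planted mixture (0.45/0.35/0.20) and a higher
capillary density in GL than in the hamstrings. Compact result tables are
written to `results/analysis/`.

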