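# Methods

This note documents the statistical models, numerical choices and known
limitations of the package. Everything stated here is computed by the test
suite, the analysis scripts or `scripts/acceptance.py`.

## Study design and the synthetic atlas

The analyses assume a repeated-measures design: up to 7 muscle tissues per
individual (GR, STM, STD from the hamstrings; RF, VL, VM from the
quadriceps; GL from the lower leg), 20 individuals, with some
individual × muscle biopsies missing. The generator
(`myoatlas.synthetic`) emulates this:

* **Counts.** Gene counts are negative-binomial (Gamma–Poisson) with
  per-sample mean `library_size × softmax(η)`, where η sums a gene
  baseline (`N(2, 1.8²)` on the natural-log scale), muscle effects,
  individual effects, a batch effect, a cell-type-mixture term and planted
  module factors. Library sizes are uniform on 8–15 M reads; the NB
  dispersion is 0.1 — conventional desk-scale values for bulk muscle
  RNA-seq.
* **Muscle effects** are hierarchical: a component shared by the muscles
  of one latent group (SD 0.12) plus a muscle-specific component
  (SD 0.08), so muscles of a group shift together. These scales are kept
  small enough that chance muscle-pattern correlation between background
  genes (r ≈ 0.17) is annihilated by the power-8 soft threshold
  (0.17⁸ ≈ 7·10⁻⁷): the planted latent-factor blocks are the only
  co-expression structure in the default world, which is the premise of
  the module-recovery checks. Individual effects (SD 0.40) dominate muscle
  effects, reproducing the atlas observation that inter-individual
  variance exceeds inter-muscle variance.
* **Cell-type mixture.** Per sample, cell-type fractions are Dirichlet
  with group-specific concentrations; the endothelial concentration is 50%
  higher in G2/G3 than G1, and G3 carries more non-muscle (FAP/immune)
  signal. Marker genes have an elevated signature (8 vs 0.5) in exactly
  one cell type, so their expression moves with log(Σ_c fraction ·
  signature).
* **Planted modules.** Five blocks (80/70/60/50/40 genes) load a shared
  per-sample latent factor with loading √(ρ/(1−ρ))·0.35 for a target
  within-module correlation ρ = 0.8. The first module's factor carries a
  group-level shift (amplitude 1.0 SD), making it muscle-related — the
  phenomenon the module–muscle association stage exists to detect.
* **Missingness** removes ~9% of individual × muscle cells uniformly at
  random (the real atlas retains 128 of 140).

What the generator does **not** emulate: compositional count coupling
beyond the softmax (no differential total RNA content), batch-by-gene
interactions, GC/length biases, isoform-level structure (transcript counts
are multinomial splits of gene counts), and correlated missingness.
Passing tests therefore certify the statistical machinery under the
design's ideal assumptions, not robustness to those artefacts.

## The atlas mixed model

All per-unit tests (cell-type scores, genes, module eigengenes, histology
metrics) use

    y_ij = μ + muscle_j + u_i + e_ij,  u_i ~ N(0, σ_u²),  e_ij ~ N(0, σ_e²/w_ij)

fitted by REML. Weights (when present, from the mean–variance trend) are
absorbed exactly by scaling the response, fixed design and random-intercept
column by √w, which makes the per-individual covariance I + θ·z z' (rank
one, θ = σ_u²/σ_e²); the restricted likelihood is profiled to a 1-D
bounded optimisation over log θ with closed-form GLS at each step. The
implementation agrees with statsmodels' MixedLM to ~10⁻⁶ (tested) at
~60× its speed, which is what makes per-gene DE over thousands of genes
practical.

Numerical choices:

* **Denominator df.** The muscle-term Wald F uses containment degrees of
  freedom, n − p − (n_individuals − 1); for a complete paired two-muscle
  design this equals the paired-t df, and the mixed-model p-value matches
  the paired t-test (tested to 10% median relative error, and the null
  false-positive rate is verified by simulation). A Satterthwaite
  approximation was not implemented; the `ddf_method` field records the
  method.
* **Pairwise contrasts** use Tukey's studentized-range adjustment over all
  21 muscle pairs. The studentized-range SF is evaluated through a cached
  log-scale interpolation table per (k, df) (relative error ~10⁻³),
  because scipy's direct quadrature costs ~8 ms per call.
* **Degenerate inputs.** A constant response returns F = 0, p = 1. A
  boundary REML fit (θ → 0) is flagged `singular`, not raised. Fewer than
  two individuals triggers a fixed-effects fallback with a warning.
* **Random-effect significance** (used for module–muscle association)
  is a ML likelihood-ratio test against the fixed-effects model with the
  0.5·χ²₀ + 0.5·χ²₁ boundary mixture.

## Preprocessing

TMM follows the published definition: reference column by
closest-to-mean upper-quartile; gene-wise M and A values on positive
counts in both samples; 30% two-sided trim on M and 5% on A (rank-based,
as in the standard implementation); inverse-asymptotic-variance weights;
factors scaled to geometric mean 1. The implementation is cross-checked
in the tests against edgeR's `calcNormFactors` (2% tolerance) and against
a brute-force reimplementation (10⁻¹⁰).

Variance decomposition fits one fixed-effects linear model per gene with
all factors, computing each factor's Type-II partial sum of squares via
shared residual-maker matrices. Because Type-II partial SS do not sum to
the total SS in unbalanced designs, percentages are normalised over
(Σ partial SS + residual SS); for orthogonal designs this equals the
classical SS/total. Constant and aliased factors are dropped with
warnings.

## Cell-type eigenvectors and the driver filter

Marker rows are standardized across samples; the per-sample score is the
first right-singular vector, sign-oriented to correlate positively with
the set's mean standardized expression (so higher score = higher marker
expression; the sign of a PC is otherwise arbitrary). Singleton sets
return the standardized gene. Scores are exactly zero-mean because
standardized rows are orthogonal to the constant vector.

The cell-type-driver filter computes Pearson correlations between each
significant DEG and each eigen-score, BH-adjusts the whole
(gene × cell type) grid of correlation p-values, and flags genes with
r > 0.5 and q < 0.05. The signed threshold (not |r|) follows the
sign-oriented score convention; an `r_threshold` parameter exposes it.

## Consensus network

* **bicor**: median/MAD biweights zeroed beyond 9 MADs; zero-MAD columns
  fall back to Pearson normalisation for their pairs (warned). Requires
  ≥ 4 observations — per-individual networks use that individual's ≤ 7
  samples, which is intentionally noisy; the cross-individual consensus is
  what stabilises it.
* **Calibration**: each TOM is rescaled so its 0.95 quantile of
  off-diagonal entries matches the median of those quantiles across
  individuals; the consensus entry is the elementwise 0.40 quantile,
  clipped to [0, 1]. Rescaling one input TOM is absorbed exactly whenever
  its quantile does not displace the median reference; no reference
  computed from the inputs can make that invariance universal while also
  returning identical inputs unchanged.
* **Tree cut** (authored implementation of the dynamic hybrid family):
  average linkage on 1 − TOM; a branch qualifies as a module when it has
  ≥ `min_module_size` genes, forms below 0.99 of the top merge height,
  and its *relative gap* — attachment height minus core scatter (mean
  internal merge height), divided by attachment height — exceeds the
  deep-split preset (0.025 / 0.015 / 0.005 for deepSplit 0 / 2 / 4).
  Selection is bottom-up: a qualifying child with a larger relative gap
  displaces its parent (keeping stragglers out), and a branch whose two
  children both qualify is split. The relative-gap criterion was chosen
  over normalised-height thresholds because it is scale-free: on
  default-scale data, pure background branches top out at relative gap
  ≈ 0.008 while pure planted-module branches reach 0.05–0.26, a margin
  that height-normalised criteria do not preserve across datasets.
  There is no PAM-like reassignment stage.
* **Merging** clusters module eigengenes at 1 − cor, merges branches
  below the cut height (into the largest member's label), recomputes and
  iterates to a fixed point.
* **Enrichment factor**: pairs classed by same-module × same-pathway
  ("same pathway" = share ≥ 1). Standalone EF excludes genes without any
  annotation (configurable); the parameter sweep includes them (they share
  no pathway), so parameter sets that sweep unannotated genes into modules
  are penalised. The sweep ranks grid points by the Haldane–Anscombe
  continuity-corrected EF, (n1+½)(n4+½)/((n2+½)(n3+½)): raw EF is +∞
  whenever no pathway is split across modules (n3 = 0), which with
  truth-derived pathways holds for many grid points regardless of how much
  background their modules absorb; the corrected form stays finite and
  orders those points by discordant mass. Ties break toward smaller power,
  then smaller minimum module size. Raw EF and an infinity flag are
  reported per grid point. The sweep is scored on merged consensus
  modules.
* **Hubs**: top 10% by intramodular connectivity per module (at least
  one); the fraction is a parameter since no published cutoff exists.

## Histology

* **Myofiber filters**: strict percentile exclusions — boundary certainty
  < P5, interior certainty > P95, circularity < P1 (pooled over muscles),
  CSA < P10 or > P99 per muscle. Percentiles are linear-interpolation
  quantiles; a constant feature excludes nothing. The verbatim protocol
  text excludes circularity *greater* than the 1st percentile, which
  would discard 99% of fibers; the default corrects this to exclusion
  below P1, and `strict_circularity_text=True` restores the literal rule.
* **Typing**: per sample and channel, MFIs are divided by the
  root-mean-square (scaling without centering — a per-sample multiplicative
  staining scale cancels exactly), natural-log transformed, pooled, and
  clustered by mean shift with bandwidth 0.02 (scikit-learn's flat-kernel
  implementation; modes closer than the bandwidth merge). Clusters holding
  < 1% of all fibers are discarded; proportions are per-sample fractions
  of total fibers. The generator's within-cluster log-SD default (0.01) is
  chosen so the published bandwidth is the natural density scale —
  within-type variation below the bandwidth, between-type separation
  (0.5–1.5 log units) far above it; mixture weights are planted exactly
  per sample (largest-remainder rounding) because with multinomial
  assignment the RMS step converts mixture sampling noise into per-sample
  log offsets comparable to the bandwidth, a small-n artefact the
  1.3-million-fiber scale of the real assay does not exhibit.
* **Capillaries / foci**: strict inequalities throughout, per the verbal
  rules. The optional negative-control intensity threshold defaults to the
  control maximum (percentile configurable), classifying approximately all
  control speckles negative.

## Pipeline determinism

One global seed fans out to per-stage seeds by CRC32(stage name) XOR seed,
masked to 31 bits, so toggling a stage never perturbs another stage's
stream. Outputs are TSV with a fixed float format; the manifest embeds the
config and SHA-256 of every file, and re-running a config is bit-identical
(tested).

## Problem sizes

Defaults are desk-scale by design: 2,000 genes × ~128 samples for the
atlas (the tests trim to 700 genes where the full scale adds nothing),
a 3 × 2 × 2 × 1 sweep grid on 700 genes, 1,000 genes for DE calibration,
and 4,000–21,000 synthetic myofibers. The real study's scale (~20,000
genes, 1.3 M fibers, a 315-point sweep) changes runtimes, not code paths.

## Known limitations

* The containment-df F test is slightly conservative in severely
  unbalanced designs; calibration is verified by simulation only for
  designs near the atlas layout.
* Per-individual bicor on ≤ 7 samples is extremely noisy by construction;
  conclusions about single-individual networks should not be drawn from
  intermediate per-individual TOMs.
* The tree-cut presets were developed against the generator's TOM scale
  (dissimilarities near 1); applying `cut_modules` to dissimilarities of a
  very different scale may need the deep-split presets revisited.
* Transcript-level synthetic counts are multinomial splits of gene counts
  and therefore carry no transcript-specific noise beyond sampling.
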