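# Methods

`gepnet` reimplements, as a tested pipeline, a coordinated-cell-state
analysis for multi-sample single-cell cohorts: per-cell-type gene expression
program (GEP) extraction by consensus NMF with stability-based rank
selection, a cross-cell-type network of programs built from the correlation
of per-sample program scores, module detection with permutation-based
gene-set themes, clinical association statistics, and rank-AUC proxy-score
transfer of signatures to independent cohorts. A seeded synthetic cohort
generator with full planted ground truth drives all validation.

## Synthetic cohort generator

The generator emulates a case/control pediatric autoimmune CITEseq cohort:
by default 27 PBMC samples in four ordered disease-activity groups
(HC 5, Inactive 6, Active 7, TreatmentNaive 9), six major immune cell
types, and K planted programs per cell type.

**Latent sample intensities.** Per-sample program intensities are drawn from
a Gaussian copula whose correlation is the planted intra-module ρ (0 across
modules), then mapped to a nonnegative scale by `softplus(z + latent_loc)`.
`latent_loc = 1.5` keeps the softplus in its near-linear range so the
planted ρ survives the mapping (measured attenuation ≈ 0.01 at ρ = 0.8; the
residual shortfall of the per-seed sample correlation is ordinary estimator
noise at n = 30).

**Disease activity.** One designated module is the activity ("IFN-like")
module: its latent intensities are shifted by `activity_effect · step`,
where step is the 0–3 index of the ordered group. A separate activity
latent, `step + N(0, vas_noise²)` with `vas_noise = 0.5`, is rank-mapped to
the 0–10 physician-global VAS scale, so at `activity_effect = 0` the module
is statistically independent of VAS. The 0.5 within-group spread encodes a
physician score that tracks true activity closely within group; it caps the
attainable module/VAS Spearman correlation near 0.85.

**Cells and counts.** Per-cell program usages are Dirichlet draws around the
sample's normalized intensities (concentration 10 — cells vary substantially
around their sample's state). Library sizes are Gamma with mean
`libsize_mean` (default 2,000, CV ≈ 0.32). Counts are gene-wise negative
binomial with mean `libsize · (W u)` and variance `μ + φμ²`
(`overdispersion` φ, default 0.3; exact Poisson at φ = 0), realized as a
gamma–Poisson mixture.

**Planted loadings.** Each program's gene-loading column sums to 1, realizes
the requested sparsity (default 90% zeros), and carries ≥ 5 disjoint
"anchor" genes whose weights dominate every background gene, making the
factorization identifiable and giving recovery tests an unambiguous target.

**ADT biomarker.** A single surface-protein channel is an affine function of
the activity-module sample intensity plus per-cell Gaussian noise, emulating
a monocyte IFN-induced protein used for disease monitoring.

**What the generator does not emulate.** No doublets, ambient RNA, batch
effects, donor-level repeated measures, or cell-type misassignment. Passing
recovery tests therefore demonstrate correctness of the algorithms under the
stated noise model, not robustness to the full artifact spectrum of real
droplet data.

## Program extraction

**Preprocessing.** NMF operates on raw counts restricted to the
`n_top_genes` (default 2,000) most overdispersed genes — ranked by
variance-to-mean ratio computed in exact integer arithmetic so ties are
reproducible — with each cell rescaled to a total of 10,000. Raw-count NMF
is otherwise dominated by library size.

**NMF.** Multiplicative updates minimizing the Frobenius reconstruction
error from a seeded nonnegative random initialization; the objective is
recorded at every convergence check (every 10 iterations, via the trace
identity, so no gene×cell intermediate is formed) and is guaranteed
nonincreasing. Loadings are column-normalized at the end with usages
rescaled compensatingly. Frobenius rather than KL: the validation criteria
measure recovery, not likelihood, and Frobenius MU steps are substantially
cheaper.

**Rank selection (weighted subtrees).** For each candidate rank k the model
is refit `n_restarts` times, each restart on a seeded random 80% subsample
of cells. All k·restarts loading vectors are pooled into an average-linkage
tree on correlation distance (1 − Pearson). A subtree *qualifies* when its
members come from ≥ ⌈0.8·restarts⌉ distinct restarts and their mean pairwise
correlation is ≥ 0.8; the metric for k sums the mean intra-correlation of
the *finest* qualifying subtrees. Three design points deserve comment:

- *Subsampled restarts.* On fully deterministic refits, extra components at
  k > K can sit at population-level optima (e.g. splits that model
  overdispersion of high-mean anchor genes) and reproduce across restarts,
  so stability never decays. Resampling cells perturbs exactly those
  noise-supported optima while genuine programs persist.
- *Finest rather than largest qualifying subtrees.* Two tight program
  clusters whose mutual correlation also clears 0.8 would otherwise merge
  into a single counted subtree, deflating the metric precisely at the true
  rank.
- *Saturation rule.* The chosen rank is the first running-peak k with no
  rise of more than 5% within a two-point lookahead (argmax if the curve
  never saturates). Dips at k < K reflect genuinely unstable
  under-factorization (which programs merge depends on the restart) and are
  skipped; the lookahead guards against selecting a pre-dip peak.

On the low-noise planted-K=5 design the metric is near-linear up to k = 5
(≈ k·0.99) and flat beyond; the rule selects k = 5 in 10/10 cohort seeds.

**Consensus model.** Loading vectors from all restarts at the chosen rank
are clustered into k groups on the same tree; each group's median loading is
a consensus column, and usages are re-solved by per-cell nonnegative least
squares. If clustering yields fewer than k groups the best-objective single
restart is returned, flagged.

**Marker scores.** With column-normalized loadings, the marker score of
gene g in program p is the z-score of W[g,p] across the k programs for that
gene times W[g,p] itself — specificity weighted by magnitude. Ranks are
per-program descending with gene-id tie-breaks. At k = 1 specificity is
undefined; raw loadings are returned flagged.

**Sample scores and outlier programs.** The per-sample program score is the
mean usage over the sample's cells (samples under `min_cells` are dropped
and logged). A program is filtered out when one sample carries more than
half its score mass or fewer than three samples exceed 10% of its maximum —
single-sample artifact programs by construction.

## Program network

Edges are Pearson correlations of per-sample scores over common samples
(≥ 5 required), with a one-sided bootstrap p-value for positive association,
`p = (1 + #{r_b ≤ 0})/(n_boot + 1)`; the network keeps edges with r > 0 and
p < 0.05 only, matching the positive-correlation definition of the network.
Under simulated independent pairs the rejection rate is ≈ 5%. Modules are
seeded Leiden modularity communities on the r-weighted graph; singleton
components get their own module, and ids are contiguous from 1, largest
module first.

Module gene-set themes: the statistic for (module M, set g) is the mean over
M's programs of −log10(max(FDR, 1e-10)) from the per-program GSEA table; the
null redraws size-|M| node sets from the whole network. Gene-loading
similarity between programs is a Pearson correlation over shared genes
(≥ 100 required) with a gene-label permutation p; top-gene overlap uses a
one-sided Fisher exact test over an explicit gene universe.

## Gene-set machinery

GMT parsing normalizes gene ids to upper case and rejects duplicate set
names and within-set case collisions (the dominant silent-failure mode of
set/feature mismatches). Preranked GSEA uses the classic running-sum ES with
hit increments ∝ |score|^w (default w = 1) and uniform miss decrements; when
the positive and negative extrema tie in magnitude within 1e-12 the positive
one wins, deterministically. p-values come from gene-label permutations with
a plus-one correction (never zero), restricted to same-sign null scores;
NES divides ES by the mean |null ES| of that sign. FDR is
Benjamini–Hochberg on the permutation p-values across sets within a program
— simpler and better calibrated at desk scale than the classic NES-based
FDR. One caveat observed on NMF marker rankings: with w = 1 the null is
dominated by permutations that catch a single huge-score gene, costing
power; for sharply peaked score distributions w = 0 is the better-behaved
choice, and the exponent is exposed everywhere.

## Clinical statistics

Composition: per-cell-type sample proportions, Kruskal–Wallis across the
treatment-naive/inactive/HC groups with Dunn's tie-corrected post hoc
z-tests (Holm-adjusted within cell type), plus Spearman against VAS
(BH-adjusted across cell types) — two adjustment families, labeled, because
they answer different questions. Program tests: Welch t (cases vs HC;
unequal group sizes make the equal-variance assumption unattractive) and
four-group one-way ANOVA with Tukey HSD. Gene modules: genes differential in
≥ 2 cell types, row-standardized (sample, cell type) average-expression
profiles, complete-linkage Euclidean hierarchical clustering cut at
`n_modules` (default 7 — a reported, not derived, count, so it is a
parameter). Module score: binned-control scoring (24 equal-occupancy
mean-expression bins, 100 control genes per set gene sampled with
replacement) of log1p per-10k-normalized expression; the null mean is
centered at 0 within ±0.01 over 1,000 cells. All tests match independent
brute-force oracles to ≤ 1e-8 in the suite.

## Proxy-score transfer

A program's proxy gene set is the top `ceil(0.05 · n)` genes by marker score
(ties to the lexicographically smaller gene id). Each cell in a new dataset
is scored by the area under the set's recovery curve within the top 5% of
that cell's expression-ranked genes, normalized by the maximal possible
area; expression ties break by ascending gene id, and the statistic is
invariant to any monotone transform of a cell's expression, so raw counts
are ranked directly. Pseudobulk is the per-sample mean.

One structural caveat: the per-cell rank-AUC is compositional — it measures
a program's usage *share* within each cell. If two programs of the same cell
type both carry the disease-activity shift, the shift cancels in their
shares and the pseudobulk proxy decouples from activity. The pan-cell-type
activity module (one shifted program per cell type), which mirrors the
biological setting, does not have this problem; the transfer validation
design reflects that.

## Pipeline and reproducibility

The driver chains factorize → filter → network → enrich → associate
(→ transfer), writes every stage table as TSV with 12-significant-digit
floats, and records a manifest (parameters, per-stage sub-seeds, input
checksums). A single global seed is expanded into per-stage sub-seeds by a
fixed SeedSequence spawn order; reruns with the same config and seed are
byte-identical. MTX orientation (genes × rows) is validated against the
sidecar files and transposed input is rejected, never fixed silently.

## Validation problem sizes

The recovery and rank-selection experiments use one cell type, 1,000 genes,
K = 5 planted programs and 30 samples × 200 cells in the Poisson
(`overdispersion = 0`), no-activity-shift regime — the package's definition
of the low-noise regime, where factorization behavior is isolated from the
disease-association machinery. Disease-association and transfer experiments
use the 5/6/7/9 four-group design at `activity_effect = 2` with the default
overdispersion 0.3. Calibration studies use 200–500 replicates per check.

## Known limitations

- Frobenius NMF on depth-scaled raw counts treats overdispersion of
  high-mean genes as signal; the weighted-subtrees procedure compensates at
  rank selection, but loading tails of recovered programs absorb some of
  this variance.
- The weighted-subtrees formula and the module-enrichment statistic are
  committed interpretations of method components the source analysis only
  names; both are parameterized so alternative definitions can be swapped
  in.
- Permutation and bootstrap p-values have resolution 1/(n+1); calibration
  statements are at desk-scale replicate counts.
- Group tests treat longitudinal samples as independent, replicating the
  analysed study's convention; a donor-collapse option is exposed in the
  clinical table rather than imposed.
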