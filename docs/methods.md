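# Methods

This note documents the models, defaults, and numerical choices behind
`plasticore`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external runs.

## Coordinates and containers

All genomic intervals are 0-based, half-open (BED convention), including
fragment records: a fragment `[100, 200)` does **not** overlap a region
`[200, 300)`, and two abutting intervals `[a, b)`, `[b, c)` are not merged.
Matrix Market files are 1-based on disk and converted on read. Count
matrices are sparse features × cells with unique string identifiers;
normalized matrices carry their method (`lognorm`, `tfidf`,
`mean_centered`) as provenance.

## Quality control

A nucleus passes QC iff `rna_min < total_RNA < rna_max`,
`atac_min < total_ATAC < atac_max`, and `mito_fraction < mito_max`, with
defaults 1,000 / 25,000 / 5,000 / 70,000 / 0.20. All bounds are strict, so
boundary values are excluded; the 12-cell boundary fixture in the test
suite pins this behavior exactly. The mitochondrial fraction is computed
on RNA UMI counts over a designated mitochondrial gene set (the modality is
a package choice; the criterion is conventionally applied to RNA).
Plate-based RNA data use a separate `total ≥ 200` UMI filter. The
PCR-duplicate cap keeps the first 5 occurrences of each identical fragment
key — since no sequence data is in scope, identity is approximated at the
fragment-coordinate level `(chrom, start, end, strand)` and the key
function is exposed for callers with richer identity information.

## Normalization

* RNA: `ln(1 + s·x/total)` with scale `s = 10⁴`. This library-size
  log-normalization stands in for regression-based variance stabilization,
  which is out of scope; differential testing on log-normalized counts is
  the standard pre-integration contrast.
* ATAC: TF-IDF with non-binarized counts in both factors —
  `TF = x/cell_total`, `IDF = n_cells/peak_total`, value
  `ln(1 + s·TF·IDF)`. A binarized-IDF variant
  (`IDF = n_cells / n_cells_open`) is available via `binarize_idf=True`;
  the exact variant used by the upstream toolchains is not standardized, so
  the default is documented rather than guessed. Zero-total peaks carry no
  IDF information and are dropped with a warning.
* Bulk: DESeq-style median-of-ratios size factors over regions positive in
  every sample. Factors are defined up to a common scale.
* Natural logarithms throughout; base-2 logs only in reported fold changes.

## Rank-sum test and AUC

The Mann–Whitney statistic is computed with midranks,
`U = R_A − n_A(n_A+1)/2`, and reported with the effect size
`AUC = U/(n_A n_B) = P(A > B) + ½P(A = B)`. For pooled sample size ≤ 12
the p-value is the exact permutation tail over all `C(n, n_A)` label
assignments (two-sided: assignments at least as far from AUC = 0.5 as
observed). Above that, a normal approximation with tie correction and 0.5
continuity correction is used; it agrees with standard asymptotic
implementations at the sample sizes the pipeline sees. Per-feature
differential tables report `avg_log2fc` on de-logged (expm1) normalized
means with pseudocount 1e-9, two-sided p, and BH-adjusted padj.

For motif deviation scores, which are signed z-scores, the effect size
accompanying the AUC is the difference of group means (`delta`) rather
than a fold change; the regulator filter requires `delta > 0` where a
fold-change sign would be meaningless.

## Bulk NB Wald test

The replicated-bulk differential test is a deliberately small two-group
negative-binomial GLM, not a reimplementation of a full shrinkage
estimator:

1. size factors by median-of-ratios;
2. per-region dispersion by method of moments on **within-condition**
   residuals of normalized counts,
   `α_i = max((s²_resid − μ̄)/mean(μ̄_g²), 10⁻⁸)`. Estimating dispersion
   across all samples would let a genuine condition effect inflate its own
   dispersion and destroy power, so residual-based estimation is essential;
3. a single global moderation floor: `α_i ← max(α_i, Q₀.₆(α))`, the 60th
   percentile of the per-region estimates. With a handful of replicates the
   raw moment estimator collapses to zero for many regions, which makes the
   Wald tail anti-conservative; the scalar floor restores near-nominal
   calibration (measured null p < 0.05 fraction ≈ 0.04–0.05, and null
   simulations yield zero BH discoveries) while leaving planted 4-fold
   effects recovered at ≥ 99%. This is a global scalar, not per-region
   empirical-Bayes shrinkage;
4. IRLS for `log μ = log sf + β₀ + β₁·[condition B]` with fixed α,
   vectorized across regions (the 2 × 2 weighted least-squares solve is
   closed-form for a binary covariate); Wald `z = β₁/SE(β₁)` with
   `SE` from the Fisher information, two-sided normal p, BH adjustment.
   All-zero regions are reported with NaN statistics and excluded from BH.

Not implemented, by design: empirical-Bayes dispersion shrinkage toward a
mean trend, outlier (Cook's distance) filtering, and independent
filtering.

## Signature scoring and classification

Per-cell signature scores are means of normalized expression over the
signature genes present in the matrix; missing genes are dropped (the
coverage fraction is reported) rather than zero-imputed, matching the
"average over present features" convention.

The rank classifier ranks **all** genes within each cell (ascending
midranks, so the most expressed gene holds the highest rank), scores each
signature by the mean rank of its genes, and assigns the label of the
top-scoring signature; a tie of the maxima within 10⁻¹² yields
`Undetermined`. Ranking across all genes (not only signature genes) makes
the score comparable between signatures of different sizes, and the
rank basis makes labels invariant to any strictly monotone per-cell
transform of expression.

Gene-activity windows are gene body plus a 2 kb flank upstream in gene
orientation (`[start−2000, end)` for `+`, `[start, end+2000)` for `−`),
clipped at position 0; chromosome-end clipping would require a
chromosome-sizes input and is not applied. TSS windows are −300 bp/+500 bp
around the strand-aware TSS; upstream/downstream are parameters because
conventions differ between sources.

Lineage-specific sets come from z-scoring significant features across
group means, average-linkage Euclidean hierarchical clustering cut at k,
and assigning each cluster to its peak group. Zero-variance rows are an
error (z-scoring is undefined), and memberships are invariant to feature
order.

## Motif deviations

For motif m and cell c, with `e_p = peak_total_p / grand_total`:
`expected_mc = cell_total_c · Σ_{p∈m} e_p`,
`raw_mc = (observed_mc − expected_mc)/expected_mc`. Each peak draws 50
background peaks (with replacement) from its bin of log mean
accessibility; bins are equal-width (50 by default) so that
well-separated accessibility modes never share a bin — quantile bins could
straddle a gap. When per-peak GC is supplied the binning becomes
two-dimensional; the synthetic genome has no sequence, so GC matching is
optional. The z-score standardizes `raw` against the 50 size-matched
background deviations (sample sd; a zero background sd yields z = 0).
Motifs with zero expected count are dropped with a warning. Useful
invariants, pinned by tests: a motif containing every peak has raw
deviation exactly 0; deviations are invariant to scaling all counts by a
constant; `(observed − expected)` sums to zero over any partition of
peaks.

## Regulator ranking

Candidate regulators join the RNA differential table (restricted to TF
genes) with the motif differential table over an explicit TF-to-motif map.
The filter requires RNA padj < 0.05 ∧ RNA log2FC > 0 ∧ motif padj < 0.05 ∧
motif delta > 0; passing TFs are ranked by `(AUC_RNA + AUC_motif)/2`, ties
broken by RNA AUC then gene id. Filtering before averaging and the
reverse give identical rankings among passing TFs; a gene mapping to
several motifs keeps its best combined pair.

## Patient-pool workflow

Condition-specific region sets are the bulk-differential regions with
padj < 0.05 and the requested fold-change sign; control sets are uniform
without-replacement samples from the shared-accessibility pool, seeded.
Per-nucleus scores are computed by counting fragments at the merged region
set per sample, concatenating samples, TF-IDF on the **merged** matrix
(so scores are cross-sample comparable; per-sample normalization is an
exposed alternative), and averaging over all regions in the set —
including zero regions, so sparsity differences between nuclei are
informative rather than hidden. Nuclei with zero fragments in the set are
dropped with a warning. The condition comparison fits per-nucleus scores
on dummy-coded condition levels by OLS, treating nuclei as independent
observations (a per-sample-mean alternative exists for users concerned
about pseudoreplication), and also reports each sample's top-90% score
subset (the `ceil(0.9·n)` largest values) for display. Per-gene
accessibility differences between conditions aggregate fragments over gene
windows per sample and apply the NB Wald test with samples as replicates.

## Synthetic data generator

The generator defines the study conditions the validation runs under; its
defaults are fixed package choices, not tuned quantities.

* **Multiome** (`SimConfig` defaults): two cell types ("ILC2", "ILC1") ×
  300 cells; 2,000 genes (10 mitochondrial) and 2,000 peaks; 50 signature
  genes and 100 signature peaks per type, disjoint across types; RNA
  counts NB with mean `0.5 · effect^[signature ∧ own type] · libfactor`,
  dispersion α = 0.5 (variance μ + αμ²), log-normal library factors with
  σ = 0.3; fold-change effect 4 for both modalities — a strong but
  realistic marker-gene separation; ATAC counts Poisson (sparse peak
  counts are near-binary at this depth); mitochondrial means tuned so the
  expected mitochondrial fraction is 0.05. Fragments: one 100 bp record
  per ATAC count unit, placed uniformly inside its peak. Motifs: 60 motifs
  × 100 peaks; motif_0 is the planted regulator, drawing 80% of its peaks
  from the first type's signature peaks, its TF gene being the first
  signature gene of that type; the other 59 are uniform decoys.
* **Synthetic genome**: 500 bp peaks spaced 2 kb apart, 1,000 per
  chromosome; separate gene chromosomes with 2 kb gene bodies 6 kb apart
  on alternating strands — enough geometry to exercise strand-aware
  windows without real annotation.
* **Bulk**: log-normal region base means around 100, NB dispersion 0.05,
  log-normal per-sample depth factors (σ = 0.2), 3 vs 3 replicates; the
  first `n_differential` regions are shifted by `planted_log2fc` in
  condition B.
* **Patient pools**: each nucleus is signature-positive with its
  condition's probability; positive nuclei have a 4-fold elevated fragment
  rate in signature regions; background-region rates are shared. Expected
  depth is 200 fragments per nucleus over the combined region set.

Seeding: one integer seed expands into independent substreams
(`numpy.random.SeedSequence.spawn`) per component, so stages are
individually reproducible and outputs across distinct seeds share no
state.

What the generator does **not** emulate: doublets, ambient contamination,
batch effects, peak co-accessibility structure, sequence content, or
realistic gene-length/GC biases. Passing the recovery tests therefore
demonstrates the statistical machinery is correct and calibrated under the
stated count models — not that the pipeline is robust to artifacts real
multiome data can contain.

## Validation sizes

The test suite and acceptance script use: 200 random instances for the
rank-statistic oracles (exact enumeration where pooled n ≤ 12), 100 random
instances for the quadratic interval-overlap oracles, 10 × 2,000-region
null bulk simulations (3 vs 3), one 2 × 300-cell multiome for
classification and marker recovery, 10 multiome seeds for regulator
recovery against 59 decoys, and 10 patient-pool seeds (3 conditions × 3
samples × 60 nuclei, positive fractions 0.1/0.4/0.8). These sizes keep a
full run around a minute while leaving the binomial pass criteria
(e.g. ≥ 9/10 seeds) well-powered.

## Known limitations

* The NB Wald test's moderation floor is a global scalar; strongly
  mean-dependent dispersion trends would be better served by a trended
  estimator.
* TF-IDF scores depend on the region set used; scores computed at
  different region sets are not comparable in absolute value.
* The rank classifier assumes signatures of broadly similar
  informativeness; a signature of mostly unexpressed genes drags its mean
  rank down rather than being treated as missing data.
* `region_set_fragment_counts` merges overlapping regions first; callers
  needing per-original-region counts must deduplicate upstream.
* The patient linear model treats nuclei as independent, as the upstream
  workflow does; with few samples per condition this can overstate
  significance when samples have strong nucleus-level correlation.
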