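# Methods

## Problem and model

`promact` infers promoter activity — the enrichment of the histone marks
H3K4me3 and H3K27ac in the 2-kb window centered on a transcription start
site (TSS) — from DNA methylation alone. Methylation is cheap to profile
(WGBS/RRBS, including FFPE material) while ChIP-seq of histone marks is
not, so a model mapping methylomes to promoter activity lets promoter
landscapes be studied in cohorts where ChIP-seq is infeasible.

The relation between methylation and promoter activity is nonlinear and
spatial: active promoters sit in hypomethylated canyons whose shape,
depth, and flanking context carry the signal. The model therefore
consumes *windowed spatial features* rather than a single promoter-mean
methylation level, and learns higher-order spatial combinations with a
small convolutional network.

## Feature extraction

Per CpG, the M-value is `log2((meth + 0.5) / (unmeth + 0.5))`, clamped
to ±log2(65); CpGs with fewer than 5 reads are dropped. Around each TSS,
two grids of 20 contiguous windows (250 bp and 2500 bp wide, covering
TSS ± 2.5 kb and ± 25 kb) summarize the M-values into three channels:
window mean, window variance (population divisor *n*), and the window's
fraction of the region-level sum of squared deviations (FSSD), whose
values over a grid sum to at most 1 by the variance decomposition.
The FSSD denominator is computed per scale over the CpGs in that scale's
window union; it is undefined (missing) when the region has fewer than
two CpGs or zero total deviation.

Each feature column is min-max scaled to [0.1, 1] **within the sample**;
windows without data become exactly 0, so 0 unambiguously encodes
"missing". Scaling per sample (rather than with training-cohort
statistics) means prediction on a new sample or platform (WGBS → RRBS)
needs no stored normalization state and absorbs platform-level shifts;
this was a genuinely open design choice and is the package's own.

Window order follows the direction of transcription by default (the
index is reversed for minus-strand promoters), because promoter
architecture is asymmetric around the TSS; `ordering="genomic"`
disables the flip.

## Response

For each promoter region, `HM_i = log2((ΣChIP_i + α) / (ΣInput_i + α))`
where the sums integrate per-base coverage over the 2-kb region and `α`
is the 25th percentile (linear interpolation) of the input sums across
the catalog — a sample-level pseudocount. No depth normalization is
applied by default (the formula has none); `depth_normalize=True`
rescales input sums by the ChIP/input total-depth ratio for raw-count
tracks at unequal depths.

## Promoter catalog

GTF transcripts give one TSS each (minus-strand TSS = annotated end);
duplicated (chrom, strand, position) TSSs collapse to the
lexicographically smallest transcript id. The training/evaluation
catalog removes chrX/chrY and runs a greedy left-to-right scan that
drops a region sharing ≥ 1000 bp (50% of 2 kb) with an already retained
same-strand region; opposite strands never conflict. Which member of an
overlapping pair survives is not identifiable from first principles, so
the deterministic greedy scan (sorted by chrom, start, transcript id) is
used. A permissive `all_protein_coding` catalog (autosomal
protein-coding, no overlap collapsing) serves gene-level expression
analyses.

## Network

Input shape is (2 scales, 20 windows, 3 channels). Three convolutional
layers (64, 64, 32 filters by default) with kernel (1, 3), stride 1 and
zero padding slide along the window axis only, so the two scales never
mix inside a convolution; two fully connected layers (128 hidden units,
1 linear output) map the extracted features to the enrichment value.
Every hidden layer uses LeakyReLU (slope 0.1) and a max-norm-3
constraint on incoming weight vectors. Training minimizes MSE with
Adadelta (lr 1.0, ρ 0.95), batch 64, an 80/20 shuffled train/validation
split over the pooled rows of all training samples, and early stopping
(patience 10, min_delta 1e-4, max 80 epochs) that restores the best
validation weights — restoring-best is not the only defensible protocol
but is strictly safer than keeping the last weights. The network is
implemented directly in NumPy (float32; im2col convolutions); all
randomness flows through one seeded generator, so identical seeds give
bit-identical fitted weights in single-threaded execution.

Exact layer widths were an open choice; (64, 64, 32)/128 are the package
defaults and every width is exposed in the estimator's parameters, as is
the fully connected baseline (`conv_filters=()`).

Separate models are trained per mark (H3K4me3, H3K27ac) on identical
inputs.

## Transfer learning

To adapt to a new tumor type with a single labeled sample, the
convolutional layers are frozen (bit-identical weights, verified in
tests) and only the fully connected layers are retrained — continuing
from the pretrained FC weights rather than re-initializing, since the
goal is to update the feature-to-activity mapping, not relearn it
(`reinit_fc=True` is available). Cohort predictions may average an
ensemble of per-sample transferred models, excluding the model
transferred on the sample being predicted (leave-one-out). Samples
whose gene-level activity/expression consistency falls below R² 0.60
can be excluded from transfer (`select_transfer_samples`).

## Downstream analytics

* **Activity calling** — per sample, a univariate 2-component Gaussian
  mixture (EM, k-means init, seed fixed, tol 1e-6, ≤ 200 iterations,
  bounded retries on non-convergence); the higher-mean component is
  "active"; assignment by maximum posterior, so posteriors are ≥ 0.5.
* **Sample-specific fraction** — for a sample pair, active promoters
  private to one sample over the union of active promoters.
* **Differential activity** — per promoter, two-sided Wilcoxon rank-sum.
  For group sizes ≤ 20 the p-value is an exact enumeration over all
  group-label assignments (mid-ranks make it valid under ties); larger
  groups use the tie-corrected normal approximation. FDR control is
  Benjamini–Hochberg ("FDR" alone does not pin a procedure; BH is the
  field default).
* **Promoter usage** — per group, a gene is active when its best
  promoter's group-mean activity exceeds 1; the primary promoter is the
  argmax of group-mean activity (ties to the smaller transcript id).
  Candidates switch primary promoters between groups while active in
  both. The per-sample usage score is activity(primary of group 1) −
  activity(primary of group 2), with groups ordered by sorted label —
  one consistent reading of a quantity that could be defined several
  ways; screens on the mean usage difference (default 0.4) and on a
  minimum between-group activity change at a primary promoter (default
  1) are configurable.
* **Evaluation** — R² is the squared Pearson correlation, RMSE the root
  mean squared difference, optionally restricted to promoters with mean
  mappability > 0.75. Gene-level expression consistency aggregates a
  gene by its most active promoter and compares against log2(FPKM + 1)
  (R²) and against the binary label FPKM ≥ 1 (AUROC, average precision);
  both the log transform and the expressed cutoff are package choices
  exposed as parameters.

## Synthetic data

The generator plants a three-state truth (active / poised / inactive;
priors 0.3 / 0.2 / 0.5) and emits only standard formats (GTF,
methylation TSV, bedGraph, truth TSV), so the command-line pipeline runs
on simulator output unmodified.

* **Methylation** — CpG positions from an inhomogeneous process (rate
  0.05/bp within ±1 kb of the TSS, 1/150 outside, up to ±25 kb);
  per-site methylation probability follows a Gaussian-bump canyon
  profile (flank level 0.85; depth 0.80/0.50/0 and width 1000/600/—
  for active/poised/inactive) with Beta noise (concentration 30);
  coverage is negative binomial (mean 30, dispersion 10; ≥ 95% of sites
  pass the 5-read filter), methylated counts binomial.
* **Enrichment** — input tracks are a near-uniform per-base baseline
  (gamma noise, CV 0.05); ChIP levels are solved per promoter so that
  the *recomputed* enrichment equals the state target plus N(0, 0.3),
  with ChIP clipped at zero (the floor `log2(α/(ΣInput+α))` is a real
  property of the enrichment statistic). The planted truth stored per
  promoter is the enrichment recomputed from the emitted tracks through
  the response module, so generator and pipeline are self-consistent to
  float precision. Default state targets: H3K27ac 3 / 0 / −1 and
  H3K4me3 3 / 2 / −1 for active / poised / inactive, mirroring the
  bimodal activity distribution and the poised definition (high
  H3K4me3, low H3K27ac).
* **Expression** — FPKM = max(2^(HM + ε) − 1, 0), ε ~ N(0, 0.25), so
  activity and expression are consistent on the scale the evaluation
  metrics use.
* **Cohorts** — a configurable fraction of promoters keeps one
  cohort-wide state; the rest redraw per sample. The **domain shift**
  emulates a new tumor type by mildly distorting canyon geometry (depth
  ×0.85, width ×0.8) and, more importantly, replacing the enrichment
  map with a non-affinely related one (H3K27ac 1.5 / 1.5 / −0.9): a
  model trained in the source domain stays correlated with the shifted
  truth but loses accuracy that only retraining the mapping layers can
  recover — exactly the regime transfer learning addresses.

What the generator does **not** emulate: sequence-dependent CpG
placement, non-CpG methylation, copy-number and mappability artifacts,
fragment-level ChIP noise, or batch effects between real platforms.
Passing tests therefore demonstrate correctness of the computations and
the learnability of a realistic signal, not clinical-grade accuracy on
real tumors.

## Experiment sizes and numerics

The bundled experiments use 4000-promoter samples (3 training + 1
held-out) for in-domain recovery and 2500-promoter samples for the
domain-shift/transfer experiment — sizes at which the planted mapping
is comfortably learnable and the whole suite runs on a single CPU in
minutes. Feature oracles are checked to 1e-10, the variance
decomposition to 1e-9, frozen-layer and ensemble identities exactly.
Degenerate inputs are defined, not special-cased: empty windows are
missing (0 after scaling), all-tied rank-sum rows give p = 1, zero-range
scaling columns map to 0.1, and a unimodal activity distribution yields
a warning and a single-state calling.

## Known limitations

* The NumPy network is CPU-only and single-threaded by design; it is
  sized for the (2, 20, 3) input, not general deep learning.
* Exact rank-sum enumeration is combinatorial; above 20 per group the
  normal approximation takes over.
* Catalog counts on real annotations depend on which member of an
  overlapping promoter pair is retained; the greedy rule is
  deterministic but not the only defensible one.
* RRBS input is supported through the same table format, but sparse
  far-flank coverage will leave many 2500-bp windows missing; the
  missing-as-zero convention handles this, at some information cost.
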