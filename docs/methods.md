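# Methods

`biphase` re-implements, as one tested pipeline over synthetic data with
planted ground truth, the regulatory analyses used to dissect a biphasic
developmental program: a larval and an adult tissue (here the oyster D-shape
larva and adult mantle) that express distinct effector gene repertoires under
distinct chromatin landscapes, coordinated by a largely shared set of
transcription factors. This note documents the models, the defaults and why
they were chosen, what the synthetic generator does and does not emulate, and
the numerical conventions.

## Expression dynamics

Counts are converted to TPM within samples and scaled between samples with
trimmed-mean-of-M-values (TMM) factors. The TMM implementation follows the
original definition — the reference sample is the one whose upper quartile of
library-scaled counts is closest to the mean upper quartile; per sample, the
log2 ratios M and average abundances A versus the reference are computed over
genes positive in both, the 30% M-tails and 5% A-tails are trimmed
(floor-based rank bounds), and the factor is 2 to the precision-weighted mean
of the surviving M values, re-centered to geometric mean 1. A unit test
checks exact agreement with the Bioconductor reference implementation.

Expressed genes are those with TPM > 1 in at least one sample. Stage
profiles (replicates averaged, per-gene Z-scaled) are clustered with K-means
(k-means++ initialization, 25 restarts, fixed seed, Euclidean distance in
Z-space; the distance and restart count are our choices, k defaults to 10).
Genes with zero variance across stages cannot be Z-scaled and are assigned a
sentinel cluster 0.

Stage enrichment is called by a Welch two-sample t-test on log2-CPM
(pseudocount 0.5) of TMM-normalized counts, with Benjamini–Hochberg
correction, at FDR < 0.05 and |log2FC| > 1. This test is a deliberately
simple, fully specified stand-in for count-model DE packages: its contract —
verified by the acceptance tests — is type-I control under the null and
recovery of planted effects, not coefficient-level equality with any
external tool. Genes with identical counts in every sample get p = 1 and
`not_significant`. Enrichment classes are named by stage
(`larva_enriched` / `adult_enriched`), so they are invariant to the contrast
orientation; reversing the contrast negates `log2fc` exactly.

## Chromatin states

Binned tracks (200-bp bins; four channels in the fixed order ATAC, H3K4me3,
H3K27ac, H3K27me3) are binarized against a genome-wide Poisson background:
a mark is present in a bin iff P(X ≥ c) < 1e-4 under Poisson(λ) with λ the
mark's genome-wide mean — the documented default of the standard
chromatin-segmentation tool; only the 200-bp resolution is prescribed by the
study design.

The segmentation model is a K-state HMM (default K = 8) whose emissions are
products of independent Bernoulli variables, one per mark. It is trained by
Baum–Welch on sequences pooled over both stages (one observation sequence
per chromosome per stage), with scaled forward–backward recursions,
emission probabilities floored at 1e-6, and a relative log-likelihood
tolerance of 1e-4 (≤ 200 iterations). The log-likelihood is non-decreasing;
a property test verifies the forward–backward posteriors against an
independent categorical-HMM implementation on the 16-symbol joint encoding.
Per-bin labels use posterior (max-marginal) decoding by default — category
summaries are per-bin quantities — with Viterbi available behind a flag.

States collapse into six categories by thresholding each emission at 0.5 and
applying rules in precedence order: **Pois** (H3K4me3 ∧ H3K27me3), **Act_promoter**
(ATAC ∧ H3K27ac ∧ H3K4me3), **Act_enhancer** (ATAC ∧ H3K27ac ∧ ¬H3K4me3),
**Rep** (H3K27me3 ∧ ¬ATAC), **ATAC** (accessibility only), **Qui** (otherwise).
The rule set is total and mutually exclusive over all 16 binary profiles
(unit-tested exhaustively); the precedence (Pois first) is our resolution of
profiles satisfying several definitions. A gene's category per stage is the
highest-precedence category among the bins of its transcription-oriented
window from 5 kb upstream of the TSS to the TES. Cross-stage transition
tables are row-normalized contingency tables over genes (per-bin mode
available); the "transitioned" fraction is the off-diagonal row sum.

## Regulatory linkage

Regions are annotated by precedence promoter > genic > distal > none, with
the promoter spanning −2,000..+500 bp of the TSS (strand-aware), genic from
+500 bp of the TSS to the TES, distal within 100 kb of the nearest gene.
Ties between overlapping promoters go to the gene with the nearer TSS.

Differential chromatin signal is assessed per gene window (−5 kb..TES):
bin counts are summed per replicate and mark, the window × sample count
matrix is TMM-normalized and tested with the same Welch/BH machinery at the
differential-peak thresholds (FDR < 0.05, |log2FC| > 0). Window-level
testing stands in for peak-level differential calling because the linkage
logic operates at the gene window. Note the TMM step assumes the majority of
windows are unchanged between stages, exactly as for expression libraries.

An enriched gene is linked ("concordant") when at least one active feature
(ATAC, H3K4me3, H3K27ac) is significantly higher in its enriched stage, or
H3K27me3 is significantly higher in the opposite stage; membership over the
four features and the active/repressive-only/unlinked split are reported.
Expression–mark coupling is summarized by the Pearson correlation of
per-gene expression log2FC with each mark's window log2FC.

## Paralog divergence

A gene is regulatory-specialized for a stage iff it is expression-enriched
there **and** at least one of H3K4me3/H3K27ac is significantly higher in the
same direction (a strict mode requires both marks; the study text does not
disambiguate, EITHER is the default). Pairs are classified by the number of
specialized members: 0 → no divergence, 1 → one-sided, 2 → both-sided; the
classifier is symmetric in the members. Gene and duplication ages are
inputs; the phylostratum bucket is `pre_mollusca` iff the origin node ranks
at or before Lophotrochozoa in the supplied root-first taxon ordering.

## Gene regulatory networks

Per stage, two evidence channels are combined:

* **Signal channel.** ATAC peaks with ≥ 50% of their length in poised/active
  bins are retained and re-centered on their summits (±100 bp, matching the
  bin size). Motif sites inside selected peaks are scored
  `logistic(z_ATAC + z_H3K27ac + z_motif)`, where the window means are
  log1p-transformed (coverage is multiplicative) and standardized across the
  stage's candidate sites. The logistic combination is a documented,
  monotone stand-in for external binding models whose internals the study
  does not specify; its acceptance surface is planted-edge recovery. Edge
  score = mean binding score of the TF's sites in the target's regulatory
  domain (promoter ∪ genic) × rank-scaled TF and target expression, min-max
  rescaled per stage; only edges strictly above the 75th percentile
  (linear-interpolation quantile, computed per stage) are retained.
* **Footprint channel.** Footprint score = mean flank (40 bp each side)
  minus mean center (20 bp) accessibility from a high-resolution (10-bp bin)
  insertion track — 200-bp bins cannot resolve a 20-bp protection dip, which
  is why the generator emits this extra track. A site is bound when its
  score exceeds the valley of a two-component Gaussian mixture over the
  stage's site scores (90th percentile fallback for degenerate fits),
  mimicking a distribution-derived threshold. Every bound site in a target's
  domain yields an edge.

The final GRN is the union of the channels (intersection behind a flag),
restricted to a target list (effector genes + TFs), with the evidence field
recording channel membership. Summaries: per-TF outdegree (distinct
targets), stage TF sets, their intersection and shared fraction, and
normalized outdegree ranks.

## Cross-species divergence

For each species–reference comparison the stage columns of both species are
jointly quantile-normalized (sorted-mean reference, ties averaged), each
stage column is normalized to a probability profile over the shared
orthologs, and the base-2 Jensen–Shannon divergence
`JSD(p,q) = H(m) − (H(p)+H(q))/2`, `m = (p+q)/2` is computed for every stage
pair (bounded in [0, 1]; 0·log 0 := 0). Orthologs are resampled with
replacement (default 1,000 bootstrap replicates — the only exchangeable unit
given one value per stage) for means and sds. Mean JSD is divided by the
comparison's ortholog count ("adjusted"; our reading of an ambiguous
prescription — it removes panel-size effects), then min-max normalized
globally across comparisons and within each comparison ("relative"). The
minimal-divergence stage per reference stage is the argmin of the normalized
row (invariant to the monotone rescaling); ties break to the earlier stage
order with a flag.

## Synthetic data generator

The generator is first-class, tested code; all downstream truth is planted:

* **Genome and genes.** 4 chromosomes × 800 kb, 240 non-overlapping genes
  (2–4 kb) in regular slots with random offsets; the first 20 genes are the
  TF repertoire. The sizes keep ~16,000 bins for HMM training while leaving
  gene windows mostly disjoint, so planted mark changes do not bleed into
  neighboring windows.
* **Chromatin.** One latent state path and mark-presence pattern per
  chromosome is drawn from the 8-state Markov chain and *shared by both
  stages*: every cross-stage signal difference is planted explicitly through
  rate multipliers, so the differential truth is knowable. Replicate counts
  are Poisson (background λ0 = 0.3, signal λ1 = 6 per bin) times the stage's
  multiplier; the merged track is the replicate sum.
* **Expression.** Negative-binomial counts (dispersion 0.05, 3 replicates
  per stage) with stage means split symmetrically around a per-gene base so
  the planted adult/larva log2FC is exact in expectation. 60 free genes are
  planted enriched (|log2FC| ∈ [2, 4], signs alternating); 80% of them also
  receive a 6× active-mark (ATAC/H3K4me3/H3K27ac) rate multiplier over
  their gene window in the enriched stage ("linked" truth). Expression is
  coupled to chromatin: bystander genes' base means scale with the open
  fraction of their domain, and network participants (TFs, true-edge
  targets) are drawn clearly expressed — networks are built over expressed
  genes, so planted edges must connect expressed genes to be recoverable.
* **Network.** 100 distinct TF→target edges onto an 80-gene effector pool
  disjoint from the expression-planted genes (so network truth is orthogonal
  to DE truth). Each true edge places a 20-bp motif site, unambiguously
  within only the target's domain, inside a 600-bp peak whose ATAC/H3K27ac
  rates are elevated 30× in both stages; true sites carry slightly stronger
  motif scores (N(11, 1.5) vs N(9, 1.5)), as genuine binding sites are
  better motif matches. The 10-bp ATAC insertion track is elevated inside
  peaks (5.0 vs 0.2 per bin) and depleted over the central 20 bp of true
  sites (0.5) — the footprint. 400 decoy sites (half hosted by quiescent
  bystander gene domains, half intergenic) sit in fully closed windows with
  no peak and no dip.
* **Paralogs.** 8 pairs per pattern. One-sided: one member larva-enriched
  with larva-high active marks, the other flat. Both-sided: reciprocal
  larva/adult specialization. No-divergence: both flat.
* **Ortholog panel.** 29 orthologs × 6 stages × 5 species. Each
  non-reference species' planted stage is the reference species'
  reference-stage profile times small log-normal noise (σ = 0.1); its other
  stages use large noise (σ = 1.0).

Randomness flows from one root seed through named child streams (CRC32 of
the stream name), so identical configurations are byte-reproducible and
adding a generator leaves the others' draws unchanged.

**What passing tests do and do not show.** The generator emulates the file
formats, the marginal statistics and the planted causal structure of the
real study inputs, but not: read-level noise, peak-calling artifacts,
mappability, replicate batch effects, correlated biological variation
between stages beyond the planted effects, motif false assignment, or
ortholog misidentification. Recovery rates measured here are therefore
upper bounds on what the same operators would achieve on real data; the
tests establish correctness of the operators and calibration of the tests,
not field performance.

## Numerical conventions and problem sizes

Coordinates are 0-based, half-open internally (BED native; GFF3 converted on
write). Emissions are floored at 1e-6; EM stops at relative tolerance 1e-4;
BH and quantiles use the standard linear-interpolation definitions; the edge
filter keeps scores strictly above the quantile (tied scores can empty the
network, warned). The default test suite and the acceptance script use the
default study conditions above plus reduced Monte-Carlo sizes chosen for
tight-but-stable statistics: 200 null DE runs of 2,000 genes, 200 planted
recovery runs of 200 genes, 100 seeded ortholog panels (20 bootstrap
replicates each — the argmin is insensitive to bootstrap depth), and
10 × 5,000-bin HMM recovery sequences.

## Known limitations

* The DE and window tests are Welch t-tests; with 3 vs 3 replicates their
  power depends on the noisy per-gene variance estimate, so recovery
  guarantees hold at the planted effect sizes, not for subtle effects.
* The binding model and footprint threshold are monotone stand-ins; they
  reproduce the decision structure, not the numerical outputs, of the
  external tools used in the original study.
* With only two stages, Z-scaled profiles take just two shapes, so K-means
  cluster counts above 2 are degenerate on the default synthetic data (the
  pipeline caps k accordingly); the clustering operator is exercised on
  multi-stage toys in the tests.
* Transition percentages, shared-TF counts and correlation coefficients
  printed by the original study derive from deposited sequencing data and
  are not reproducible at this scale; the pipeline reports the same
  quantities computed on its synthetic inputs.
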