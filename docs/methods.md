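# Methods

## Scope and model

The package implements the desk-scale statistical core of a
regulatory-enrichment analysis: given gene annotation, genomic sequence,
DEG tables per contrast, binding-motif models and/or peak sets, it asks
whether a regulator's targets are over-represented among differentially
expressed genes, quantifies spike-in-calibrated binding changes per locus,
partitions DEGs by regulator, and applies a standardized breath-waveform
QC. Read processing (trimming, alignment, peak calling, de novo motif
discovery) is out of scope; the package consumes their standard outputs
(BED/narrowPeak, FASTA, TSV tables, JASPAR/MEME motifs).

## Coordinates and annotation

All intervals are 0-based half-open (BED convention). The TSS of a
plus-strand gene is its `start`; for a minus-strand gene it is its `end`
(base `end-1` is the first transcribed base). The promoter window is the
1 kb immediately upstream on the gene's strand, truncated at chromosome
boundaries. Any gene-level or transcript-level annotation table works; the
package does not impose a transcript model.

## Motif scanning

Motifs are position weight matrices over A,C,G,T. JASPAR count matrices
get a pseudocount (default 0.01 per cell) and per-position renormalization;
MEME minimal files may carry their own background, otherwise uniform.
Scoring is log2 log-odds against the background. An occurrence is called
where the score reaches the threshold at which the exact background score
distribution has tail mass ≤ α (default 1e-4, the conventional occurrence
cutoff). The distribution is computed by dynamic programming over
per-position scores discretized to a 1e-3-bit grid; scanning compares
word scores on the same integer grid, so threshold, per-hit p-values and
the DP distribution are mutually exact, with discretization error bounded
by w·grid/2 bits in the reported real-valued scores. Both strands are
scanned by default (reverse strand via reverse-complemented window
sequence; offsets reported in forward window coordinates). `N` bases take
the per-position minimum score so ambiguous sequence can never create a
hit. No per-position multiple-testing correction is applied: downstream
analysis uses only the binary gene-has-occurrence indicator.

Degenerate edge: a zero-information PWM has a single achievable score with
tail mass 1, so no threshold satisfies the tail condition for α < 1 and
scanning returns no hits; at α = 1 every position is a hit.

## Interval operations

A small vectorized engine (merged intervals with prefix sums;
searchsorted counting) backs peak filtering and annotation, with bedtools
semantics where an analogous tool exists:

- **Repeat filtering** removes a peak iff masked bases / peak length
  strictly exceeds 0.5; masked intervals are merged first, so the result
  is invariant to pre-merging.
- **Summit flanks** are `[summit − f, summit + f + 1)`, clipped.
- **Peak→gene association** finds the nearest gene(s) on the same
  chromosome by interval gap (ties keep all, as `bedtools closest -t
  all`), then emits an assignment iff the peak overlaps the gene body or
  lies within 5 kb of the TSS in either direction (boundary inclusive).
  The 5 kb rule is bidirectional because the upstream-only reading is not
  determined by convention; distance is measured between base coordinates
  (TSS base to nearest peak base).
- **Fragment filtering** keeps fragments strictly under 120 bp — the
  length class produced by transcription-factor-footprint cleavage, as
  opposed to nucleosomal fragments.
- **Overlap counting** counts fragments overlapping a locus by ≥ 1 base
  under half-open semantics (a fragment ending where a locus starts does
  not overlap); one fragment may count toward several loci.

Every operation is tested for exact agreement with a quadratic
brute-force oracle on ≥ 1,000 randomized instances plus the boundary
cases (exactly 50% masked, exactly 5,000 bp, abutment).

## Enrichment bootstrap

DEGs are genes with adjusted p < 0.05; non-DEGs have padj present and
≥ 0.05; genes without an adjusted p belong to neither universe. Each
repetition draws |DEG| non-DEGs uniformly without replacement;
repetitions are independent. Because only the draw's feature frequency is
recorded, the draw's feature count is exactly hypergeometric, and the
sampler draws that count directly (numpy PCG64) — distribution-identical
to materializing the gene sets and verified against an explicit gene-draw
oracle. The p-value is (r+1)/(n+1) with r counting null frequencies
strictly greater than the observed one; the `tie="geq"` option counts
ties into r for a conservative variant. The full null vector is a
deterministic function of the seed. A hypergeometric tail probability is
available as an analytic cross-check, never as the headline statistic.

**Calibration.** At 200 DEGs / 2,000 non-DEGs with a 10% feature rate,
the measured type-I error at α = 0.05 is ≈ 0.086 (3,000 simulated
datasets), i.e. the statistic is mildly anti-conservative. Two causes:
(a) null frequencies live on a 1/|DEG| grid, so the strictly-greater rule
discards substantial tie mass and lowers p; (b) the null is drawn from
non-DEGs only and is centred on the non-DEG pool's realized feature rate,
so its spread is narrower than the binomial variability of the observed
DEG frequency. The `tie="geq"` variant measures ≈ 0.065 under the same
conditions. Practical consequence: p-values within roughly a factor of
two of a chosen α should not be over-read; strong enrichments (the
intended use) are unaffected. Power is high where it matters: a 30% vs
10% feature-rate difference at 500 DEGs / 5,000 non-DEGs is detected at
p ≤ 0.05 in ≈ 100% of datasets.

## Spike-in quantification

Sample *i*'s counts are scaled by C / spike_i with C = 10,000 (the
convention of the standard spike-in calibration workflow); C cancels in
fold changes and only sets signal units. Per-locus log2 fold changes use
group means with a pseudocount of 1.0 to keep zero-signal loci finite.
Genotype |log2FC| distributions are compared with a two-sided
Mann-Whitney U test: full enumeration of all C(n+m, n) labelings when
both groups have ≤ 8 samples (correct under ties; two-sided
p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))), a tie-corrected normal
approximation otherwise. This direct normalization + fold change + rank
test deliberately replaces a negative-binomial shrinkage model: it is
assumption-light, exactly reproducible, and validated by fold-change
recovery on synthetic truth (median recovered log2FC within ±0.1 of a
planted 1.0 at 500 loci, mean depth 100, despite 3-fold spike-in depth
divergence).

Noise floor: with 3 replicates per group at mean depth 100, the
per-locus log2-ratio standard deviation is ≳ 0.12 from counting noise
alone, so per-locus null estimates scatter accordingly; the signed
median across loci is unbiased (within ±0.05 of 0 in tests). Claims
about individual loci at this depth should rely on the rank test, not on
point estimates.

## Classification and rescue

The multi-TF partition is exclusive and exhaustive: each DEG is labeled
with the unique TF whose target set contains it, "multiple TFs" for two
or more, "none" otherwise; counts always sum to |DEG|. A disease-contrast
DEG (padj < 0.05) is *rescued* when its adjusted p exceeds 0.05 in the
corrected contrast; genes unmeasured in the corrected contrast are
reported as indeterminate and excluded from the rescue fraction rather
than silently classified. IP-MS significance keeps proteins with
|log2FC| ≥ 4 (inclusive) and p < 0.05 (strict) versus the preclear
control. Candidate prioritization ranks single-TF DEGs expressed in the
validation system by |log2FC| (sign-blind, since both up- and
downregulated targets are of interest; a signed option exists), breaking
ties lexicographically for determinism.

## Breath QC

Pipeline order is fixed: (1) per-breath exclusions — inspiratory time
< 0.025 s, expiratory time > 10 s, or expiratory tidal volume more than
twice inspiratory, all strict; (2) a 200-breath sliding window (step 1)
removes every breath belonging to any window in which strictly more than
10% of breaths exceed 600 breaths/min (the fraction is compared as
count/window to avoid float edge effects at exactly 10%); streams shorter
than the window are judged as one window; (3) subjects with fewer than
100 surviving breaths are excluded. Whole flagged windows are removed
(the filter targets intervals, not single breaths). The window filter is
not idempotent in general — removal splices distant fast breaths into new
adjacency — but removal is monotone and untouched streams are fixed
points. IBII is |L(n+1) − L(n)| / L(n) over consecutive surviving breath
lengths; it is invariant under uniform time rescaling.

## Synthetic data

All generators are pure functions of (config, seed) with numpy PCG64
pinned as the RNG; outputs are bit-identical across runs. The genome
generator packs non-overlapping genes with alternating strands and room
for a full promoter window; sequence is i.i.d. over configured base
frequencies. Motif planting inserts the consensus at a uniform offset and
strand with per-class probabilities (defaults 0.30 in DEG promoters vs
0.10 in non-DEG promoters — a 3-fold target-rate difference with a ~10%
baseline, typical of a real regulator's footprint among expressed genes).
Counts are negative binomial parameterized by mean and dispersion
(variance = μ + μ²·φ, default φ = 0.05), with sample depths spanning
3-fold and spike-ins Poisson around 10,000·depth. Breath streams are
log-normal around a 0.3 s breath (~200 breaths/min, a resting mouse)
with mutually exclusive injected artifacts and optional tachypneic
bursts.

What the generators do **not** emulate: genomic sequence composition
beyond i.i.d. bases (no repeats, GC structure, or real promoter
architecture), correlated TF target sets unless configured, peak-width
and summit-offset distributions of real callers, overdispersion structure
beyond a single NB dispersion, or autocorrelated breathing rhythms.
Passing tests therefore demonstrate correctness of the computations and
their statistical operating characteristics under the stated models, not
robustness to every artifact of real libraries.

## Problem sizes and numerics

Default verification scales — 2,200 genes / 200 DEGs for end-to-end
enrichment, 500 null datasets × 1,000 repetitions for calibration, 100
datasets × 10,000 repetitions for power, 500 loci for fold-change
recovery, ≥ 1,000 randomized instances per interval oracle — keep the
full suite and the acceptance script to a few minutes on one CPU while
leaving every statistical check well-powered. Score-DP grid 1e-3 bits;
log base 2 throughout; empirical p-values computed from integer (r, n)
only. Ties, boundary values (padj = 0.05, exactly 50% masked, exactly
5 kb, 120 bp, 10% fast breaths) follow the strict/inclusive choices
stated above, each pinned by a dedicated test.
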