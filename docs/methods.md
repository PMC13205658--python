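# Methods

This note documents the models, parameter choices and numerical decisions
behind `lncfunnel`, and what the synthetic-data generators do and do not
emulate.

## Differential expression (`lncfunnel.expression`)

**Model.** Counts are negative binomial with var(K) = μ + αμ², the
standard RNA-seq overdispersion model. Normalization is median-of-ratios:
for each gene with positive counts in every sample, per-sample counts are
divided by the gene's geometric mean; a sample's size factor is the median
of those ratios. The two-group test is a Wald test on
log₂FC = log₂((μ̂_B + c)/(μ̂_A + c)) with pseudo-mean c = 0.5 normalized
counts, which bounds the fold change of genes with a zero group mean. The
standard error comes from the delta method:
var(μ̂_g) = n⁻² Σⱼ (μ̂_g/sⱼ + α μ̂_g²), divided through by
((μ̂_g + c) ln 2)². The statistic log₂FC/se is referred to the standard
normal and adjusted by Benjamini–Hochberg (via statsmodels).

**Dispersion.** α is estimated by the method of moments — pooled
within-group variance of normalized counts, solved against
μ·E[1/s] + αμ² — per gene, then averaged across genes (negative estimates
floored at 10⁻⁸ first) into one common α. This pooling is the deliberate
design choice that keeps the normal-referenced Wald test calibrated at
n = 3 per group: a per-gene variance estimate has ~4 degrees of freedom,
so the statistic would behave like a t₄ and reject ~12% of null genes at
the 5% level. The synthetic data (and the model above) carry a single α
per dataset, so the common estimate is also the efficient one. Deliberate
simplifications: no dispersion shrinkage toward a mean trend, no
covariates, no outlier handling.

**Known limitation.** Because the pseudo-mean c is additive, log₂FC is not
exactly invariant to rescaling one sample's library: scaling one of n
columns by κ rescales all normalized counts by κ^(1/n), perturbing log₂FC
by O(c/μ). The tests bound this rather than asserting exact invariance.
On real data with gene-specific dispersion the common-α choice would be
anticonservative for high-dispersion genes; this is a desk-scale tool, not
a DESeq2 replacement.

**Filters.** All threshold comparisons are strict (padj < 0.05,
log₂FC > 3 for neuronal enrichment; padj < 0.05, log₂FC > 0.5 for the
knockdown analysis), so boundary values are excluded.

**Tissue specificity.** τ = Σᵢ(1 − xᵢ/x_max)/(N − 1) over N tissues; 0 for
flat profiles, 1 for single-tissue expression, invariant to rescaling a
gene's profile. "Brain-enriched" is operationalized as τ ≥ 0.8 (a config
knob) with the expression argmax in a brain tissue — the atlas filter in
the source studies is qualitative, so a concrete, monotone rule was
chosen. All-zero profiles get τ = NaN and are flagged not enriched.

## Homology calling (`lncfunnel.homology`)

**Synteny.** The species-B partner set of a species-A lncRNA is every
species-B lncRNA lying between the orthologs of the A-gene's nearest
protein-coding neighbours (either block orientation). This is the minimal
reading of "shared syntenic locus": one conserved flank pair, no
multi-gene chains.

**Similarity.** Smith–Waterman local alignment with match +1, mismatch −1,
linear gap −2; N never matches. Similarity = (matches in the optimal
alignment) / min(|a|, |b|). Normalizing by the shorter sequence rather
than by alignment columns is essential: the per-column identity of an
optimal *local* alignment between unrelated 300-mers is near 1 (a short
pure-match segment), which would make any similarity threshold vacuous.
Under the shorter-sequence convention, unrelated sequences score ≈ 0.1
and 60%-identity homologs score ≈ 0.6, so the 40% threshold (inclusive,
"minimum of 40%") separates them cleanly. Among equal-score optima the
alignment with the most matches is taken (a lexicographic DP objective),
making the value deterministic; both strands of the candidate are aligned
because lncRNA annotation strand is unreliable across species. Measured
similarity is biased slightly upward (≤ ~0.07 at 300 nt) relative to
planted point identity because edge mismatches are trimmed.

Best partner per query: highest similarity, ties by distance to the
syntenic-block midpoint, then lexicographic id.

## MEA metrics (`lncfunnel.mea`)

Spike detection: per-electrode noise σ̂ = MAD/0.6745 after median
subtraction (robust to the spikes themselves); samples with deviation
strictly above 6σ̂ are events; events within a 1 ms refractory window
collapse to the absolute peak; σ̂ < 10⁻¹² (constant traces) yields no
spikes. Bursts: maximal runs of ≥ 5 spikes with all ISIs ≤ 100 ms
(inclusive, "within 100 ms"). Network bursts: on the pooled train of
active electrodes, maximal ISI-runs with ≥ 50 spikes and participation
strictly above 35% of active electrodes. "Active" = ≥ 5 spikes/minute — a
config knob, because the vendor definition behind the 35% rule is
unpublished. Synchrony: for each electrode pair, spike-time differences
within ±0.5 s are binned at 1 ms, the histogram normalized to unit mass,
and the pair's index is the mass within ±10 ms (total window 20 ms); the
well index is the mean over pairs with any mass. Identical periodic 1 Hz
trains give exactly 1.0; independent Poisson trains give ≈ window/span =
0.02. The NAS is the unweighted mean of the five metrics (firing rate,
burst rate, network-burst rate, synchrony, active fraction) after min–max
normalization across the wells of a batch (constant metrics contribute 0).
The published NAS is vendor-defined without formulas; this transparent
composite preserves its comparative use, but absolute NAS values are only
meaningful within a batch.

## Promoter motifs (`lncfunnel.motifs`)

Promoters are the 1000 bp upstream of the TSS, read toward it
(minus-strand windows reverse-complemented), clipped at chromosome ends.
PFMs become log₂-odds PWMs with pseudocount 0.8 distributed by the
background, JASPAR-style. Scan stringency is an exact p-value: the score
distribution of a background L-mer is computed by column-wise convolution
on a 10⁻³ score grid, and the threshold is the smallest *achievable* score
whose tail probability is ≤ p (default p = 10⁻⁴). Scan decisions are made
on that same grid (reported scores are exact float sums) so the admitted
window set is exactly the one the tail probability counts. Both strands
are scanned; N-containing windows are skipped. Note that an exact p = 10⁻⁴
threshold on a sharp 10–11 bp motif admits one-mismatch windows, not just
the consensus; with 11-mers the chance-positive rate per 1 kb promoter is
≈ 1.6%, which is why the test panel uses 11 bp consensus motifs.

The G-quadruplex screen is the classical deterministic pattern rule
G₃₊(N₁₋₇G₃₊)₃ on both strands (C-pattern on the forward strand reported as
a minus-strand hit), overlaps resolved greedily left-to-right. This is a
transparent substitute for machine-learned quadruplex predictors and
should be read as a candidate screen, not a stability prediction.

## ChIP integration (`lncfunnel.chip`)

Peaks are assigned to the gene with the TSS nearest the peak midpoint
(ties to the lexicographically smaller id), with the feature labelled
promoter (strand-aware 1 kb upstream window), gene body, or intergenic.
Differential occupancy reuses the NB Wald test on peak counts with
FDR < 0.1 and |log₂FC| > 1, both strict; the fold-change threshold is on
the log₂ scale, matching differential-binding convention (a linear ratio
of 1 would be vacuous). Gene-level sets use an any-peak rule. The direct-
target report is an exact set intersection of upregulated genes with
genes losing the mark.

## qPCR closed forms

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt is taken against the
*mean* control ΔCt (standard practice; no per-sample pairing is assumed);
fold = 2^−ΔΔCt. Percent input: the input Ct is measured on a fraction f of
the lysate, so it is shifted by log₂(1/f) cycles before comparison:
%input = 100 · f · 2^(Ct_input − Ct_IP), with f = 0.10 as the default
protocol fraction.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their arguments including the seed.
Study conditions (defaults): 2000 genes, 3 samples per group, 5% planted
neuron-enriched lncRNAs at log₂FC = 4, dispersion α = 0.05, baseline
means log-uniform on [20, 2000]; lncRNA transcripts 300 nt; 16-electrode,
15-minute MEA wells; 1 kb promoters; an 8-tissue atlas with two brain
tissues. Planted structures satisfy the detectors' definitions by
construction (bursts are literal spike runs, homologs are point-mutated
copies in syntenic loci, motif positives carry an embedded consensus), so
detector tests have countable ground truth.

Not emulated: read-level noise, GC/length bias, unwanted-variation
structure between replicates, gene-specific dispersion, correlated genes,
indels between homologs, dinucleotide promoter composition, biological
burst shapes (planted bursts are regular spike trains). Passing tests
therefore demonstrate correctness of the statistics and detectors under
their stated models — not robustness to the full messiness of real
sequencing or electrophysiology data.

## Problem sizes

The bundled analyses and the acceptance rerun use desk-scale sizes chosen
to make the statistical checks sharp while keeping every run in seconds:
2000-gene null and recovery experiments, 500 random alignment-oracle
pairs (length ≤ 30), 8-lncRNA toy genomes, 500 1-kb promoters, 900-second
rasters, and 1000-peak ChIP tables. Headline counts from full-scale
tissue experiments (hundreds of enriched lncRNAs, hundreds of
differential genes) depend on deposited sequencing data and external
atlases and are out of scope; the pipeline's guarantees are the
property-based ones the test suite and `scripts/acceptance.py` compute.
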