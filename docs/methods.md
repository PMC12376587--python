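# Methods

## Data model and conventions

All coordinates are 0-based half-open internally (BED convention); GTF is
converted at the boundary in both directions. On the minus strand the TSS
is the last covered base (`end − 1`) and the TTS is `start`. Coverage is a
dense per-chromosome vector at a configurable bin size (default 1 base):
exact, simple, and adequate at the scale this package targets (megabase
toy genomes, focused real loci). Chromosome lengths come from a
`chrom.sizes` file and any record extending past them is an error, which
catches off-by-one mistakes early. rpm normalization is
`value × 10⁶ / library_size` and re-normalizing an rpm track is rejected
rather than silently ignored.

## Candidate peak calling

The caller is a deliberately small, deterministic stand-in for a
MACS-style workflow: windows of 300 bases stepped by 50 are scored with
the Poisson survival function P(X ≥ obs | λ), where λ is the largest of
(a) the genome-wide input expectation, (b) a local input expectation over
10 kb, and (c) a pseudocount of 0.5 — the input scaled by the library-size
ratio, mirroring the local-λ idea. Windows with p < 1e-5 are merged when
separated by ≤ 100 bases; merged peaks shorter than 150 bases are dropped;
the summit is the leftmost coverage argmax and the score the best window's
−log₁₀ p (capped at 10⁴ where the survival function underflows). Bit
parity with MACS is a non-goal; the contract is the statistical behaviour
(no calls on null data at the stated cutoff, reliable calls on strongly
enriched regions), which the tests pin down.

## Even/odd concordance and true peaks

"Same shape in the raw data" is operationalized as: reciprocal interval
overlap ≥ 0.5 and summit distance ≤ 500 bases, with a greedy one-to-one
assignment (descending overlap, then smaller summit distance, then
leftmost) for deterministic matching. The combined lane is the base-wise
sum of even and odd raw coverage with summed library size — the natural
pooling. The scoring window is ±2 kb around the combined summit or the raw
peak interval, whichever is narrower. Fold enrichment adds ε = 0.25 rpm to
both numerator and denominator so input deserts cannot divide by zero; a
constant even or odd window is assigned r = 0 (an undefined correlation
should not pass a concordance test). Thresholds (coverage > 1.5,
enrichment > 2, r > 0.3) are strict inequalities. Candidate calling runs
per probe lane and concordance is checked afterwards; the alternative
(calling on the pooled lane first) would weaken the independence argument
between lanes.

Peak annotation classifies the summit with priority
promoter ≤1 kb > promoter 1–2 kb > promoter 2–3 kb > exon > intron >
downstream ≤3 kb > distal intergenic, with promoter bands measured as
absolute distance to the nearest TSS (both directions within the band) and
downstream bands strand-aware beyond the TTS. A gene is a binding target
when any true peak overlaps its body extended 2 kb upstream of the TSS.

## TSS profiles and escape indexes

Profile matrices cover [TSS − 2 kb, TSS + 2 kb) at 50-base bins (the bin
size is configurable; 50 bases resolves promoter-proximal structure
without noisy single-base bins). Windows are anchored on the TSS boundary
(interval start for +, interval end for −) and minus-strand rows reversed,
which makes the strand-reflection symmetry exact. Genes whose window
leaves the chromosome are dropped with a logged count. Log₂ fold-change
profiles compare per-bin means with ε = 0.25 rpm on both terms for
finiteness. Heatmap alignment re-centers every gene on the reference
matrix's leftmost argmax bin and orders rows by descending reference row
mean.

The escape index divides the mean rpm over the gene body — 101 bases to
2 kb downstream of the TSS, clipped at the TTS for genes shorter than
2 kb — by the mean over the promoter-proximal window. The promoter window
is TSS ± 100: the body starting at +101 implies the promoter-proximal
region ends at +100, and the symmetric window is the least-assumption
choice; it is configurable. Genes with promoter mean below 0.1 rpm are
reported NA rather than producing unstable ratios, and NA genes are
excluded from ECDFs and statistics with logged counts. EI is a ratio of
means and therefore invariant under global rescaling of the track.

Group comparisons use a two-sided Mann–Whitney U test: exact by full
enumeration of all C(n₁+n₂, n₁) pooled assignments when the smaller sample
has ≤ 8 points (correct under ties), and the tie-corrected normal
approximation with continuity correction otherwise. Families of
comparisons are adjusted by Benjamini–Hochberg step-up with the cumulative
minimum enforcing monotonicity.

The wave-front detector is this package's own construction: per-base rpm
along the gene (TSS→TTS orientation) is smoothed with a centered 1-kb
moving average, and the front is the farthest position at or above 3× a
user-supplied background that is not separated from the TSS by a
sub-threshold run longer than 2 kb. It returns NA when the promoter itself
is sub-threshold.

## Temporal clustering and targets

FPKM rows are z-scored with the population SD (ddof 0); zero-variance rows
are dropped with a logged count. An optional `min_shift` additionally
subtracts the row minimum so the lowest standardized value is 0 while the
SD stays 1 — plain z-scores are the default, and the shifted variant
exists because the two descriptions of standardization in circulation
disagree; the choice affects only the additive level, not distances, so
clustering is unchanged.

Dynamic transcripts are those whose |log₂ FC| versus the first timepoint
(pseudocount 0.1 FPKM) exceeds 0.75 anywhere in the course; the reference
timepoint is configurable. Soft clustering is fuzzy c-means with
fuzzifier m = 1.5 (a common default for standardized expression profiles;
no published value exists for this workflow), tolerance 1e-6,
k-means++-style seeding, and the best of 5 restarts by the objective
Σ uᵐ d²; results are a pure function of (data, seed). A cluster is
stage-specific when its centroid's largest |value| exceeds every other
timepoint's |value| by ≥ 0.5 SD units — one isolated extremum, reported
with its timepoint and direction.

Target prediction labels a (lncRNA, coding gene) pair *colocal* when the
gap between the gene intervals is ≤ 100 kb on the same chromosome and
*coexpr* when |Pearson r| across timepoints ≥ 0.9; the co-expression
cutoff is a package choice (the workflow it follows computes the
correlation without stating a threshold) and is configurable and echoed in
output metadata. Enrichment uses the hypergeometric upper tail
P(X ≥ k) with BH adjustment and a 0.05 significance level on adjusted
p-values. The DEG filter keeps |log₂FC| ≥ 1 (inclusive) and padj < 0.05
(exclusive); the absolute value is intended because down-regulated genes
are analyzed throughout the workflow.

## Synthetic data

All generators are pure functions of (parameters, seed) using NumPy's
PCG64 stream, so outputs are bitwise reproducible. Read counts are modeled
as Poisson draws at the base level rather than placing reads — fast at
desk scale and sufficient for coverage statistics; fragment-length and
GC effects are deliberately out of scope, so passing tests demonstrate the
*logic* of the pipeline, not robustness to library-preparation artifacts.

**ChIRP triples.** The default genome is two 600-kb chromosomes with 200
planted concordant sites and 200 lane-specific decoys of 500 bases at
5-fold enrichment over a Poisson(1) background. Enrichment is planted as a
Gaussian-shaped bump (σ = peak length / 4) scaled so the *mean over the
planted interval* equals enrichment × background. The shape matters: the
concordance Pearson statistic is driven by shared mean structure inside
the scoring window, and a flat rectangle has none once the window
collapses to the called interval. All three lanes carry one nominal
library size (the expected background mass), i.e. depth-matched
sequencing; on a toy genome where planted peaks occupy a sizable fraction
of all bases, using realized totals would let the planted mass itself
deflate rpm units in the probe lanes, an artifact of the compressed genome
rather than of the assay. The genome is kept small enough that background
coverage is near 1 rpm, comparable to a focused real library, so the
protocol's fixed absolute thresholds (1.5 rpm coverage, 2-fold
enrichment) are meaningful for 5-fold planted sites.

**RNAPII tracks.** Ser5P piles a constant level (default 20 counts/base)
on the promoter window (TSS ± 100) plus a low body level; Ser2P weights
the gene body (TSS+101 to TTS). UV scales the Ser5P promoter window by
(1 − δ₅) and the Ser2P body by (1 + δ₂); Poisson noise is overlaid. The
four tracks again share one nominal library size (depth-matched), so the
planted effects appear directly in rpm space and the analytically planted
escape-index ratio, (background + promoter)/(background + (1 − δ₅) ×
promoter), is recorded in the truth file. With δ₅ = 0.5 the planted
promoter log₂FC is slightly above −1 because of the 0.25-rpm pseudocount
and the background floor; the recovery tolerance (±0.15) accommodates
exactly this known bias.

**Expression courses.** Six timepoints (0–48 h); cluster *i* peaks at
timepoint *i* with amplitude 2 in log₂ units, flat elsewhere;
FPKM = 10 × 2^shape plus Gaussian noise of SD 0.5 × 10 FPKM, truncated at
0 — in z-score units the noise is ≈ 0.5 SD against a ≈ 2 SD peak.

## Problem sizes

Defaults used throughout tests and the acceptance script are the package's
study conditions: 1.2-Mb two-chromosome genomes, 200 genes, 400 planted
ChIRP sites, 1800 transcripts across six clusters, five clustering seeds.
These sizes give stable statistics (binomial noise on a 95% recall bound
at n = 200 is ~1.5%) while keeping any single stage under a few seconds.

## Known limitations

- The Poisson caller is not MACS; peak boundaries and scores will differ
  on real data even though the filtering logic downstream is faithful.
- The synthetic genome compresses a 3-Gb genome into megabases; absolute
  rpm levels on real data depend on depth and genome size, and the
  depth-matched library convention above is part of the generator's
  definition, not a claim about real libraries.
- Hard cluster labels come from maximal membership; near-boundary
  transcripts are better interpreted through the membership matrix.
- Reproducing the original study's genome-wide counts requires the
  deposited sequencing data and upstream aligner parity; the pipeline
  exposes the exact thresholds for that but ships no alignment stage.
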