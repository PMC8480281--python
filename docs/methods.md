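# Methods

## Scope and model of the data

cobindscan analyzes summit-anchored ChIP-seq evidence for two cooperating
transcription factors across a perturbation (shRNA knockdown of one factor
versus a non-targeting control). All genomic logic is summit-centric: a peak
is represented by its interval, its absolute summit (the single base of
maximum signal), its MACS2 pileup (the peak-strength statistic) and its fold
enrichment over input. Coordinates are 0-based half-open throughout; GTF
input is converted on read. Peaks are treated as unstranded; strand is
honored only in gene models. The pipeline starts from peak calls and
coverage tracks — read alignment, deduplication and peak calling are
upstream of it by design.

## Stage-by-stage procedure and parameters

**Called-peak filter.** A peak is "called" when pileup ≥ 50 and fold
enrichment ≥ 5 (both inclusive). Blacklist exclusion removes peaks whose
*summit* lies inside an artifact interval; any-overlap removal is available
behind a flag (`mode="overlap"`). Summit containment is the default because
every downstream measurement anchors on the summit, so a peak whose summit
is clean but whose tail touches an artifact region still carries usable
evidence.

**Strength classes.** The strongest-fraction selector sorts by descending
pileup (ties stabilized by chromosome and start so the result is independent
of input order), takes the pileup of the ceil(f·N)-th peak as the class
threshold, and keeps every peak at or above it. Ties therefore inflate the
realized fraction slightly above the requested one — which is why a "top
20%" class can realize as 20.1% — and re-filtering by the reported threshold
reproduces the class exactly.

**Summit co-localization.** Two peaks are co-bound when their summits lie
within 200 bp (inclusive) on the same chromosome. Matching is greedy
one-to-one nearest-neighbor: candidate pairs at distance ≤ 200 bp are taken
in ascending-distance order (ties broken by leftmost A summit, then leftmost
B summit) and each peak is used at most once, so co-bound sites are unique
genomic locations rather than many-to-many overlaps. The FR-20 class holds
strong A peaks whose matched partner is a strong B peak; F-20 and R-20 hold
the remaining strong peaks of each factor; the three classes are disjoint
and conserve cardinality. One site list carries two anchors: FR-20-style
quantification windows center on the A-side summit, RF-20-style on the
B-side summit. The enhancer filter removes sites annotated to promoter or
5′UTR sequence.

**Genomic annotation.** Summit-based, with a HOMER-style priority ladder:
promoter > 5′UTR > TTS > exon > intron > intergenic. The promoter window is
[TSS−1000, TSS+100) on the coding strand; the TTS window mirrors it as
[TES−100, TES+1000). Annotation depends only on the summit, never on peak
width.

**Chromatin categories.** H3K27Ac and H3K4Me1 signal in ±1,000 bp windows
places each site in a 2×2 grid — active A (both high), active B (K27 high
only), primed (K4me1 high only), quiet (both low); signal exactly at a cut
counts as high. Because no universal high/low cut exists for window counts,
cuts are calibrated per mark from the assessed sites. The default
("bimodal-valley") histograms log1p signal in 64 bins, smooths heavily with
a Gaussian kernel (SD 2 bins) so sampling noise inside a mode cannot
masquerade as extra modes, requires the two dominant modes to be at least
bins/8 apart, and places the cut at the valley minimum between them; a
unimodal histogram falls back to the median, and the fallback is logged. A
quantile method and explicit numeric cuts are available. This is a 2×2
thresholding by construction, not a hidden-Markov segmentation.

**Window quantification.** Signal at a site is the coverage integral over
the half-open window [summit−h, summit+h): h = 300 for transcription
factors, HDACs, TLE and ATAC (the "reads/600 bp" unit) and h = 1000 for
histone marks ("reads/2,000 bp"). The integral is exact for
piecewise-constant tracks and invariant to re-encoding of identical
coverage. Whether published window counts of this kind are deduplicated
fragment counts or coverage integrals is generally ambiguous; this package
defines them as coverage integrals. Group comparisons report mean ± SEM
(sample SD/√n, requiring n ≥ 2) and a two-sided Welch unequal-variance t
test ("unpaired t test" is read as Welch; the pooled variant would also be
defensible, and the choice is configurable). Printed percent changes round
half-up at one decimal; full precision is retained internally.

**Running-mean normalization.** Sequencing depth and IP efficiency differ
between conditions, and the fold change between conditions drifts with peak
strength, so a single total-read scale factor is biased by background and
by strength-dependent effects. The remedy: build a union universe by
concatenating the summit anchors of all peak sets from both conditions
(duplicates across sets retained, so the universe size is the plain sum of
set sizes); count reads in ±300 bp windows in each condition; compute
per-site fold change fc = control/treated (treated = 0 sites are excluded
from factor estimation but kept in the output, taking the factor of their
rank neighborhood); rank sites by descending control count (ties broken by
chromosome and start); smooth each site's factor as the mean of its own and
the W−1 subsequent fold changes in rank order (forward window, W = 2500 by
default); and rescale each treated count by its smoothed factor. The
direction fc = control/treated is chosen so that multiplying treated counts
by the factor maps the treated experiment onto the control scale — the
mirror convention would divide. End-of-list windows truncate rather than
wrap or reflect: this affects only the weakest W−1 sites, which are
dominated by background. Consequences asserted in the test suite: constant
fold change normalizes treated exactly onto control; the output is
invariant to rescaling all treated counts by any c > 0 (machine precision);
permuting input order changes nothing; W = 1 returns control exactly at
every treated-positive site. Recovery of a planted global scale factor is
scored as the median normalized/control ratio over null sites; the mean-based
smoothing is mildly sensitive to asymmetric true fold changes inside a
window (a ~2% bias at 5% true-change sites with fold changes 0.4/2.5),
which is an inherent property of a running *mean* and the reason the
recovery criterion is a 3% band rather than exactness under noise.

**Response groups.** At co-bound enhancer sites, per-site fold changes
(normalized knockdown / control — normalization happens first) of the two
assayed factors classify each site into group 1 (RUNX1-like down,
CEBPA-like up), 2 (down/down), 3 (up/up) or 4 (up/down). "Down" is fold
change < 1; a fold change of exactly 1 counts as up, a documented,
configurable tie rule. The groups partition the site set, and swapping the
two factor columns maps group 1 ↔ group 4 while fixing groups 2 and 3.
Strong peaks of the two conditions are partitioned into redistribution
groups A (control-only), B (shared) and C (knockdown-only) using the same
200 bp one-to-one summit rule for cross-condition identity — a published
Venn of "shared" peaks could equally have used interval overlap; the summit
rule is used uniformly here for consistency with co-localization, and the
classification is condition-symmetric (swapping conditions swaps A and C).

**Gene linking and enrichment.** Each gene receives a basal regulatory
domain [TSS−5000, TSS+1000) oriented by strand, extended up to 1 Mb each way
but stopped at the nearest neighboring gene's basal domain
(basal-plus-extension with the tool's standard defaults, configurable); a
site links to every gene whose extended domain contains its summit. The
expression filter keeps genes with FPKM ≥ 2 in at least one condition and
calls ≥ 2-fold changes up or down, with a zero denominator counting as an
infinite fold change (qualifies). For ranking only, log2 fold changes use a
0.1 FPKM pseudo-count, and duplicate gene symbols collapse to the
max-|log2FC| entry — deterministic rules for cases the filter definition
leaves open. Pre-ranked GSEA scores a gene set against the
descending-log2FC ranking with the weighted Kolmogorov–Smirnov running sum
(hit increments ∝ |metric|^weight, default weight 1 with weight 0
available; miss decrements uniform); the null is size-matched random gene
sets (the only permutation scheme available to pre-ranked input), NES is ES
over the mean |null ES| of the same sign, the p-value uses the add-one
permutation convention, and the leading edge is the hits at or before the
running-sum extremum.

## Synthetic data: what it emulates, and what it does not

The generator plants every quantity the pipeline is later asked to recover.
Peak sets draw log-normal pileups (default μ = 4, σ = 1 on the log scale,
i.e. median ≈ 55) at summits spaced ≥ 4 kb apart; a co-binding fraction f
gives exactly round(f·|A|) A peaks a B partner within ≤ 50 bp of the A
summit, while unpaired B peaks stay ≥ 10× the matching threshold away from
every A summit, so the planted pair list is exactly recoverable. Both
members of a planted pair draw their pileups with a +1.5 log-scale location
boost, emulating the stabilized, stronger binding at co-bound sites that
makes strong–strong co-location enriched over independence — without it,
independent strengths would leave almost no strong–strong sites at desk
scale, unlike real data where co-binding concentrates in the strong classes.
Coverage bumps are triangular with 150 bp half-width, discretized at 10 bp
(simple, exactly integrable as represented, and fully contained in a ±300 bp
window for offsets ≤ 150 bp); bump height is the peak's pileup, tying
"strongest 20%" classes to visible signal. The knockdown condition
multiplies each site's signal by its planted group fold change, a global
scale factor (default 0.5, standing for a twofold depth/efficiency
difference) and multiplicative log-normal noise (default σ = 0.1) —
multiplicative noise matches the ratio-based downstream analysis of
positive, right-skewed counts — and the background level scales with the
scale factor, as sequencing depth would. Chromatin classes are drawn from a
mixture (default 10/10/21/59% active A/active B/primed/quiet) and realized
as high (median 800) or low (median 50) histone bump heights, σ = 0.3 on
the log scale. The expression table plants up/down genes at ≥ 2-fold with
FPKM ≥ 2 in the high condition while null genes stay within |log2 fold| <
0.9 (and silent genes stay silent), so the filter recovers the planted
lists exactly; in the full scenario the planted up-regulated genes
preferentially sit near planted group-1 sites so gene linking and GSEA have
genuine signal to find. The default scenario is deliberately desk-scale —
two 25 Mb chromosomes, 1,200 + 2,000 + 2,000 peaks, 400 modeled genes, a
2,000-gene expression table with 100 up / 150 down — roughly a 1:60
reduction of a genome-scale experiment, sized so the full pipeline runs in
seconds while every class retains enough members to be meaningful.

Deliberate idealizations: no read-level sampling noise, mappability
structure, GC bias or copy-number variation; background is uniform;
condition-specific strong-peak sets for the redistribution arm are
generated directly as two planted strong lists rather than re-derived from
a full knockdown peak-calling pass; the proteomics arm is not simulated.
Passing tests therefore demonstrate correctness of the *computations* under
a faithful generative model of the analysis-level data, not robustness to
upstream artifacts that peak callers and alignment filters are responsible
for.

## Numerical choices and degenerate inputs

Printed percentages round half-up at the displayed precision (one decimal
for co-binding percentages and percent changes, integers for overlap
percentages). Welch's test returns p = 1 for two zero-variance groups with
equal means. Pearson correlation of a zero-variance column is reported as
NaN rather than raised. Empty peak lists are an error for top-fraction
selection; an empty gene model annotates everything intergenic; an
all-zero treated count vector is an error for normalization. Interval
queries running off a chromosome end are clipped and the clipping logged.
Seeds: every generator takes a numpy Generator or integer seed; identical
configs give byte-identical scenario files, and re-running the pipeline on
the same inputs gives byte-identical outputs.

## Known limitations

The running mean is sensitive to dense clusters of same-direction true
changes within a rank window (it will partially absorb them into the
factor); a running median would be more robust but is not what the method
under study specifies. The valley calibration assumes the two chromatin
states are separable in one dimension per mark; continuous or overlapping
signal distributions degrade to quantile-like behavior. Greedy one-to-one
matching is not a maximum matching; in degenerate equal-distance
configurations it can leave one more pair unmatched than an optimal
assignment would, though with continuous summit positions such ties have
measure zero. GREAT-style domains deliberately ignore 3D contact
information; a site near a domain boundary links to the nearer gene's
domain regardless of actual enhancer–promoter wiring.
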