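# cobindscan

Summit-centric analysis of transcription-factor co-binding and enhancer
response for ChIP-seq experiments, built around the question of how two
factors (the motivating case: the Forkhead factor FOXC1 and RUNX1 in acute
myeloid leukemia cells) co-occupy regulatory elements and how their occupancy
redistributes after one of them is depleted.

The package is for computational biologists who have peak calls (ENCODE
narrowPeak with MACS2 pileup and fold-enrichment statistics), per-base
coverage tracks (bedGraph), a minimal gene model (GTF) and an expression
table (FPKM per condition), and who want a tested, reproducible
implementation of the following analysis chain:

1. **Called-peak filtering** — pileup ≥ 50 and fold enrichment over input ≥ 5,
   after removing peaks whose summit falls in a blacklist region.
2. **Strength classes** — "strongest 20%" peak classes with
   threshold-then-include tie semantics (the realized fraction may slightly
   exceed the requested one, e.g. 20.1%), plus arbitrary pileup bands.
3. **Summit co-localization** — two peaks are co-bound when their absolute
   summits lie within 200 bp; matching is greedy one-to-one
   nearest-neighbor, so a co-bound site is a unique pair of peaks. From the
   strong sets this yields FR-20 (strong A + strong B), F-20 and R-20 site
   classes, and an enhancer filter drops sites annotated to promoter or
   5′UTR sequence.
4. **Chromatin context** — H3K27Ac / H3K4Me1 window signal places each site
   in a 2×2 grid: active A (high/high), active B (high/low), primed
   (low/high), quiet (low/low); high/low cuts are calibrated from the data.
5. **Window quantification** — ChIP/ATAC signal as the coverage integral over
   [summit−300, summit+300) ("reads/600 bp"; ±1,000 bp for histone marks),
   with group mean ± SEM and Welch t tests.
6. **Running-mean normalization** — the between-condition normalization over
   a union peak universe: rank sites by descending control count, compute
   per-site control/treated fold changes, smooth each site's factor as the
   mean of its own and the 2,499 subsequent fold changes in rank order, and
   rescale treated counts by the smoothed factor. This tracks
   strength-dependent fold-change drift that a single total-read factor
   cannot.
7. **Response groups** — FR-20 enhancer sites fall into groups 1–4 by the
   direction of the normalized RUNX1/CEBPA fold change after knockdown
   (1: RUNX1 down / CEBPA up, 2: down/down, 3: up/up, 4: up/down); strong
   peaks across conditions fall into redistribution groups A (control only),
   B (shared) and C (knockdown only) by the same 200 bp summit rule.
8. **Gene linking** — GREAT-style basal-plus-extension regulatory domains
   (TSS −5 kb/+1 kb, extended up to 1 Mb to the nearest neighboring basal
   domain), a ≥2 FPKM / ≥2-fold expression filter, and pre-ranked GSEA
   (weighted Kolmogorov–Smirnov running sum with size-matched random-set
   permutations) on the log2 fold-change-ranked gene list.

A first-class synthetic-data module generates all of these inputs with
planted ground truth (co-binding fraction, chromatin classes, per-group fold
changes, a global between-condition scale factor, up/down genes) so every
stage is testable end-to-end without any external download.

## Worked example

Simulate a synthetic scenario and run the full pipeline:

```bash
$ cobind-scan simulate -o demo/inputs --seed 7
scenario written to demo/inputs
$ cobind-scan run -i demo/inputs -o demo/results
305 co-bound pairs (38.4% of FOXC1, 25.4% of RUNX1); 59 FR-20 enhancer sites; median null normalization ratio 1.000
```

The 305 co-bound pairs are the planted FOXC1/RUNX1 summit pairs that survive
the called-peak filter; the percentages are pair counts over each factor's
filtered peak total; the 59 FR-20 enhancer sites are strong–strong pairs
outside promoter/5′UTR sequence; and a median null normalization ratio of
1.000 means the running-mean normalization fully absorbed the planted
twofold sequencing-depth difference between the conditions. Per-site detail
lands in TSV/BED files, e.g.:

```
$ head -3 demo/results/fr20_enhancer_groups.tsv
foxc1_peak   runx1_peak   distance  fc_runx1  fc_cebpa  group
FOXC1_00242  RUNX1_00063  1         0.858     1.343     group1
FOXC1_00946  RUNX1_00266  1         0.553     1.626     group1
```

— group 1 sites lost RUNX1 signal (fold change < 1) and gained CEBPA after
knockdown. The same stages are available as a library:

```python
from cobindscan import match_summits, cobound_percentages, read_narrowpeak

foxc1 = read_narrowpeak("demo/inputs/foxc1_peaks.narrowPeak")
runx1 = read_narrowpeak("demo/inputs/runx1_ntc_peaks.narrowPeak")
pairs = match_summits(foxc1, runx1, max_dist=200)
print(cobound_percentages(len(pairs), len(foxc1), len(runx1)))
```

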