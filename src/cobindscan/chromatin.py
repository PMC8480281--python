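"""Chromatin-state classification and genomic annotation of binding sites.

Each site's surrounding chromatin is placed in a 2x2 grid by H3K27Ac and
H3K4Me1 window signal: active A (both high), active B (K27 high, K4me1 low),
primed (K27 low, K4me1 high), quiet (both low). "High" means signal >= cut,
with cuts calibrated per mark from the assessed sites (the thresholds are
data-driven; see `calibrate_cuts`).

Genomic annotation is summit-based with a HOMER-style priority order:
promoter > 5'UTR > TTS > exon > intron > intergenic. The promoter window is
[TSS-1000, TSS+100) on the coding strand and the TTS window mirrors it.
"""

from __future__ import annotations

import enum
import logging

import numpy as np
import pandas as pd

from .genomic_io import GeneModel

logger = logging.getLogger(__name__)


class ChromatinCategory(str, enum.Enum):
    activeA = "activeA"
    activeB = "activeB"
    primed = "primed"
    quiet = "quiet"


class GenomicAnnotation(str, enum.Enum):
    promoter = "promoter"
    five_prime_utr = "five_prime_utr"
    tts = "tts"
    exon = "exon"
    intron = "intron"
    intergenic = "intergenic"


ANNOTATION_PRIORITY = [
    GenomicAnnotation.promoter,
    GenomicAnnotation.five_prime_utr,
    GenomicAnnotation.tts,
    GenomicAnnotation.exon,
    GenomicAnnotation.intron,
    GenomicAnnotation.intergenic,
]


def classify_chromatin(k27_signal, k4me1_signal, k27_cut: float, k4_cut: float):
    """Map (H3K27Ac, H3K4Me1) window signal to a chromatin category.

    Scalar inputs return one category; array inputs return an object array.
    Signal exactly at a cut counts as high (inclusive).
    """
    if k27_cut <= 0 or k4_cut <= 0:
        raise ValueError("cuts must be > 0")
    k27 = np.asarray(k27_signal, dtype=float)
    k4 = np.asarray(k4me1_signal, dtype=float)
    k27_high = k27 >= k27_cut
    k4_high = k4 >= k4_cut
    table = np.array(
        [[ChromatinCategory.quiet, ChromatinCategory.primed],
         [ChromatinCategory.activeB, ChromatinCategory.activeA]],
        dtype=object,
    )
    # scalar inputs index to the bare category, arrays to an object array
    return table[k27_high.astype(int), k4_high.astype(int)]


def calibrate_cuts(signals, method: str = "bimodal-valley", param: float = 0.5,
                   bins: int = 64) -> float:
    """Derive a high/low cut from the signal distribution at assessed sites.

    method="quantile": the `param`-quantile of the raw signal. method=
    "bimodal-valley": the histogram of log1p signal is lightly smoothed, the
    two largest modes found, and the cut set at the valley minimum between
    them; unimodal input falls back to the median (logged).
    """
    x = np.asarray(signals, dtype=float)
    if x.size < 100:
        raise ValueError("calibrate_cuts needs >= 100 sites")
    if x.std() == 0:
        raise ValueError("degenerate constant signal")
    if method == "quantile":
        return float(np.quantile(x, param))
    if method != "bimodal-valley":
        raise ValueError(f"unknown method {method!r}")
    lx = np.log1p(x)
    hist, edges = np.histogram(lx, bins=bins)
    # heavy Gaussian smoothing so sampling noise inside a mode does not
    # masquerade as extra modes
    grid = np.arange(-6, 7)
    kernel = np.exp(-0.5 * (grid / 2.0) ** 2)
    smooth = np.convolve(hist, kernel / kernel.sum(), mode="same")
    maxima = [
        i for i in range(1, bins - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] > smooth[i + 1]
    ]
    maxima.sort(key=lambda i: -smooth[i])
    min_sep = max(3, bins // 8)
    top2 = None
    for j in maxima[1:]:
        if maxima and abs(j - maxima[0]) >= min_sep:
            top2 = sorted((maxima[0], j))
            break
    if top2 is None:
        logger.info("unimodal signal histogram; falling back to median cut")
        return float(np.median(x))
    valley = top2[0] + int(np.argmin(smooth[top2[0]:top2[1] + 1]))
    return float(np.expm1((edges[valley] + edges[valley + 1]) / 2))


def annotate_peaks(
    peaks,
    gene_model: GeneModel,
    promoter_up: int = 1000,
    promoter_down: int = 100,
    tts_up: int = 100,
    tts_down: int = 1000,
) -> list[GenomicAnnotation]:
    """Assign one annotation per peak from its summit position.

    The assignment depends only on the summit, never on the peak width. An
    empty gene model yields all-intergenic.
    """
    windows: dict[GenomicAnnotation, dict[str, list[tuple[int, int]]]] = {
        a: {} for a in ANNOTATION_PRIORITY[:-1]
    }

    def add(kind, chrom, s, e):
        if s < e:
            windows[kind].setdefault(chrom, []).append((s, e))

    for _, g in gene_model.genes.iterrows():
        if g.strand == "+":
            add(GenomicAnnotation.promoter, g.chrom, g.tss - promoter_up, g.tss + promoter_down)
            add(GenomicAnnotation.tts, g.chrom, g.tes - tts_up, g.tes + tts_down)
        else:
            add(GenomicAnnotation.promoter, g.chrom, g.tss - promoter_down + 1, g.tss + promoter_up + 1)
            add(GenomicAnnotation.tts, g.chrom, g.tes - tts_down + 1, g.tes + tts_up + 1)
        add(GenomicAnnotation.intron, g.chrom, g.start, g.end)
    for _, f in gene_model.features.iterrows():
        kind = (GenomicAnnotation.five_prime_utr if f.feature == "five_prime_utr"
                else GenomicAnnotation.exon)
        add(kind, f.chrom, f.start, f.end)

    arrays = {
        kind: {
            chrom: (np.array([s for s, _ in sorted(iv)]), np.array([e for _, e in sorted(iv)]))
            for chrom, iv in per.items()
        }
        for kind, per in windows.items()
    }

    def contains(kind, chrom, pos) -> bool:
        per = arrays[kind]
        if chrom not in per:
            return False
        starts, ends = per[chrom]
        return bool(np.any((starts <= pos) & (pos < ends)))

    out = []
    for p in peaks:
        for kind in ANNOTATION_PRIORITY[:-1]:
            if contains(kind, p.chrom, p.summit):
                out.append(kind)
                break
        else:
            out.append(GenomicAnnotation.intergenic)
    return out


def category_proportions(categories) -> pd.Series:
    """Fraction of sites per chromatin category (sums to 1)."""
    s = pd.Series([c.value for c in categories])
    props = s.value_counts(normalize=True)
    return props.reindex([c.value for c in ChromatinCategory], fill_value=0.0)
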