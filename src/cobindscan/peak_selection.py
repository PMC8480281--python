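"""Peak-strength thresholds and "strongest 20%" class construction.

Called-peak criteria follow MACS2 post-filters (pileup >= 50, fold enrichment
over input >= 5, both inclusive). Top-fraction selection uses
threshold-then-include semantics: the pileup of the ceil(f*N)-th strongest
peak becomes the class threshold and ties at that threshold are kept, so the
realized fraction can slightly exceed the requested one (e.g. 20.1%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genomic_io import Peak


@dataclass(frozen=True)
class StrengthClass:
    label: str
    requested_fraction: float
    threshold: float
    realized_fraction: float


def filter_called_peaks(peaks, min_pileup: float = 50.0, min_fe: float = 5.0) -> list[Peak]:
    """Keep peaks with pileup >= min_pileup and fold enrichment >= min_fe."""
    return [p for p in peaks if p.pileup >= min_pileup and p.fold_enrichment >= min_fe]


def _strength_order(peaks) -> list[int]:
    # descending pileup, stabilized by (chrom, start) for order independence
    return sorted(range(len(peaks)), key=lambda i: (-peaks[i].pileup, peaks[i].chrom, peaks[i].start))


def select_top_fraction(peaks, fraction: float = 0.2, label: str = "top20"):
    """Strongest `fraction` of peaks by pileup, ties at the threshold included.

    Returns (subset, StrengthClass). Raises on empty input or fraction
    outside (0, 1].
    """
    if not peaks:
        raise ValueError("select_top_fraction: empty peak list")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    order = _strength_order(peaks)
    k = math.ceil(fraction * len(peaks))
    threshold = peaks[order[k - 1]].pileup
    subset = [p for p in peaks if p.pileup >= threshold]
    cls = StrengthClass(label, fraction, threshold, len(subset) / len(peaks))
    return subset, cls


def strength_bands(peaks, cuts) -> list[list[Peak]]:
    """Partition peaks into len(cuts)+1 pileup bands.

    Band i holds peaks with cuts[i-1] <= pileup < cuts[i]; the last band is
    pileup >= cuts[-1] (so a single cut of 270 puts pileup 269 in the lower
    band). cuts must be strictly increasing.
    """
    cuts = list(cuts)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cuts must be strictly increasing")
    bands: list[list[Peak]] = [[] for _ in range(len(cuts) + 1)]
    edges = np.array(cuts, dtype=float)
    for p in peaks:
        bands[int(np.searchsorted(edges, p.pileup, side="right"))].append(p)
    return bands
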