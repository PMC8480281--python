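"""Summit-distance co-binding discovery and site-class construction.

Two factors co-bind a genomic location when the absolute summits of their
peaks lie within a distance threshold (default 200 bp, inclusive). Matching
is greedy one-to-one nearest-neighbor: candidate pairs at distance <= the
threshold are taken in ascending-distance order, each peak used at most once,
so a co-bound site is a unique pair of peaks. From the strong (top-class)
peak sets of factors A and B this yields three disjoint site classes: AB
(strong A matched to strong B — FR-20-style), A-only and B-only. The
enhancer filter then drops sites annotated to promoter or 5'UTR sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chromatin import GenomicAnnotation
from .genomic_io import Peak
from .signal_quant import round_half_up


@dataclass(frozen=True)
class CoboundSite:
    """A matched pair of peaks from two factors and their summit distance."""

    peak_a: Peak
    peak_b: Peak
    distance: int

    def anchor(self, which: str = "A") -> int:
        """Summit used for signal windows: "A" (FR-20-style) or "B" (RF-20-style)."""
        return self.peak_a.summit if which == "A" else self.peak_b.summit


@dataclass
class SiteClassSet:
    label: str
    sites: list = field(default_factory=list)   # CoboundSite for pair classes, Peak otherwise
    enhancer_filtered: bool = False

    def __len__(self):
        return len(self.sites)


def match_summits(peaks_a, peaks_b, max_dist: int = 200) -> list[CoboundSite]:
    """Greedy one-to-one nearest matching of summits within max_dist (inclusive).

    Candidates are processed in ascending-distance order with ties broken by
    leftmost A summit then leftmost B summit.
    """
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for j, p in enumerate(peaks_b):
        by_chrom_b.setdefault(p.chrom, []).append((p.summit, j))
    for lst in by_chrom_b.values():
        lst.sort()

    import bisect

    candidates = []
    for i, p in enumerate(peaks_a):
        lst = by_chrom_b.get(p.chrom)
        if not lst:
            continue
        lo = bisect.bisect_left(lst, (p.summit - max_dist, -1))
        hi = bisect.bisect_right(lst, (p.summit + max_dist, len(peaks_b)))
        for summit_b, j in lst[lo:hi]:
            candidates.append((abs(p.summit - summit_b), p.summit, summit_b, i, j))
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for dist, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(CoboundSite(peaks_a[i], peaks_b[j], dist))
    return pairs


def cobound_percentages(n_pairs: int, n_a: int, n_b: int) -> tuple[float, float]:
    """Pair count as a percentage of each factor's peaks, 1 decimal, half-up."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("peak totals must be positive")
    if n_pairs > min(n_a, n_b):
        raise ValueError("more pairs than peaks")
    return (round_half_up(100.0 * n_pairs / n_a, 1), round_half_up(100.0 * n_pairs / n_b, 1))


def build_site_classes(strong_a, strong_b, pairs, labels=("AB-20", "A-20", "B-20")):
    """Split strong peaks into co-bound and single-factor classes.

    AB = strong A peaks whose matched partner is a strong B peak; A-only =
    strong A without a strong-B partner; B-only symmetric. The classes are
    disjoint and |strong A| = |AB| + |A-only|.
    """
    strong_a_set = set(strong_a)
    strong_b_set = set(strong_b)
    ab = SiteClassSet(labels[0])
    matched_a: set[Peak] = set()
    matched_b: set[Peak] = set()
    for site in pairs:
        if site.peak_a in strong_a_set and site.peak_b in strong_b_set:
            ab.sites.append(site)
            matched_a.add(site.peak_a)
            matched_b.add(site.peak_b)
    a_only = SiteClassSet(labels[1], [p for p in strong_a if p not in matched_a])
    b_only = SiteClassSet(labels[2], [p for p in strong_b if p not in matched_b])
    return ab, a_only, b_only


def enhancer_filter(site_class: SiteClassSet, annotations: dict) -> SiteClassSet:
    """Drop members annotated to promoter or 5'UTR sequence.

    `annotations` maps a member's key peak name (the A-side peak for pair
    classes) to its GenomicAnnotation; a missing annotation is an error.
    """
    excluded = {GenomicAnnotation.promoter, GenomicAnnotation.five_prime_utr}
    kept = []
    for s in site_class.sites:
        key = s.peak_a.name if isinstance(s, CoboundSite) else s.name
        if key not in annotations:
            raise KeyError(f"no annotation for site {key!r}")
        if annotations[key] not in excluded:
            kept.append(s)
    return SiteClassSet(site_class.label + "_enhancer", kept, enhancer_filtered=True)


def cross_sample_overlap(sites_x, sites_y, max_dist: int = 200) -> tuple[int, int]:
    """Count X sites with any Y summit within max_dist; percent of X as integer.

    Inputs are summit-anchored (chrom, summit) pairs, Peaks, or CoboundSites
    (anchored on the A-side summit).
    """

    def anchors(sites):
        out = []
        for s in sites:
            if isinstance(s, CoboundSite):
                out.append((s.peak_a.chrom, s.peak_a.summit))
            elif isinstance(s, Peak):
                out.append((s.chrom, s.summit))
            else:
                out.append((s[0], int(s[1])))
        return out

    import bisect

    ys: dict[str, list[int]] = {}
    for chrom, pos in anchors(sites_y):
        ys.setdefault(chrom, []).append(pos)
    for lst in ys.values():
        lst.sort()
    xs = anchors(sites_x)
    n = 0
    for chrom, pos in xs:
        lst = ys.get(chrom)
        if not lst:
            continue
        k = bisect.bisect_left(lst, pos - max_dist)
        if k < len(lst) and lst[k] <= pos + max_dist:
            n += 1
    if not xs:
        raise ValueError("empty X site list")
    return n, int(round_half_up(100.0 * n / len(xs), 0))
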