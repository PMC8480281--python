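"""Readers, writers and interval primitives for the formats the pipeline touches.

All coordinates are 0-based half-open (BED convention). GTF input is converted
on read. Peaks are unstranded; strand is honored only in gene models. The
narrowPeak ``signalValue`` column carries the MACS2 pileup and the following
column carries fold enrichment over input — a stated contract of this pipeline.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "pileup", "fold_enrichment", "qvalue", "summit_offset",
]


class ParseError(ValueError):
    """A malformed record in an input file; message names the line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths in bp."""

    lengths: dict[str, int]

    def __post_init__(self):
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("duplicate chromosome names")
        for name, length in self.lengths.items():
            if int(length) < 1:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def clip(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Clip an interval to [0, length); logs when clipping occurs."""
        n = self.lengths[chrom]
        cs, ce = max(0, start), min(n, end)
        if (cs, ce) != (start, end):
            logger.info("clipped interval %s:[%d,%d) to [%d,%d)", chrom, start, end, cs, ce)
        return cs, ce


@dataclass(frozen=True)
class Peak:
    """One called binding site: interval, absolute summit, pileup, fold enrichment."""

    chrom: str
    start: int
    end: int
    summit: int
    pileup: float
    fold_enrichment: float
    name: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"peak {self.name}: start {self.start} >= end {self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.name}: summit {self.summit} outside [{self.start},{self.end})"
            )
        if self.pileup < 0 or self.fold_enrichment < 0:
            raise ValueError(f"peak {self.name}: negative pileup or fold enrichment")


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_narrowpeak(path) -> list[Peak]:
    """Read ENCODE narrowPeak (BED6+4) into Peaks, order preserved.

    col7 (signalValue) -> pileup, col8 -> fold enrichment, col10 -> summit
    offset from start; a negative offset falls back to the interval midpoint.
    """
    peaks = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ParseError(
                    f"{path}: line {lineno}: expected 10 tab-separated columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                pileup = float(fields[6])
                fe = float(fields[7])
                offset = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if offset >= end - start:
                raise ParseError(
                    f"{path}: line {lineno}: summit offset {offset} >= peak length {end - start}"
                )
            summit = start + offset if offset >= 0 else start + (end - start) // 2
            try:
                peaks.append(Peak(chrom, start, end, summit, pileup, fe, name))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(peaks, path) -> None:
    """Write Peaks as narrowPeak; inverse of :func:`read_narrowpeak`."""
    with _open_text(path, "wt") as fh:
        for p in peaks:
            offset = p.summit - p.start
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                f"{p.pileup:.17g}\t{p.fold_enrichment:.17g}\t-1\t{offset}\n"
            )


def peaks_to_frame(peaks) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "summit": [p.summit for p in peaks],
            "pileup": [p.pileup for p in peaks],
            "fold_enrichment": [p.fold_enrichment for p in peaks],
            "name": [p.name for p in peaks],
        }
    )


@dataclass
class BlacklistSet:
    """Intervals prone to artifact; same coordinate convention as peaks."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @classmethod
    def from_bed(cls, path) -> "BlacklistSet":
        out = []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(f"{path}: line {lineno}: expected >= 3 BED columns")
                out.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(out)

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in self.intervals)


def subtract_blacklist(peaks, blacklist: BlacklistSet, mode: str = "summit") -> list[Peak]:
    """Remove blacklisted peaks.

    mode="summit" (default) removes peaks whose summit falls inside a
    blacklist interval; mode="overlap" removes peaks with any interval
    overlap. Summit containment is the default because all downstream logic
    is summit-centric.
    """
    if mode not in ("summit", "overlap"):
        raise ValueError(f"unknown blacklist mode {mode!r}")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in blacklist.intervals:
        by_chrom.setdefault(c, []).append((s, e))
    starts_ends = {
        c: (np.array(sorted(s for s, _ in iv)), np.array([e for _, e in sorted(iv)]))
        for c, iv in by_chrom.items()
    }

    def hit(p: Peak) -> bool:
        if p.chrom not in starts_ends:
            return False
        starts, ends = starts_ends[p.chrom]
        if mode == "summit":
            return bool(np.any((starts <= p.summit) & (p.summit < ends)))
        return bool(np.any((starts < p.end) & (p.start < ends)))

    return [p for p in peaks if not hit(p)]


class CoverageTrack:
    """Piecewise-constant read coverage, queryable by interval.

    Stored per chromosome as sorted, non-overlapping (start, end, value) runs
    with a precomputed cumulative integral, so window sums are exact and O(log n).
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 layout: GenomeLayout | None = None):
        self._runs = {}
        self.layout = layout
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted run")
            if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: runs overlap or are unsorted")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative coverage value")
            cum = np.concatenate([[0.0], np.cumsum((ends - starts) * values)])
            self._runs[chrom] = (starts, ends, values, cum)

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over [start, end); off-chromosome parts clip to 0."""
        if start >= end:
            raise ValueError(f"empty query interval [{start},{end})")
        if self.layout is not None and chrom in self.layout:
            start, end = self.layout.clip(chrom, start, end)
            if start >= end:
                return 0.0
        if chrom not in self._runs:
            return 0.0
        starts, ends, values, cum = self._runs[chrom]
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i0 >= i1:
            return 0.0
        total = cum[i1] - cum[i0]
        # trim partial first/last runs
        total -= max(0, start - starts[i0]) * values[i0]
        total -= max(0, ends[i1 - 1] - end) * values[i1 - 1]
        return float(total)

    def interval_sums(self, chrom: str, starts, ends) -> np.ndarray:
        return np.array([self.interval_sum(chrom, s, e) for s, e in zip(starts, ends)])

    def reencoded(self, pieces: int = 2) -> "CoverageTrack":
        """Return an equivalent track with every run split into `pieces` runs."""
        out = {}
        for chrom, (starts, ends, values, _) in self._runs.items():
            ns, ne, nv = [], [], []
            for s, e, v in zip(starts, ends, values):
                cuts = np.unique(np.linspace(s, e, pieces + 1).astype(np.int64))
                for a, b in zip(cuts[:-1], cuts[1:]):
                    ns.append(a), ne.append(b), nv.append(v)
            out[chrom] = (np.array(ns), np.array(ne), np.array(nv))
        return CoverageTrack(out, layout=self.layout)

    @classmethod
    def from_bedgraph(cls, path, layout: GenomeLayout | None = None) -> "CoverageTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
        )
        runs = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            runs[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(), sub["value"].to_numpy())
        return cls(runs, layout=layout)

    def to_bedgraph(self, path) -> None:
        frames = []
        for chrom, (starts, ends, values, _) in self._runs.items():
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": values}))
        df = pd.concat(frames) if frames else pd.DataFrame(columns=["chrom", "start", "end", "value"])
        df.to_csv(path, sep="\t", header=False, index=False)


def interval_coverage_sum(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Module-level convenience wrapper over :meth:`CoverageTrack.interval_sum`."""
    return track.interval_sum(chrom, start, end)


@dataclass
class GeneModel:
    """Minimal gene model: per-gene TSS/TES/strand plus exon and 5'UTR intervals.

    ``genes`` columns: gene_id, chrom, start, end, strand, tss, tes.
    ``features`` columns: gene_id, chrom, start, end, feature (exon | five_prime_utr).
    """

    genes: pd.DataFrame
    features: pd.DataFrame

    @classmethod
    def from_gtf(cls, path) -> "GeneModel":
        import pyranges

        df = pyranges.read_gtf(str(path)).df
        g = df[df.Feature == "gene"]
        if g.empty:  # fall back to transcript records
            g = df[df.Feature == "transcript"]
        strand = g.Strand.to_numpy()
        start = g.Start.to_numpy()
        end = g.End.to_numpy()
        tss = np.where(strand == "+", start, end - 1)
        tes = np.where(strand == "+", end - 1, start)
        genes = pd.DataFrame(
            {
                "gene_id": g.gene_id.to_numpy(),
                "chrom": g.Chromosome.astype(str).to_numpy(),
                "start": start,
                "end": end,
                "strand": strand,
                "tss": tss,
                "tes": tes,
            }
        ).reset_index(drop=True)
        f = df[df.Feature.isin(["exon", "five_prime_utr"])]
        features = pd.DataFrame(
            {
                "gene_id": f.gene_id.to_numpy(),
                "chrom": f.Chromosome.astype(str).to_numpy(),
                "start": f.Start.to_numpy(),
                "end": f.End.to_numpy(),
                "feature": f.Feature.to_numpy(),
            }
        ).reset_index(drop=True)
        return cls(genes, features)

    def to_gtf(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for _, g in self.genes.iterrows():
                attrs = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\tcobindscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                feats = self.features[self.features.gene_id == g.gene_id]
                for _, r in feats.iterrows():
                    fh.write(
                        f"{r.chrom}\tcobindscan\t{r.feature}\t{r.start + 1}\t{r.end}\t.\t"
                        f'{g.strand}\t.\t{attrs} transcript_id "{g.gene_id}.t1";\n'
                    )
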