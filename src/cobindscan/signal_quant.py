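"""Window signal quantification around peak summits.

ChIP/ATAC signal at a site is the coverage integral over a half-open
summit-centered window [summit-h, summit+h); with the default h=300 for
transcription factors this is the "reads/600 bp" quantity, and with h=1000
for histone marks "reads/2000 bp". Group comparisons report mean +- SEM and a
two-sided Welch (unequal-variance) t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import CoverageTrack

TF_HALFWIDTH = 300
HISTONE_HALFWIDTH = 1000


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the displayed precision (printed values only)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SiteSignalMatrix:
    """Sites x samples window read counts plus per-site metadata.

    ``sites`` carries chrom / summit / source peak id / class labels; signal
    columns are added one per sample with their window half-width recorded.
    """

    sites: pd.DataFrame
    signal: pd.DataFrame = None
    halfwidths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.signal is None:
            self.signal = pd.DataFrame(index=self.sites.index)

    def add_column(self, name: str, track: CoverageTrack, halfwidth: int = TF_HALFWIDTH,
                   anchor: str = "summit") -> None:
        """Quantify `track` in +-halfwidth windows around the `anchor` column."""
        self.signal[name] = quantify_sites(self.sites, track, halfwidth, anchor=anchor)
        self.halfwidths[name] = halfwidth

    def to_tsv(self, path) -> None:
        meta = " ".join(f"{k}={v}" for k, v in self.halfwidths.items())
        df = pd.concat([self.sites, self.signal], axis=1)
        with open(path, "w") as fh:
            fh.write(f"# window halfwidths (bp): {meta}\n")
            df.to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float


def quantify_sites(sites: pd.DataFrame, track: CoverageTrack, halfwidth: int = TF_HALFWIDTH,
                   anchor: str = "summit") -> np.ndarray:
    """Coverage sum over [anchor-halfwidth, anchor+halfwidth) per site.

    Windows running off a chromosome end are clipped by the track's layout.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    out = np.empty(len(sites))
    anchors = sites[anchor].to_numpy()
    chroms = sites["chrom"].to_numpy()
    for i, (chrom, pos) in enumerate(zip(chroms, anchors)):
        out[i] = track.interval_sum(chrom, int(pos) - halfwidth, int(pos) + halfwidth)
    return out


def summarize_group(values, label: str = "") -> GroupSummary:
    """Mean and SEM (sample SD / sqrt(n)) of a group of window counts."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("summarize_group requires >= 2 values")
    return GroupSummary(label, values.size, float(values.mean()),
                        float(values.std(ddof=1) / np.sqrt(values.size)))


def welch_t(a, b) -> tuple[float, float]:
    """Two-sided Welch t test; both-constant equal groups give p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    if a.std() == 0 and b.std() == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def percent_change(mean_before: float, mean_after: float) -> float:
    """Percent reduction of the mean, rounded half-up to 1 decimal."""
    if mean_before <= 0:
        raise ValueError("percent_change requires mean_before > 0")
    return round_half_up(100.0 * (mean_before - mean_after) / mean_before, 1)


def signal_correlation(matrix: SiteSignalMatrix, col_a: str, col_b: str) -> float:
    """Pearson r between two signal columns; NaN if a column has zero variance."""
    a = matrix.signal[col_a].to_numpy(dtype=float)
    b = matrix.signal[col_b].to_numpy(dtype=float)
    if a.size < 3:
        raise ValueError("signal_correlation requires >= 3 rows")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
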