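"""Synthetic peak sets, coverage tracks, gene models and expression tables.

Every generator plants a known ground truth (co-bound pairs, chromatin
classes, per-group signal fold changes, a global between-condition scale
factor, up/down-regulated genes) so each downstream stage of the pipeline can
be scored against what was planted, without any external data. All
randomness flows from a single seed; identical configs give identical data.

Coverage bumps are triangular with configurable half-width (default 150 bp),
discretized at 10 bp resolution: simple, exactly integrable as represented,
and fully contained in a +-300 bp summit window whenever the planted summit
offset stays <= 150 bp. Site strength and narrowPeak pileup are tied (the
pileup is the bump's peak height), so "strongest 20%" classes are meaningful
in synthesis. Signal noise is multiplicative log-normal, matching the
ratio-based downstream analysis of positively valued, right-skewed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .chromatin import ChromatinCategory
from .differential import EnhancerGroup
from .genomic_io import BlacklistSet, CoverageTrack, GeneModel, GenomeLayout, Peak

DEFAULT_GROUP_EFFECTS = {
    "group1": {"RUNX1": 0.6, "CEBPA": 1.5},
    "group2": {"RUNX1": 0.6, "CEBPA": 0.7},
    "group3": {"RUNX1": 1.5, "CEBPA": 1.4},
    "group4": {"RUNX1": 1.5, "CEBPA": 0.7},
}

DEFAULT_GROUP_PROPORTIONS = {"group1": 0.39, "group2": 0.31, "group3": 0.15, "group4": 0.15}

DEFAULT_CHROMATIN_PROPORTIONS = {
    "activeA": 0.10, "activeB": 0.10, "primed": 0.21, "quiet": 0.59,
}


@dataclass
class ScenarioConfig:
    """Fully specifies one synthetic run; serializable to scenario.yaml."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 25_000_000, "chr2": 25_000_000}
    )
    # per-factor peak counts and log-normal pileup distribution parameters
    factors: dict[str, dict] = field(
        default_factory=lambda: {
            "FOXC1": {"n_peaks": 1200, "pileup_mu": 4.0, "pileup_sigma": 1.0},
            "RUNX1": {"n_peaks": 2000, "pileup_mu": 4.0, "pileup_sigma": 1.0},
            "CEBPA": {"n_peaks": 2000, "pileup_mu": 4.0, "pileup_sigma": 1.0},
        }
    )
    cobinding_fraction: float = 0.28
    cobound_pileup_boost: float = 1.5   # log-scale strength boost at co-bound sites
    max_summit_offset: int = 50
    match_threshold: int = 200
    chromatin_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHROMATIN_PROPORTIONS)
    )
    group_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS)
    )
    group_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_EFFECTS.items()}
    )
    redistribution_shared_fraction: float = 0.372
    scale_factor: float = 0.5
    noise_sigma: float = 0.1
    background: float = 0.05      # reads per base outside bumps
    bump_halfwidth: int = 150
    min_spacing: int = 4000
    n_genes: int = 400
    n_blacklist: int = 10
    expression: dict[str, int] = field(
        default_factory=lambda: {"n_genes": 2000, "n_up": 100, "n_down": 150}
    )

    def __post_init__(self):
        for name, props in (("chromatin", self.chromatin_proportions),
                            ("group", self.group_proportions)):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {total}, not 1")
        if not 0 <= self.cobinding_fraction <= 1:
            raise ValueError("cobinding fraction must lie in [0, 1]")
        if self.scale_factor <= 0:
            raise ValueError("scale factor must be > 0")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(dict(self.chrom_lengths))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What was planted, keyed so downstream recovery can be scored."""

    cobound_pairs: list[tuple[str, str]] = field(default_factory=list)
    chromatin: dict[str, str] = field(default_factory=dict)
    enhancer_groups: dict[str, str] = field(default_factory=dict)
    redistribution: dict[str, str] = field(default_factory=dict)
    scale_factor: float = 1.0
    up_genes: list[str] = field(default_factory=list)
    down_genes: list[str] = field(default_factory=list)
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)


def replace_pileup(peak: Peak, pileup: float) -> Peak:
    from dataclasses import replace

    return replace(peak, pileup=pileup)


def _spaced_summits(rng: np.random.Generator, layout: GenomeLayout, n: int,
                    min_spacing: int, margin: int = 500) -> list[tuple[str, int]]:
    """n summit positions, >= min_spacing apart, spread across chromosomes."""
    total = sum(layout.lengths.values())
    cells = []
    for chrom, length in layout.lengths.items():
        n_cells = (length - 2 * margin) // min_spacing
        cells.extend((chrom, i) for i in range(n_cells))
    if n > len(cells):
        raise ValueError(f"{n} peaks exceed genome capacity at spacing {min_spacing}")
    chosen = rng.choice(len(cells), size=n, replace=False)
    out = []
    for k in chosen:
        chrom, i = cells[k]
        base = margin + i * min_spacing
        out.append((chrom, base + int(rng.integers(0, min_spacing // 4))))
    out.sort()
    return out


def generate_peakset(rng: np.random.Generator, layout: GenomeLayout, factor_name: str,
                     n_peaks: int, pileup_mu: float = 4.0, pileup_sigma: float = 1.0,
                     min_spacing: int = 4000, width: int = 400) -> list[Peak]:
    """A sorted, non-degenerate peak set with log-normal pileups."""
    if n_peaks == 0:
        return []
    summits = _spaced_summits(rng, layout, n_peaks, min_spacing)
    pileups = rng.lognormal(pileup_mu, pileup_sigma, size=n_peaks)
    fes = rng.uniform(5.0, 50.0, size=n_peaks)
    peaks = []
    for i, ((chrom, summit), pu, fe) in enumerate(zip(summits, pileups, fes)):
        half = width // 2
        start = max(0, summit - half)
        end = min(layout.length(chrom), summit + half)
        peaks.append(Peak(chrom, start, end, summit, float(pu), float(fe),
                          name=f"{factor_name}_{i:05d}"))
    return peaks


def generate_cobound_pair(rng: np.random.Generator, layout: GenomeLayout,
                          n_a: int, n_b: int, fraction: float, max_offset: int,
                          match_threshold: int = 200, min_spacing: int = 4000,
                          name_a: str = "A", name_b: str = "B",
                          pileup_mu: float = 4.0, pileup_sigma: float = 1.0,
                          cobound_pileup_boost: float = 0.0):
    """Two peak sets where exactly round(fraction * n_a) A peaks have a B partner.

    Partner summits sit within max_offset of the A summit; all other B peaks
    are placed at least 10x match_threshold from any A summit, so a matcher
    at `match_threshold` recovers the planted pairs exactly.
    `cobound_pileup_boost` shifts the log-pileup location of both members of
    a planted pair, emulating the stabilized (stronger) binding at co-bound
    sites that makes strong-strong co-location enriched over independence.
    """
    if max_offset > match_threshold:
        raise ValueError("max offset must not exceed the matching threshold")
    peaks_a = generate_peakset(rng, layout, name_a, n_a, pileup_mu, pileup_sigma,
                               min_spacing=max(min_spacing, 20 * match_threshold + 2 * max_offset))
    n_pairs = round(fraction * n_a)
    partner_idx = sorted(rng.choice(n_a, size=n_pairs, replace=False)) if n_pairs else []
    truth = GroundTruth()
    peaks_b: list[Peak] = []
    pileups_b = rng.lognormal(pileup_mu, pileup_sigma, size=n_b)
    fes = rng.uniform(5.0, 50.0, size=n_b)
    if cobound_pileup_boost:
        boosted = rng.lognormal(pileup_mu + cobound_pileup_boost, pileup_sigma,
                                size=2 * len(partner_idx))
        new_a = list(peaks_a)
        for j, i in enumerate(partner_idx):
            new_a[i] = replace_pileup(peaks_a[i], float(boosted[j]))
            pileups_b[j] = boosted[len(partner_idx) + j]
        peaks_a = new_a
    k = 0
    for i in partner_idx:
        a = peaks_a[i]
        offset = int(rng.integers(-max_offset, max_offset + 1))
        summit = min(max(200, a.summit + offset), layout.length(a.chrom) - 200)
        b = Peak(a.chrom, summit - 200, summit + 200, summit,
                 float(pileups_b[k]), float(fes[k]), name=f"{name_b}_{k:05d}")
        peaks_b.append(b)
        truth.cobound_pairs.append((a.name, b.name))
        k += 1
    # remaining B peaks: >= 10x threshold away from every A summit
    a_positions: dict[str, np.ndarray] = {}
    for p in peaks_a:
        a_positions.setdefault(p.chrom, [])
    for p in peaks_a:
        a_positions[p.chrom].append(p.summit)
    a_positions = {c: np.array(sorted(v)) for c, v in a_positions.items()}
    exclusion = 10 * match_threshold
    attempts = 0
    while k < n_b:
        (chrom, summit), = _spaced_summits(rng, layout, 1, min_spacing)
        near = a_positions.get(chrom)
        if near is not None and near.size:
            j = np.searchsorted(near, summit)
            close = any(
                abs(int(near[jj]) - summit) < exclusion
                for jj in (j - 1, j) if 0 <= jj < near.size
            )
            if close:
                attempts += 1
                if attempts > 100 * n_b:
                    raise RuntimeError("could not place background peaks away from A summits")
                continue
        if any(q.chrom == chrom and abs(q.summit - summit) < exclusion for q in peaks_b):
            continue
        peaks_b.append(Peak(chrom, summit - 200, summit + 200, summit,
                            float(pileups_b[k]), float(fes[k]), name=f"{name_b}_{k:05d}"))
        k += 1
    peaks_b.sort(key=lambda p: (p.chrom, p.start))
    return peaks_a, peaks_b, truth


def generate_condition_counts(rng: np.random.Generator, n_sites: int, fold_changes,
                              scale_factor: float, noise_sigma: float,
                              base_mu: float = 6.0, base_sigma: float = 1.0):
    """Control and raw treated window counts with planted per-site fold changes.

    control ~ log-normal site strength; raw treated = control x fold x
    scale_factor x exp(N(0, sigma)).
    """
    fold = np.asarray(fold_changes, dtype=float)
    if fold.shape != (n_sites,):
        raise ValueError("one fold change per site required")
    control = rng.lognormal(base_mu, base_sigma, size=n_sites)
    noise = np.exp(rng.normal(0.0, noise_sigma, size=n_sites)) if noise_sigma > 0 else 1.0
    treated = control * fold * scale_factor * noise
    return control, treated


def _triangle_runs(summit: int, halfwidth: int, height: float, step: int = 10):
    """Discretized triangular bump runs (start, end, value)."""
    runs = []
    for left in range(summit - halfwidth, summit + halfwidth, step):
        right = min(left + step, summit + halfwidth)
        center = (left + right) / 2
        value = height * max(0.0, 1.0 - abs(center - summit) / halfwidth)
        runs.append((left, right, value))
    return runs


def build_track(sites, heights, layout: GenomeLayout, halfwidth: int = 150,
                background: float = 0.0, step: int = 10) -> CoverageTrack:
    """A coverage track with a triangular bump of peak `height` per site.

    `sites` are (chrom, summit) pairs; the continuous bump integral equals
    height x halfwidth. Background level fills the rest of the genome.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in layout.chroms}
    for (chrom, summit), h in zip(sites, heights):
        per_chrom[chrom].extend(_triangle_runs(int(summit), halfwidth, float(h), step))
    runs = {}
    for chrom, bumps in per_chrom.items():
        length = layout.length(chrom)
        # event sweep so overlapping bumps sum instead of clashing
        events: dict[int, float] = {0: 0.0, length: 0.0}
        for s, e, v in bumps:
            s, e = max(0, s), min(length, e)
            if s >= e or v == 0.0:
                continue
            events[s] = events.get(s, 0.0) + v
            events[e] = events.get(e, 0.0) - v
        breaks = sorted(events)
        starts, ends, values = [], [], []
        level = 0.0
        for a, b in zip(breaks[:-1], breaks[1:]):
            level += events[a]
            value = level + background
            if value > 0:
                starts.append(a), ends.append(b), values.append(value)
        if starts:
            runs[chrom] = (np.array(starts), np.array(ends), np.array(values))
    return CoverageTrack(runs, layout=layout)


def generate_condition_tracks(sites, group_labels, effects: dict, scale_factor: float,
                              rng: np.random.Generator, layout: GenomeLayout,
                              strengths=None, noise_sigma: float = 0.0,
                              halfwidth: int = 150, background: float = 0.0):
    """Control and treated coverage tracks with planted per-group fold changes.

    `sites` are (chrom, summit) pairs; `group_labels` index into `effects`
    (missing labels mean fold 1). The treated background scales with the
    global scale factor, as sequencing depth would. Returns (control track,
    treated track, truth) where truth records the per-site fold changes.
    """
    n = len(sites)
    strengths = (np.asarray(strengths, dtype=float) if strengths is not None
                 else rng.lognormal(4.0, 1.0, size=n))
    fold = np.array([float(effects.get(g, 1.0)) for g in group_labels])
    noise = np.exp(rng.normal(0.0, noise_sigma, size=n)) if noise_sigma > 0 else np.ones(n)
    control = build_track(sites, strengths, layout, halfwidth, background)
    treated = build_track(sites, strengths * fold * scale_factor * noise, layout,
                          halfwidth, background * scale_factor)
    truth = GroundTruth(scale_factor=scale_factor)
    truth.fold_changes["track"] = {f"site_{i}": float(f) for i, f in enumerate(fold)}
    return control, treated, truth


def generate_expression_table(rng: np.random.Generator, n_genes: int, n_up: int, n_down: int,
                              min_fpkm: float = 2.0, min_fold: float = 2.0):
    """(gene, FPKM control, FPKM KD) table with planted up/down genes.

    Planted up genes have KD/control >= min_fold with FPKM >= min_fpkm in
    the KD condition (down symmetric); null genes keep |log2 fold| < 1 so
    the expression filter recovers the planted lists exactly. A third of the
    nulls sit below the expressed cut in both conditions.
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    ctrl = np.empty(n_genes)
    kd = np.empty(n_genes)
    roles = np.array(["null"] * n_genes, dtype=object)
    idx = rng.permutation(n_genes)
    up_idx, down_idx = idx[:n_up], idx[n_up:n_up + n_down]
    roles[up_idx], roles[down_idx] = "up", "down"
    for i in range(n_genes):
        if roles[i] == "up":
            base = rng.uniform(min_fpkm, 50.0)
            ctrl[i] = base / rng.uniform(min_fold, 4 * min_fold)
            kd[i] = base
        elif roles[i] == "down":
            base = rng.uniform(min_fpkm, 50.0)
            ctrl[i] = base
            kd[i] = base / rng.uniform(min_fold, 4 * min_fold)
        else:
            lo = rng.uniform(0.1, min_fpkm * 0.9) if rng.random() < 1 / 3 \
                else rng.uniform(min_fpkm, 50.0)
            ctrl[i] = lo
            kd[i] = lo * 2 ** rng.uniform(-0.9, 0.9)
            if ctrl[i] < min_fpkm:  # keep fully silent genes silent
                kd[i] = min(kd[i], min_fpkm * 0.95)
    table = pd.DataFrame({"gene": genes, "fpkm_control": ctrl, "fpkm_kd": kd})
    truth = GroundTruth(
        up_genes=[genes[i] for i in sorted(up_idx)],
        down_genes=[genes[i] for i in sorted(down_idx)],
    )
    return table, truth


def generate_gene_model(rng: np.random.Generator, layout: GenomeLayout, n_genes: int,
                        spacing: int = 100_000) -> GeneModel:
    """A minimal strand-aware gene model with exons and 5'UTRs."""
    positions = _spaced_summits(rng, layout, n_genes, spacing, margin=10_000)
    gene_rows, feat_rows = [], []
    for i, (chrom, anchor) in enumerate(positions):
        gid = f"gene_{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(5_000, 40_000))
        start = anchor
        end = min(anchor + length, layout.length(chrom) - 1)
        tss = start if strand == "+" else end - 1
        tes = end - 1 if strand == "+" else start
        gene_rows.append((gid, chrom, start, end, strand, tss, tes))
        # 3 exons: first holds a 200 bp 5'UTR at the TSS end
        exon_len = max(200, (end - start) // 10)
        bounds = [start, start + exon_len,
                  (start + end) // 2, (start + end) // 2 + exon_len,
                  end - exon_len, end]
        for a, b in zip(bounds[::2], bounds[1::2]):
            feat_rows.append((gid, chrom, a, b, "exon"))
        if strand == "+":
            feat_rows.append((gid, chrom, start, start + 200, "five_prime_utr"))
        else:
            feat_rows.append((gid, chrom, end - 200, end, "five_prime_utr"))
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chrom", "start", "end", "strand", "tss", "tes"])
    feats = pd.DataFrame(feat_rows, columns=["gene_id", "chrom", "start", "end", "feature"])
    return GeneModel(genes, feats)


def generate_chromatin_labels(rng: np.random.Generator, names, proportions: dict[str, float]):
    """Assign each site a chromatin category by the mixture proportions."""
    cats = list(proportions)
    p = np.array([proportions[c] for c in cats])
    draws = rng.choice(len(cats), size=len(names), p=p / p.sum())
    return {name: cats[d] for name, d in zip(names, draws)}


def chromatin_signal_levels(rng: np.random.Generator, labels: dict[str, str],
                            high_mu: float = np.log(800.0), low_mu: float = np.log(50.0),
                            sigma: float = 0.3):
    """Per-site (H3K27Ac, H3K4Me1) bump heights realizing the planted categories."""
    high_map = {
        "activeA": (True, True), "activeB": (True, False),
        "primed": (False, True), "quiet": (False, False),
    }
    k27, k4 = {}, {}
    for name, cat in labels.items():
        k27_high, k4_high = high_map[cat]
        k27[name] = float(rng.lognormal(high_mu if k27_high else low_mu, sigma))
        k4[name] = float(rng.lognormal(high_mu if k4_high else low_mu, sigma))
    return k27, k4


def generate_redistribution_sets(rng: np.random.Generator, layout: GenomeLayout,
                                 n_ctrl: int, n_kd: int, shared_fraction: float,
                                 max_offset: int = 50, match_threshold: int = 200,
                                 min_spacing: int = 4000):
    """Two strong-peak sets where round(shared_fraction * n_kd) KD peaks sit
    within max_offset of a control peak and the rest are far from all of them."""
    ctrl, kd, pair_truth = generate_cobound_pair(
        rng, layout, n_ctrl, n_kd, fraction=round(shared_fraction * n_kd) / n_ctrl,
        max_offset=max_offset, match_threshold=match_threshold, min_spacing=min_spacing,
        name_a="RUNX1_NTC", name_b="RUNX1_KD",
    )
    truth = GroundTruth(redistribution={})
    shared_ctrl = {a for a, _ in pair_truth.cobound_pairs}
    shared_kd = {b for _, b in pair_truth.cobound_pairs}
    for p in ctrl:
        truth.redistribution[p.name] = "B" if p.name in shared_ctrl else "A"
    for p in kd:
        truth.redistribution[p.name] = "B" if p.name in shared_kd else "C"
    return ctrl, kd, truth


def generate_blacklist(rng: np.random.Generator, layout: GenomeLayout, n: int,
                       width: int = 10_000, avoid=None) -> BlacklistSet:
    """n artifact intervals, optionally avoiding a set of summit positions."""
    avoid_pos: dict[str, np.ndarray] = {}
    for s in avoid or []:
        chrom, pos = (s.chrom, s.summit) if hasattr(s, "summit") else (s[0], int(s[1]))
        avoid_pos.setdefault(chrom, []).append(pos)
    avoid_pos = {c: np.sort(np.array(v)) for c, v in avoid_pos.items()}
    intervals = []
    guard = 0
    while len(intervals) < n:
        guard += 1
        if guard > 1000 * max(n, 1):
            raise RuntimeError("could not place blacklist intervals")
        chrom = layout.chroms[int(rng.integers(len(layout.chroms)))]
        start = int(rng.integers(0, layout.length(chrom) - width))
        pos = avoid_pos.get(chrom)
        if pos is not None and pos.size:
            j0 = np.searchsorted(pos, start - 500)
            j1 = np.searchsorted(pos, start + width + 500)
            if j1 > j0:
                continue
        intervals.append((chrom, start, start + width))
    return BlacklistSet(intervals)
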