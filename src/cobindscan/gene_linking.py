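"""Region-to-gene assignment, expression filtering and pre-ranked GSEA.

Genes receive a basal regulatory domain of [TSS-5000, TSS+1000) oriented by
strand, extended up to 1 Mb in each direction but stopped at the nearest
neighboring gene's basal domain (basal-plus-extension rule, GREAT defaults).
A genomic site is linked to every gene whose extended domain contains its
summit.

Expression filtering keeps genes at >= 2 FPKM in at least one condition and
calls them up/down at a >= 2-fold change (a zero denominator counts as an
infinite fold change and qualifies). Enrichment of a gene set in a
fold-change-ranked list is scored with the weighted Kolmogorov-Smirnov
running sum; significance comes from size-matched random gene-set draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GeneModel


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal_start: int
    basal_end: int
    ext_start: int
    ext_end: int


def expression_filter(table: pd.DataFrame, min_fpkm: float = 2.0, min_fold: float = 2.0,
                      control_col: str = "fpkm_control", kd_col: str = "fpkm_kd"):
    """Split a (gene, FPKM per condition) table into expressed / up / down gene lists.

    up: expressed and KD/control >= min_fold; down: expressed and
    control/KD >= min_fold. Returns three lists of gene ids.
    """
    ctrl = table[control_col].to_numpy(dtype=float)
    kd = table[kd_col].to_numpy(dtype=float)
    if np.any(ctrl < 0) or np.any(kd < 0):
        raise ValueError("negative FPKM")
    expressed = (ctrl >= min_fpkm) | (kd >= min_fpkm)
    with np.errstate(divide="ignore", invalid="ignore"):
        up = expressed & np.where(ctrl > 0, kd / np.maximum(ctrl, 1e-300) >= min_fold, kd > 0)
        down = expressed & np.where(kd > 0, ctrl / np.maximum(kd, 1e-300) >= min_fold, ctrl > 0)
    genes = table["gene"].to_numpy()
    return list(genes[expressed]), list(genes[up]), list(genes[down])


def log2_fold_changes(table: pd.DataFrame, pseudo: float = 0.1,
                      control_col: str = "fpkm_control", kd_col: str = "fpkm_kd") -> pd.Series:
    """log2(KD/control) with a pseudo-count, for ranking only (not for the 2-fold filter).

    Duplicate gene symbols collapse to the max-|log2FC| entry.
    """
    lfc = np.log2((table[kd_col] + pseudo) / (table[control_col] + pseudo))
    s = pd.Series(lfc.to_numpy(), index=table["gene"].to_numpy())
    if s.index.has_duplicates:
        s = s.groupby(level=0).agg(lambda v: v.iloc[np.argmax(np.abs(v.to_numpy()))])
    return s.sort_values(ascending=False)


def build_regulatory_domains(gene_model: GeneModel, basal_up: int = 5000, basal_down: int = 1000,
                             max_ext: int = 1_000_000,
                             chrom_lengths: dict[str, int] | None = None) -> list[RegulatoryDomain]:
    """GREAT basal-plus-extension regulatory domains, one per gene."""
    out = []
    genes = gene_model.genes
    for chrom, sub in genes.groupby("chrom", sort=False):
        sub = sub.sort_values("tss").reset_index(drop=True)
        basal = []
        for _, g in sub.iterrows():
            if g.strand == "+":
                bs, be = g.tss - basal_up, g.tss + basal_down
            else:
                bs, be = g.tss - basal_down + 1, g.tss + basal_up + 1
            basal.append((max(0, bs), be))
        n_chrom = chrom_lengths.get(chrom) if chrom_lengths else None
        for i, (_, g) in enumerate(sub.iterrows()):
            bs, be = basal[i]
            left_ends = [basal[j][1] for j in range(len(basal)) if j != i and basal[j][1] <= bs]
            left_lim = max(left_ends) if left_ends else 0
            right_starts = [basal[j][0] for j in range(len(basal)) if j != i and basal[j][0] >= be]
            right_lim = min(right_starts) if right_starts else np.inf
            es = max(g.tss - max_ext, left_lim)
            ee = min(g.tss + max_ext, right_lim)
            es = min(es, bs)
            ee = max(ee, be)
            es = max(0, int(es))
            if n_chrom is not None:
                ee = min(int(ee), n_chrom)
                be = min(be, n_chrom)
            else:
                ee = int(min(ee, 2**62))
            out.append(RegulatoryDomain(g.gene_id, chrom, bs, be, es, ee))
    return out


def sites_to_genes(sites, domains: list[RegulatoryDomain]) -> set[str]:
    """Genes with >= 1 site summit inside their extended regulatory domain.

    `sites` are (chrom, summit) pairs or objects with .chrom/.summit. A site
    may contribute to multiple genes.
    """
    anchors = []
    for s in sites:
        if hasattr(s, "summit"):
            anchors.append((s.chrom, s.summit))
        else:
            anchors.append((s[0], int(s[1])))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos in anchors:
        by_chrom.setdefault(chrom, []).append(pos)
    hit = set()
    for d in domains:
        positions = by_chrom.get(d.chrom)
        if not positions:
            continue
        if any(d.ext_start <= pos < d.ext_end for pos in positions):
            hit.add(d.gene_id)
    return hit


def enrichment_score(metric: np.ndarray, hits: np.ndarray, weight: float = 1.0):
    """Weighted KS running-sum enrichment score over a rank-ordered metric.

    `hits` is a boolean membership mask aligned with the ranking. Returns
    (ES, index of the running-sum extremum).
    """
    metric = np.asarray(metric, dtype=float)
    hits = np.asarray(hits, dtype=bool)
    w = np.abs(metric) ** weight
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit metrics are zero; fall back to uniform hit steps
        hit_w = hits.astype(float)
        denom = hit_w.sum()
    miss = (~hits) / (hits.size - hits.sum())
    path = np.cumsum(hit_w / denom - miss)
    i = int(np.argmax(np.abs(path)))
    return float(path[i]), i


def gsea_preranked(ranked: pd.Series, gene_set, weight: float = 1.0, n_perm: int = 1000,
                   seed: int | np.random.Generator = 0):
    """Weighted KS enrichment of `gene_set` in a descending-log2FC ranking.

    Hit steps are proportional to |rank metric|^weight, miss steps uniform;
    ES is the running-sum extremum. NES and p come from `n_perm` random
    gene sets of the same size (NES = ES / mean |null ES| of the same sign).
    Returns (ES, NES, p, leading_edge_genes).
    """
    genes = np.asarray(ranked.index)
    if pd.Index(genes).has_duplicates:
        raise ValueError("duplicate genes in ranking")
    metric = ranked.to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set))
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == genes.size:
        raise ValueError("gene set must intersect the ranking and be a strict subset")

    es, peak = enrichment_score(metric, in_set, weight)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.choice(genes.size, size=n_hit, replace=False)
        h = np.zeros(genes.size, dtype=bool)
        h[idx] = True
        null[k], _ = enrichment_score(metric, h, weight)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size:
        nes = es / np.abs(same_sign).mean()
        p = float((np.abs(same_sign) >= abs(es)).sum() + 1) / (same_sign.size + 1)
    else:
        nes, p = np.inf * np.sign(es), 1.0 / (n_perm + 1)
    if es >= 0:
        leading = [g for g, h in zip(genes[:peak + 1], in_set[:peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], in_set[peak:]) if h]
    return es, float(nes), p, leading
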