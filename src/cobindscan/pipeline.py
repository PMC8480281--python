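"""End-to-end orchestration: simulate a scenario, run the analysis, write outputs.

`simulate` materializes a complete, pipeline-ready input directory (peak
sets, coverage tracks, blacklist, gene model, expression table) plus a
ground-truth sidecar. `run` executes the analysis stages in order — called-
peak filtering, blacklist exclusion, strength classes, summit co-
localization, genomic annotation and enhancer filtering, chromatin
categorization, window quantification, running-mean normalization, enhancer
group and redistribution classification, and region-to-gene linking with
pre-ranked GSEA — writing TSV/BED outputs and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin as chrom_mod
from . import colocalization as coloc
from . import differential as diff
from . import gene_linking as genes_mod
from . import normalization as norm
from . import peak_selection as sel
from . import signal_quant as quant
from . import synthetic as synth
from .genomic_io import (BlacklistSet, CoverageTrack, GeneModel, GenomeLayout, Peak,
                         read_narrowpeak, subtract_blacklist, write_narrowpeak)

logger = logging.getLogger(__name__)
__version__ = "0.1.0"


@dataclass
class RunParams:
    """All analysis thresholds, with the pipeline's standard defaults."""

    min_pileup: float = 50.0
    min_fold_enrichment: float = 5.0
    top_fraction: float = 0.2
    match_threshold: int = 200
    tf_halfwidth: int = 300
    histone_halfwidth: int = 1000
    norm_window: int = 2500
    chromatin_cut_method: str = "bimodal-valley"
    blacklist_mode: str = "summit"
    great_basal_up: int = 5000
    great_basal_down: int = 1000
    great_max_ext: int = 1_000_000
    gsea_weight: float = 1.0
    gsea_n_perm: int = 200
    min_fpkm: float = 2.0
    min_expr_fold: float = 2.0
    seed: int = 0


def simulate(config: synth.ScenarioConfig, outdir) -> Path:
    """Generate a scenario's input directory plus ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    layout = config.layout

    gene_model = synth.generate_gene_model(rng, layout, config.n_genes)

    fx = config.factors
    foxc1, runx1, pair_truth = synth.generate_cobound_pair(
        rng, layout,
        n_a=fx["FOXC1"]["n_peaks"], n_b=fx["RUNX1"]["n_peaks"],
        fraction=config.cobinding_fraction, max_offset=config.max_summit_offset,
        match_threshold=config.match_threshold, min_spacing=config.min_spacing,
        name_a="FOXC1", name_b="RUNX1",
        pileup_mu=fx["FOXC1"]["pileup_mu"], pileup_sigma=fx["FOXC1"]["pileup_sigma"],
        cobound_pileup_boost=config.cobound_pileup_boost,
    )
    cebpa = synth.generate_peakset(
        rng, layout, "CEBPA", fx["CEBPA"]["n_peaks"],
        fx["CEBPA"]["pileup_mu"], fx["CEBPA"]["pileup_sigma"], config.min_spacing,
    )

    truth = synth.GroundTruth(cobound_pairs=pair_truth.cobound_pairs,
                              scale_factor=config.scale_factor)

    # enhancer groups planted on the co-bound pairs
    by_name = {p.name: p for p in foxc1 + runx1}
    groups = list(config.group_proportions)
    gp = np.array([config.group_proportions[g] for g in groups])
    draws = rng.choice(len(groups), size=len(truth.cobound_pairs), p=gp / gp.sum())
    pair_group = {}
    for (a_name, b_name), d in zip(truth.cobound_pairs, draws):
        pair_group[(a_name, b_name)] = groups[d]
        truth.enhancer_groups[a_name] = groups[d]

    # chromatin labels: one per genomic site (paired RUNX1 inherits its partner's)
    partner_of = dict(truth.cobound_pairs)
    paired_b = set(partner_of.values())
    site_names = [p.name for p in foxc1] + [p.name for p in runx1 if p.name not in paired_b]
    labels = synth.generate_chromatin_labels(rng, site_names, config.chromatin_proportions)
    for a_name, b_name in truth.cobound_pairs:
        labels[b_name] = labels[a_name]
    truth.chromatin = labels

    k27_h, k4_h = synth.chromatin_signal_levels(rng, {n: labels[n] for n in site_names})
    histone_sites = [(by_name[n].chrom, by_name[n].summit) for n in site_names]
    k27_track = synth.build_track(histone_sites, [k27_h[n] for n in site_names], layout,
                                  halfwidth=500, background=config.background)
    k4_track = synth.build_track(histone_sites, [k4_h[n] for n in site_names], layout,
                                 halfwidth=500, background=config.background)

    # RUNX1 condition tracks: bumps at every RUNX1 peak, planted folds at paired ones
    runx1_sites = [(p.chrom, p.summit) for p in runx1]
    runx1_strengths = np.array([p.pileup for p in runx1])
    b_group = {b: g for (a, b), g in pair_group.items()}
    runx1_folds = np.array([config.group_effects.get(b_group.get(p.name, ""), {}).get("RUNX1", 1.0)
                            for p in runx1])
    noise = lambda n: (np.exp(rng.normal(0, config.noise_sigma, n))
                       if config.noise_sigma > 0 else np.ones(n))
    runx1_ntc = synth.build_track(runx1_sites, runx1_strengths, layout,
                                  config.bump_halfwidth, config.background)
    runx1_kd = synth.build_track(
        runx1_sites, runx1_strengths * runx1_folds * config.scale_factor * noise(len(runx1)),
        layout, config.bump_halfwidth, config.background * config.scale_factor)
    truth.fold_changes["RUNX1"] = {p.name: float(f) for p, f in zip(runx1, runx1_folds)}

    # CEBPA condition tracks: own peaks (fold 1) plus bumps at pair sites with
    # the planted CEBPA fold, anchored on the FOXC1-side summit
    pair_sites = [(by_name[a].chrom, by_name[a].summit) for a, _ in truth.cobound_pairs]
    pair_strengths = rng.lognormal(fx["CEBPA"]["pileup_mu"], fx["CEBPA"]["pileup_sigma"],
                                   size=len(pair_sites))
    pair_folds = np.array([config.group_effects[pair_group[(a, b)]].get("CEBPA", 1.0)
                           for a, b in truth.cobound_pairs])
    cebpa_sites = [(p.chrom, p.summit) for p in cebpa] + pair_sites
    cebpa_strengths = np.concatenate([np.array([p.pileup for p in cebpa]), pair_strengths])
    cebpa_folds = np.concatenate([np.ones(len(cebpa)), pair_folds])
    cebpa_ntc = synth.build_track(cebpa_sites, cebpa_strengths, layout,
                                  config.bump_halfwidth, config.background)
    cebpa_kd = synth.build_track(
        cebpa_sites, cebpa_strengths * cebpa_folds * config.scale_factor * noise(len(cebpa_sites)),
        layout, config.bump_halfwidth, config.background * config.scale_factor)
    truth.fold_changes["CEBPA"] = {a: float(f)
                                   for (a, _), f in zip(truth.cobound_pairs, pair_folds)}

    # redistribution: strong RUNX1 sets in control vs knockdown conditions
    redist_ctrl, redist_kd, redist_truth = synth.generate_redistribution_sets(
        rng, layout, n_ctrl=400, n_kd=350,
        shared_fraction=config.redistribution_shared_fraction,
        max_offset=config.max_summit_offset, match_threshold=config.match_threshold,
        min_spacing=config.min_spacing)
    truth.redistribution = redist_truth.redistribution

    # blacklist avoiding real peaks, with planted artifact peaks inside it
    blacklist = synth.generate_blacklist(rng, layout, config.n_blacklist,
                                         avoid=foxc1 + runx1 + cebpa + redist_ctrl + redist_kd)
    decoys = []
    for i, (chrom, s, e) in enumerate(blacklist.intervals[:5]):
        mid = (s + e) // 2
        decoys.append(Peak(chrom, mid - 200, mid + 200, mid, 500.0, 20.0,
                           name=f"FOXC1_artifact_{i}"))

    # expression: planted up genes include those whose regulatory domains hold
    # a planted group-1 site, so gene linking + GSEA have signal to find
    expr_cfg = config.expression
    domains = genes_mod.build_regulatory_domains(gene_model, chrom_lengths=dict(layout.lengths))
    g1_sites = [(by_name[a].chrom, by_name[a].summit)
                for a, _ in truth.cobound_pairs if truth.enhancer_groups[a] == "group1"]
    g1_genes = sorted(genes_mod.sites_to_genes(g1_sites, domains))
    table, expr_truth = synth.generate_expression_table(
        rng, expr_cfg["n_genes"], expr_cfg["n_up"], expr_cfg["n_down"])
    # overwrite gene ids so the table covers the gene model, group-1-proximal
    # genes first among the planted ups
    model_ids = list(gene_model.genes.gene_id)
    ids = model_ids + [f"extra_{i:05d}" for i in range(len(table) - len(model_ids))]
    n_up = expr_cfg["n_up"]
    up_ids = (g1_genes + [g for g in ids if g not in set(g1_genes)])[:n_up]
    rest = [g for g in ids if g not in set(up_ids)]
    down_ids = rest[:expr_cfg["n_down"]]
    null_ids = rest[expr_cfg["n_down"]:]
    new_ids = np.empty(len(table), dtype=object)
    old_roles = (["up"] * len(expr_truth.up_genes) + ["down"] * len(expr_truth.down_genes)
                 + ["null"] * (len(table) - n_up - expr_cfg["n_down"]))
    order = {g: i for i, g in enumerate(table.gene)}
    up_iter, down_iter, null_iter = iter(up_ids), iter(down_ids), iter(null_ids)
    for i, g in enumerate(table.gene):
        if g in set(expr_truth.up_genes):
            new_ids[i] = next(up_iter)
        elif g in set(expr_truth.down_genes):
            new_ids[i] = next(down_iter)
        else:
            new_ids[i] = next(null_iter)
    table = table.assign(gene=new_ids)
    truth.up_genes = sorted(up_ids)
    truth.down_genes = sorted(down_ids)

    # ---- write everything ----
    pd.DataFrame({"chrom": layout.chroms,
                  "length": [layout.length(c) for c in layout.chroms]}
                 ).to_csv(outdir / "genome.tsv", sep="\t", index=False)
    write_narrowpeak(list(foxc1) + decoys, outdir / "foxc1_peaks.narrowPeak")
    write_narrowpeak(runx1, outdir / "runx1_ntc_peaks.narrowPeak")
    write_narrowpeak(cebpa, outdir / "cebpa_peaks.narrowPeak")
    write_narrowpeak(redist_ctrl, outdir / "runx1_strong_ntc.narrowPeak")
    write_narrowpeak(redist_kd, outdir / "runx1_strong_kd.narrowPeak")
    with open(outdir / "blacklist.bed", "w") as fh:
        for c, s, e in blacklist.intervals:
            fh.write(f"{c}\t{s}\t{e}\n")
    for name, track in [("runx1_ntc", runx1_ntc), ("runx1_kd", runx1_kd),
                        ("cebpa_ntc", cebpa_ntc), ("cebpa_kd", cebpa_kd),
                        ("h3k27ac", k27_track), ("h3k4me1", k4_track)]:
        track.to_bedgraph(outdir / f"{name}.bedGraph")
    gene_model.to_gtf(outdir / "genes.gtf")
    table.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "scenario.yaml")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=1)
    return outdir


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run(indir, outdir, params: RunParams | None = None) -> dict:
    """Execute the full analysis over a pipeline-ready input directory.

    Returns a results dict (also serialized into the output directory along
    with a manifest recording config, input checksums and stage counts).
    """
    params = params or RunParams()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(params), "inputs": {}, "counts": {},
                "version": __version__, "wallclock_s": {}}
    results: dict = {}
    t0 = time.time()

    def stage(name):
        manifest["wallclock_s"][name] = round(time.time() - t0, 3)

    required = ["genome.tsv", "foxc1_peaks.narrowPeak", "runx1_ntc_peaks.narrowPeak",
                "cebpa_peaks.narrowPeak", "runx1_strong_ntc.narrowPeak",
                "runx1_strong_kd.narrowPeak", "blacklist.bed", "runx1_ntc.bedGraph",
                "runx1_kd.bedGraph", "cebpa_ntc.bedGraph", "cebpa_kd.bedGraph",
                "h3k27ac.bedGraph", "h3k4me1.bedGraph", "genes.gtf", "expression.tsv"]
    for fname in required:
        path = indir / fname
        if not path.exists():
            raise FileNotFoundError(f"stage=load: missing input file {path}")
        manifest["inputs"][fname] = _checksum(path)

    genome = pd.read_csv(indir / "genome.tsv", sep="\t")
    layout = GenomeLayout(dict(zip(genome.chrom, genome.length)))
    blacklist = BlacklistSet.from_bed(indir / "blacklist.bed")
    tracks = {name: CoverageTrack.from_bedgraph(indir / f"{name}.bedGraph", layout)
              for name in ["runx1_ntc", "runx1_kd", "cebpa_ntc", "cebpa_kd",
                           "h3k27ac", "h3k4me1"]}
    gene_model = GeneModel.from_gtf(indir / "genes.gtf")
    expression = pd.read_csv(indir / "expression.tsv", sep="\t")

    # 1. filter: called-peak thresholds then blacklist exclusion
    peak_sets = {}
    for key, fname in [("FOXC1", "foxc1_peaks"), ("RUNX1", "runx1_ntc_peaks"),
                       ("CEBPA", "cebpa_peaks")]:
        raw = read_narrowpeak(indir / f"{fname}.narrowPeak")
        called = sel.filter_called_peaks(raw, params.min_pileup, params.min_fold_enrichment)
        kept = subtract_blacklist(called, blacklist, mode=params.blacklist_mode)
        peak_sets[key] = kept
        manifest["counts"][key] = {"raw": len(raw), "called": len(called),
                                   "after_blacklist": len(kept)}
    stage("filter")

    # 2. strength classes
    strong = {}
    for key, peaks in peak_sets.items():
        subset, cls = sel.select_top_fraction(peaks, params.top_fraction)
        strong[key] = subset
        manifest["counts"][f"{key}_top"] = {"n": len(subset), "threshold": cls.threshold,
                                            "realized_fraction": cls.realized_fraction}
    stage("classes")

    # 3. summit co-localization of FOXC1 and RUNX1
    pairs = coloc.match_summits(peak_sets["FOXC1"], peak_sets["RUNX1"],
                                params.match_threshold)
    pct_a, pct_b = coloc.cobound_percentages(len(pairs), len(peak_sets["FOXC1"]),
                                             len(peak_sets["RUNX1"]))
    results["n_cobound_pairs"] = len(pairs)
    results["cobound_pct_foxc1"] = pct_a
    results["cobound_pct_runx1"] = pct_b
    results["recovered_pairs"] = [(s.peak_a.name, s.peak_b.name) for s in pairs]
    fr20, f20, r20 = coloc.build_site_classes(strong["FOXC1"], strong["RUNX1"], pairs,
                                              labels=("FR-20", "F-20", "R-20"))
    stage("colocalize")

    # 4. annotation + enhancer filter
    all_named = peak_sets["FOXC1"] + peak_sets["RUNX1"] + peak_sets["CEBPA"]
    annotations = dict(zip((p.name for p in all_named),
                           chrom_mod.annotate_peaks(all_named, gene_model)))
    fr20_enh = coloc.enhancer_filter(fr20, annotations)
    f20_enh = coloc.enhancer_filter(f20, annotations)
    r20_enh = coloc.enhancer_filter(r20, annotations)
    for cls_set in (fr20_enh, f20_enh, r20_enh):
        manifest["counts"][cls_set.label] = len(cls_set)
    results["n_fr20_enhancer"] = len(fr20_enh)
    stage("annotate")

    # 5. chromatin context at strong FOXC1/RUNX1 sites
    anchors = pd.DataFrame(
        {"chrom": [p.chrom for p in strong["FOXC1"] + strong["RUNX1"]],
         "summit": [p.summit for p in strong["FOXC1"] + strong["RUNX1"]],
         "name": [p.name for p in strong["FOXC1"] + strong["RUNX1"]]})
    k27 = quant.quantify_sites(anchors, tracks["h3k27ac"], params.histone_halfwidth)
    k4 = quant.quantify_sites(anchors, tracks["h3k4me1"], params.histone_halfwidth)
    k27_cut = chrom_mod.calibrate_cuts(k27, params.chromatin_cut_method)
    k4_cut = chrom_mod.calibrate_cuts(k4, params.chromatin_cut_method)
    categories = chrom_mod.classify_chromatin(k27, k4, k27_cut, k4_cut)
    results["chromatin_calls"] = dict(zip(anchors.name, (c.value for c in categories)))
    results["chromatin_cuts"] = {"h3k27ac": k27_cut, "h3k4me1": k4_cut}
    stage("chromatin")

    # 6. union universe + running-mean normalization (RUNX1 and CEBPA tracks)
    universe = norm.build_union_universe(
        {"FOXC1": peak_sets["FOXC1"], "RUNX1": peak_sets["RUNX1"],
         "CEBPA": peak_sets["CEBPA"],
         "RUNX1_KD": read_narrowpeak(indir / "runx1_strong_kd.narrowPeak")})
    manifest["counts"]["union_universe"] = len(universe)
    results["union_universe_size"] = len(universe)
    norm_models = {}
    for factor, (c_track, k_track) in {"RUNX1": ("runx1_ntc", "runx1_kd"),
                                       "CEBPA": ("cebpa_ntc", "cebpa_kd")}.items():
        ctrl = quant.quantify_sites(universe, tracks[c_track], params.tf_halfwidth,
                                    anchor="summit")
        kd = quant.quantify_sites(universe, tracks[k_track], params.tf_halfwidth,
                                  anchor="summit")
        model = norm.running_mean_normalize(ctrl, kd, params.norm_window,
                                            chroms=universe.chrom.to_numpy(),
                                            starts=universe.summit.to_numpy())
        norm_models[factor] = (ctrl, kd, model)
        out = universe.copy()
        out["control"] = ctrl
        out["raw_kd"] = kd
        out = pd.concat([out, model.to_frame()], axis=1)
        out.to_csv(outdir / f"normalized_{factor.lower()}.tsv", sep="\t", index=False)
    ctrl_r, _, model_r = norm_models["RUNX1"]
    results["norm_median_null_ratio"] = norm.recover_scale_factor(ctrl_r, model_r.normalized)
    stage("normalize")

    # 7. enhancer groups at FR-20 enhancer sites (normalized fold changes)
    row_of = {(s, n): i for i, (s, n) in enumerate(zip(universe.source, universe.name))}
    fr_rows = []
    for site in fr20_enh.sites:
        ia = row_of[("FOXC1", site.peak_a.name)]
        ib = row_of[("RUNX1", site.peak_b.name)]
        _, _, m_r = norm_models["RUNX1"]
        _, _, m_c = norm_models["CEBPA"]
        ctrl_runx1 = norm_models["RUNX1"][0][ib]
        ctrl_cebpa = norm_models["CEBPA"][0][ia]
        fc_r = m_r.normalized[ib] / ctrl_runx1 if ctrl_runx1 > 0 else np.nan
        fc_c = m_c.normalized[ia] / ctrl_cebpa if ctrl_cebpa > 0 else np.nan
        fr_rows.append((site.peak_a.name, site.peak_b.name, site.distance, fc_r, fc_c))
    fr_df = pd.DataFrame(fr_rows, columns=["foxc1_peak", "runx1_peak", "distance",
                                           "fc_runx1", "fc_cebpa"])
    if len(fr_df):
        ok = fr_df[["fc_runx1", "fc_cebpa"]].notna().all(axis=1)
        grp = np.array([None] * len(fr_df), dtype=object)
        grp[ok.to_numpy()] = [g.value for g in np.atleast_1d(
            diff.classify_enhancer_groups(fr_df.fc_runx1[ok], fr_df.fc_cebpa[ok]))]
        fr_df["group"] = grp
    else:
        fr_df["group"] = []
    fr_df.to_csv(outdir / "fr20_enhancer_groups.tsv", sep="\t", index=False)
    results["enhancer_groups"] = dict(zip(fr_df.foxc1_peak, fr_df.group))
    stage("groups")

    # 8. redistribution groups from the condition strong sets
    strong_ctrl = read_narrowpeak(indir / "runx1_strong_ntc.narrowPeak")
    strong_kd = read_narrowpeak(indir / "runx1_strong_kd.narrowPeak")
    redist = diff.classify_redistribution(strong_ctrl, strong_kd, params.match_threshold)
    redist_calls = {}
    for p in redist.group_a:
        redist_calls[p.name] = "A"
    for pc, pk in redist.group_b:
        redist_calls[pc.name] = "B"
        redist_calls[pk.name] = "B"
    for p in redist.group_c:
        redist_calls[p.name] = "C"
    results["redistribution_calls"] = redist_calls
    results["redistribution_shared_of_kd"] = len(redist.group_b) / len(strong_kd)
    stage("redistribution")

    # 9. expression filter, gene linking, pre-ranked GSEA on group-1-proximal genes
    expressed, up, down = genes_mod.expression_filter(expression, params.min_fpkm,
                                                      params.min_expr_fold)
    results["n_expressed"], results["n_up"], results["n_down"] = map(
        len, (expressed, up, down))
    results["up_genes"], results["down_genes"] = sorted(up), sorted(down)
    domains = genes_mod.build_regulatory_domains(
        gene_model, params.great_basal_up, params.great_basal_down,
        params.great_max_ext, dict(layout.lengths))
    by_name = {p.name: p for p in peak_sets["FOXC1"]}
    g1_sites = [by_name[n] for n, g in results["enhancer_groups"].items() if g == "group1"]
    g1_genes = genes_mod.sites_to_genes(g1_sites, domains)
    results["n_group1_genes"] = len(g1_genes)
    ranking = genes_mod.log2_fold_changes(expression)
    gsea_rows = []
    in_rank = g1_genes & set(ranking.index)
    if 0 < len(in_rank) < len(ranking):
        es, nes, p, leading = genes_mod.gsea_preranked(
            ranking, in_rank, params.gsea_weight, params.gsea_n_perm, params.seed)
        gsea_rows.append(dict(gene_set="group1_proximal", size=len(in_rank), es=es,
                              nes=nes, p=p, leading_edge=",".join(map(str, leading))))
        results["gsea_group1_es"] = es
        results["gsea_group1_p"] = p
    pd.DataFrame(gsea_rows).to_csv(outdir / "gsea_report.tsv", sep="\t", index=False)
    stage("genes")

    # serialize BED-ish outputs and the manifest
    for label, cls_set in [("fr20_enhancer", fr20_enh), ("f20_enhancer", f20_enh),
                           ("r20_enhancer", r20_enh)]:
        with open(outdir / f"{label}.bed", "w") as fh:
            for s in cls_set.sites:
                if isinstance(s, coloc.CoboundSite):
                    p = s.peak_a
                    fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{s.distance}\n")
                else:
                    fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.name}\t.\n")
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, default=str)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return results
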