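import numpy as np
import pandas as pd
import pytest

from cobindscan.gene_linking import (build_regulatory_domains, enrichment_score,
                                     expression_filter, gsea_preranked,
                                     log2_fold_changes, sites_to_genes)
from cobindscan.genomic_io import GeneModel, GenomeLayout
from cobindscan.synthetic import generate_expression_table, generate_gene_model


def expr_table(rows):
    return pd.DataFrame(rows, columns=["gene", "fpkm_control", "fpkm_kd"])


class TestExpressionFilter:
    def test_below_cut_in_both_is_not_expressed(self):
        exp, up, down = expression_filter(expr_table([("g", 1.0, 1.0)]))
        assert exp == [] and up == [] and down == []

    def test_fourfold_up(self):
        exp, up, down = expression_filter(expr_table([("g", 10.0, 40.0)]))
        assert up == ["g"] and down == []

    def test_zero_denominator_counts_as_infinite_fold(self):
        _, up, down = expression_filter(expr_table([("g", 0.0, 5.0), ("h", 5.0, 0.0)]))
        assert up == ["g"] and down == ["h"]

    def test_recovers_planted_counts_exactly(self, rng):
        table, truth = generate_expression_table(rng, 1000, 50, 100)
        _, up, down = expression_filter(table)
        assert sorted(up) == truth.up_genes
        assert sorted(down) == truth.down_genes

    def test_up_down_disjoint_subsets_of_expressed(self, rng):
        table, _ = generate_expression_table(rng, 500, 40, 40)
        exp, up, down = expression_filter(table)
        assert not (set(up) & set(down))
        assert set(up) | set(down) <= set(exp)

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            expression_filter(expr_table([("g", -1.0, 1.0)]))


def model_from_rows(rows):
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand",
                                        "tss", "tes"])
    feats = pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "feature"])
    return GeneModel(genes, feats)


class TestRegulatoryDomains:
    def test_lone_gene_extends_one_megabase(self):
        model = model_from_rows([("g", "chr1", 5_000_000, 5_020_000, "+",
                                  5_000_000, 5_019_999)])
        (d,) = build_regulatory_domains(model)
        assert (d.basal_start, d.basal_end) == (4_995_000, 5_001_000)
        assert (d.ext_start, d.ext_end) == (4_000_000, 6_000_000)

    def test_neighbors_stop_at_each_others_basal(self):
        model = model_from_rows([
            ("a", "chr1", 1_000_000, 1_005_000, "+", 1_000_000, 1_004_999),
            ("b", "chr1", 1_010_000, 1_015_000, "+", 1_010_000, 1_014_999)])
        da, db = build_regulatory_domains(model)
        assert da.ext_end == db.basal_start == 1_005_000
        assert db.ext_start == da.basal_end == 1_001_000

    def test_chromosome_edge_clips_upstream_basal(self):
        model = model_from_rows([("g", "chr1", 500, 10_000, "+", 500, 9_999)])
        (d,) = build_regulatory_domains(model, chrom_lengths={"chr1": 50_000})
        assert d.basal_start == 0 and d.ext_start == 0
        assert d.ext_end == 50_000

    def test_basal_always_inside_extended(self, rng):
        layout = GenomeLayout({"chr1": 5_000_000})
        model = generate_gene_model(rng, layout, 30, spacing=150_000)
        for d in build_regulatory_domains(model, chrom_lengths=dict(layout.lengths)):
            assert d.ext_start <= d.basal_start < d.basal_end <= d.ext_end

    def test_extensions_never_cross_neighbor_basal(self, rng):
        layout = GenomeLayout({"chr1": 5_000_000})
        model = generate_gene_model(rng, layout, 30, spacing=150_000)
        domains = build_regulatory_domains(model, chrom_lengths=dict(layout.lengths))
        for d in domains:
            for other in domains:
                if other.gene_id == d.gene_id:
                    continue
                # extension may not reach strictly inside a neighbor's basal
                # region beyond its boundary facing this gene
                if other.basal_end <= d.basal_start:
                    assert d.ext_start >= other.basal_end or d.ext_start <= other.basal_start
                if other.basal_start >= d.basal_end:
                    assert d.ext_end <= other.basal_start or d.ext_end >= other.basal_end


class TestSitesToGenes:
    def test_single_domain_hit(self):
        model = model_from_rows([("g", "chr1", 1_000_000, 1_005_000, "+",
                                  1_000_000, 1_004_999)])
        domains = build_regulatory_domains(model)
        assert sites_to_genes([("chr1", 999_000)], domains) == {"g"}
        assert sites_to_genes([("chr1", 3_000_000)], domains) == set()

    def test_site_in_overlapping_basals_hits_both(self):
        model = model_from_rows([
            ("a", "chr1", 1_000_000, 1_005_000, "+", 1_000_000, 1_004_999),
            ("b", "chr1", 1_000_500, 1_006_000, "+", 1_000_500, 1_005_999)])
        domains = build_regulatory_domains(model)
        assert sites_to_genes([("chr1", 1_000_200)], domains) == {"a", "b"}

    def test_matches_brute_force_containment(self, rng):
        layout = GenomeLayout({"chr1": 8_000_000})
        model = generate_gene_model(rng, layout, 30, spacing=250_000)
        domains = build_regulatory_domains(model, chrom_lengths=dict(layout.lengths))
        sites = [("chr1", int(p)) for p in rng.integers(0, 8_000_000, 200)]
        expected = {d.gene_id for d in domains
                    if any(d.ext_start <= pos < d.ext_end for _, pos in sites)}
        assert sites_to_genes(sites, domains) == expected


class TestGsea:
    def _ranking(self, rng, n=500):
        vals = np.sort(rng.normal(0, 1, n))[::-1]
        return pd.Series(vals, index=[f"g{i}" for i in range(n)])

    def test_top_block_is_enriched_with_full_leading_edge(self, rng):
        ranked = self._ranking(rng)
        top = set(ranked.index[:25])
        es, nes, p, leading = gsea_preranked(ranked, top, n_perm=200, seed=rng)
        assert es > 0.5 and nes > 1 and p < 0.05
        assert set(leading) == top

    def test_bottom_block_scores_negative(self, rng):
        ranked = self._ranking(rng)
        es, _, _, _ = gsea_preranked(ranked, set(ranked.index[-25:]), n_perm=50, seed=rng)
        assert es < -0.5

    def test_matches_independent_running_sum_oracle(self, rng):
        ranked = self._ranking(rng, 300)
        metric = ranked.to_numpy()
        for _ in range(20):
            members = set(rng.choice(ranked.index, size=20, replace=False))
            hits = np.array([g in members for g in ranked.index])
            # plain-python oracle for the weighted running sum
            nr = sum(abs(m) for m, h in zip(metric, hits) if h)
            path, best = 0.0, 0.0
            for m, h in zip(metric, hits):
                path += abs(m) / nr if h else -1.0 / (len(metric) - 20)
                if abs(path) > abs(best):
                    best = path
            es, _ = enrichment_score(metric, hits)
            assert es == pytest.approx(best, abs=1e-12)

    def test_weight_zero_invariant_to_monotone_rescale(self, rng):
        ranked = self._ranking(rng, 200)
        members = set(rng.choice(ranked.index, size=15, replace=False))
        hits = np.array([g in members for g in ranked.index])
        es1, _ = enrichment_score(ranked.to_numpy(), hits, weight=0)
        es2, _ = enrichment_score(np.exp(ranked.to_numpy()), hits, weight=0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_reversal_flips_sign_at_weight_zero(self, rng):
        ranked = self._ranking(rng, 200)
        members = set(rng.choice(ranked.index, size=15, replace=False))
        hits = np.array([g in members for g in ranked.index])
        es_fwd, _ = enrichment_score(ranked.to_numpy(), hits, weight=0)
        es_rev, _ = enrichment_score(ranked.to_numpy()[::-1], hits[::-1], weight=0)
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_degenerate_sets_rejected(self, rng):
        ranked = self._ranking(rng, 50)
        with pytest.raises(ValueError):
            gsea_preranked(ranked, {"absent"})
        with pytest.raises(ValueError):
            gsea_preranked(ranked, set(ranked.index))


def test_duplicate_symbols_collapse_to_strongest(rng):
    table = expr_table([("g", 10.0, 40.0), ("g", 10.0, 11.0), ("h", 10.0, 5.0)])
    ranks = log2_fold_changes(table)
    assert len(ranks) == 2
    assert ranks["g"] == pytest.approx(np.log2(40.1 / 10.1))
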