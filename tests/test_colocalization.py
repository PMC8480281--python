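import numpy as np
import pytest

from cobindscan.chromatin import GenomicAnnotation
from cobindscan.colocalization import (CoboundSite, build_site_classes,
                                       cobound_percentages, cross_sample_overlap,
                                       enhancer_filter, match_summits)
from cobindscan.genomic_io import GenomeLayout, Peak
from cobindscan.synthetic import generate_cobound_pair


def peak_at(summit, name="p", pileup=100.0, chrom="chr1"):
    return Peak(chrom, summit - 200, summit + 200, summit, pileup, 10.0, name)


def brute_force_greedy(peaks_a, peaks_b, max_dist=200):
    """Quadratic oracle: all candidate pairs, ascending distance, one-to-one."""
    cands = []
    for i, a in enumerate(peaks_a):
        for j, b in enumerate(peaks_b):
            if a.chrom == b.chrom and abs(a.summit - b.summit) <= max_dist:
                cands.append((abs(a.summit - b.summit), a.summit, b.summit, i, j))
    cands.sort()
    used_a, used_b, out = set(), set(), []
    for d, _, _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, d))
    return out


class TestMatchSummits:
    def test_within_threshold_pairs(self):
        pairs = match_summits([peak_at(1000)], [peak_at(1150)])
        assert len(pairs) == 1 and pairs[0].distance == 150

    def test_strictly_beyond_threshold_fails(self):
        assert match_summits([peak_at(1000)], [peak_at(1201)]) == []
        assert len(match_summits([peak_at(1000)], [peak_at(1200)])) == 1

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(5):
            a = [peak_at(int(s), f"a{k}") for k, s in
                 enumerate(rng.choice(np.arange(300, 999_700), 300, replace=False))]
            b = [peak_at(int(s), f"b{k}") for k, s in
                 enumerate(rng.choice(np.arange(300, 999_700), 300, replace=False))]
            got = {(s.peak_a.name, s.peak_b.name, s.distance) for s in match_summits(a, b)}
            want = {(a[i].name, b[j].name, d) for i, j, d in brute_force_greedy(a, b)}
            assert got == want

    def test_pair_count_symmetric(self, rng):
        a = [peak_at(int(s), f"a{k}") for k, s in
             enumerate(rng.choice(np.arange(300, 499_700), 400, replace=False))]
        b = [peak_at(int(s), f"b{k}") for k, s in
             enumerate(rng.choice(np.arange(300, 499_700), 400, replace=False))]
        assert len(match_summits(a, b)) == len(match_summits(b, a))

    def test_all_distances_within_threshold(self, rng):
        a = [peak_at(int(s)) for s in rng.choice(np.arange(300, 99_700), 200, replace=False)]
        b = [peak_at(int(s)) for s in rng.choice(np.arange(300, 99_700), 200, replace=False)]
        for s in match_summits(a, b, max_dist=200):
            assert s.distance <= 200
            assert s.peak_a.chrom == s.peak_b.chrom

    def test_recovers_planted_cobinding_exactly(self, rng):
        layout = GenomeLayout({"chr1": 40_000_000})
        a, b, truth = generate_cobound_pair(rng, layout, n_a=1000, n_b=1200,
                                            fraction=0.28, max_offset=50)
        pairs = match_summits(a, b, max_dist=200)
        assert len(pairs) == round(0.28 * 1000) == 280
        assert {(s.peak_a.name, s.peak_b.name) for s in pairs} == set(truth.cobound_pairs)

    def test_zero_and_full_fractions(self, rng):
        layout = GenomeLayout({"chr1": 20_000_000})
        a, b, _ = generate_cobound_pair(rng, layout, 200, 250, fraction=0.0, max_offset=50)
        assert match_summits(a, b) == []
        a, b, _ = generate_cobound_pair(rng, layout, 200, 200, fraction=1.0, max_offset=50)
        assert len(match_summits(a, b)) == 200


class TestCoboundPercentages:
    def test_printed_example(self):
        assert cobound_percentages(5246, 18745, 34180) == (28.0, 15.3)

    def test_degenerate_cases(self):
        assert cobound_percentages(0, 10, 20) == (0.0, 0.0)
        assert cobound_percentages(7, 7, 7) == (100.0, 100.0)

    def test_rejects_impossible_counts(self):
        with pytest.raises(ValueError):
            cobound_percentages(11, 10, 20)


class TestSiteClasses:
    def test_no_pairs_all_single(self):
        strong_a = [peak_at(1000, "a0"), peak_at(5000, "a1")]
        strong_b = [peak_at(9000, "b0")]
        ab, a_only, b_only = build_site_classes(strong_a, strong_b, [])
        assert len(ab) == 0 and len(a_only) == 2 and len(b_only) == 1

    def test_planted_strong_pairs_counted(self, rng):
        strong_a, strong_b, pairs = [], [], []
        pos = 1000
        for i in range(621):
            a, b = peak_at(pos, f"a{i}"), peak_at(pos + 40, f"b{i}")
            strong_a.append(a)
            strong_b.append(b)
            pairs.append(CoboundSite(a, b, 40))
            pos += 5000
        for i in range(200):  # extra unmatched strong peaks
            strong_a.append(peak_at(pos, f"xa{i}"))
            pos += 5000
        ab, a_only, b_only = build_site_classes(strong_a, strong_b, pairs)
        assert len(ab) == 621
        assert len(a_only) == 200 and len(b_only) == 0
        assert len(ab) + len(a_only) == len(strong_a)

    def test_pair_with_weak_partner_stays_single(self):
        a = peak_at(1000, "a0", pileup=300)
        weak_b = peak_at(1040, "b0", pileup=10)
        ab, a_only, _ = build_site_classes([a], [], [CoboundSite(a, weak_b, 40)])
        assert len(ab) == 0 and a_only.sites == [a]


class TestEnhancerFilter:
    def test_all_intergenic_unchanged(self):
        peaks = [peak_at(1000 + 5000 * i, f"p{i}") for i in range(5)]
        cls = build_site_classes(peaks, [], [])[1]
        ann = {p.name: GenomicAnnotation.intergenic for p in peaks}
        assert len(enhancer_filter(cls, ann)) == 5

    def test_planted_promoter_sites_removed(self):
        sites, ann = [], {}
        pos = 1000
        for i in range(621):
            a, b = peak_at(pos, f"a{i}"), peak_at(pos + 40, f"b{i}")
            sites.append(CoboundSite(a, b, 40))
            ann[a.name] = (GenomicAnnotation.promoter if i < 25
                           else GenomicAnnotation.five_prime_utr if i < 40
                           else GenomicAnnotation.intron)
            pos += 5000
        from cobindscan.colocalization import SiteClassSet

        filtered = enhancer_filter(SiteClassSet("FR-20", sites), ann)
        assert len(filtered) == 581
        assert filtered.enhancer_filtered

    def test_missing_annotation_is_error(self):
        cls = build_site_classes([peak_at(1000, "a0")], [], [])[1]
        with pytest.raises(KeyError):
            enhancer_filter(cls, {})


class TestCrossSampleOverlap:
    @pytest.mark.parametrize("n_hit,n_total,expected", [
        (324, 581, 56), (459, 1096, 42), (122, 224, 54)])
    def test_printed_percentages(self, n_hit, n_total, expected):
        x = [("chr1", 10_000 * i) for i in range(n_total)]
        y = [("chr1", 10_000 * i + 30) for i in range(n_hit)]
        assert cross_sample_overlap(x, y) == (n_hit, expected)

    def test_self_overlap_is_total(self):
        x = [("chr1", 1000 * i) for i in range(50)]
        assert cross_sample_overlap(x, x) == (50, 100)
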