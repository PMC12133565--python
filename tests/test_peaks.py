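"""Peak algebra against per-base painting oracles, plus annotation rules."""

import numpy as np
import pytest

from tadlink.genomic_model import GeneModel, Interval
from tadlink.peaks import (
    annotate_peaks,
    build_group_consensus,
    merge_intervals,
    peak_size_summary,
    venn_classify,
)

GENOME_BP = 10_000


def paint(intervals, n=GENOME_BP):
    """Per-base boolean coverage oracle (single chromosome)."""
    mask = np.zeros(n, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


def bridges(intervals, n=GENOME_BP):
    """bridge[b] is True when a single input interval spans the junction
    between bases b-1 and b — merging happens only across bridged junctions,
    so two merely adjacent intervals stay separate regions."""
    cross = np.zeros(n + 1, dtype=bool)
    for iv in intervals:
        cross[iv.start + 1 : iv.end] = True
    return cross


def oracle_regions(intervals, n=GENOME_BP):
    """Brute-force region decomposition: per-base coverage runs, split at
    unbridged junctions (half-open adjacency does not merge)."""
    mask, cross = paint(intervals, n), bridges(intervals, n)
    out = []
    start = None
    for b in range(n + 1):
        covered = b < n and mask[b]
        if covered and start is None:
            start = b
        elif start is not None and (not covered or not cross[b]):
            out.append((start, b))
            start = b if covered else None
    return out


def random_intervals(rng, n, max_pos=GENOME_BP, chrom="chr1"):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos - 1))
        end = start + int(rng.integers(1, 300))
        out.append(Interval(chrom, start, min(end, max_pos)))
    return out


class TestMergeIntervals:
    def test_overlap_merges(self):
        merged = merge_intervals([Interval("chr1", 0, 10), Interval("chr1", 5, 20)])
        assert [(m.start, m.end) for m in merged] == [(0, 20)]

    def test_adjacency_does_not_merge(self):
        merged = merge_intervals([Interval("chr1", 0, 10), Interval("chr1", 10, 20)])
        assert [(m.start, m.end) for m in merged] == [(0, 10), (10, 20)]

    def test_empty_input(self):
        assert merge_intervals([]) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_painting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, 40)
        merged = merge_intervals(ivs)
        assert np.array_equal(paint(merged), paint(ivs))
        assert [(m.start, m.end) for m in merged] == oracle_regions(ivs)


class TestGroupConsensus:
    def test_two_identical_samples_support_two(self):
        peak = [Interval("chr1", 100, 300)]
        cons = build_group_consensus({"s1": peak, "s2": peak}, min_samples=2)
        assert len(cons) == 1 and cons.support == [2]

    def test_low_support_peak_excluded(self):
        sets = {
            "s1": [Interval("chr1", 0, 100)],
            "s2": [Interval("chr1", 0, 100)],
            "s3": [Interval("chr1", 500, 600)],
            "s4": [],
        }
        cons = build_group_consensus(sets, min_samples=2)
        assert [(p.start, p.end) for p in cons.peaks] == [(0, 100)]

    def test_min_samples_above_sample_count_is_error(self):
        with pytest.raises(ValueError):
            build_group_consensus({"s1": []}, min_samples=2)

    def test_invariant_to_sample_input_order(self):
        rng = np.random.default_rng(3)
        sets = {f"s{i}": random_intervals(rng, 20) for i in range(4)}
        a = build_group_consensus(sets, min_samples=2)
        b = build_group_consensus(dict(reversed(list(sets.items()))), min_samples=2)
        assert [(p.start, p.end) for p in a.peaks] == [(p.start, p.end) for p in b.peaks]
        assert a.support == b.support

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_support_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = {f"s{i}": random_intervals(rng, 15) for i in range(4)}
        min_samples = 2
        cons = build_group_consensus(sets, min_samples=min_samples)
        # oracle: merged regions of the union in which >= min_samples
        # distinct samples cover at least one base
        union_runs = oracle_regions([iv for s in sets.values() for iv in s])
        masks = {s: paint(ivs) for s, ivs in sets.items()}
        expected = [
            (s, e)
            for s, e in union_runs
            if sum(m[s:e].any() for m in masks.values()) >= min_samples
        ]
        assert [(p.start, p.end) for p in cons.peaks] == expected


class TestVennClassify:
    def test_overlapping_pair_is_one_shared_region(self):
        v = venn_classify([Interval("chr1", 0, 100)], [Interval("chr1", 50, 150)])
        assert v.counts == (1, 0, 0)
        assert (v.shared[0].start, v.shared[0].end) == (0, 150)

    def test_mixed_example(self):
        v = venn_classify(
            [Interval("chr1", 0, 100), Interval("chr1", 200, 300)],
            [Interval("chr1", 50, 150)],
        )
        assert v.counts == (1, 1, 0)

    def test_identical_sets_have_no_unique_regions(self):
        a = [Interval("chr1", 0, 100), Interval("chr1", 500, 700)]
        v = venn_classify(a, a)
        assert v.counts == (2, 0, 0)

    def test_symmetric_under_argument_swap(self):
        rng = np.random.default_rng(7)
        a, b = random_intervals(rng, 25), random_intervals(rng, 25)
        v1, v2 = venn_classify(a, b), venn_classify(b, a)
        key = lambda ivs: [(i.start, i.end) for i in ivs]
        assert key(v1.shared) == key(v2.shared)
        assert key(v1.unique_a) == key(v2.unique_b)
        assert key(v1.unique_b) == key(v2.unique_a)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_label_oracle_and_conserves_coverage(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_intervals(rng, 20), random_intervals(rng, 20)
        v = venn_classify(a, b)
        mask_a, mask_b = paint(a), paint(b)
        expected = {"shared": [], "unique_a": [], "unique_b": []}
        for s, e in oracle_regions(list(a) + list(b)):
            in_a, in_b = mask_a[s:e].any(), mask_b[s:e].any()
            label = "shared" if (in_a and in_b) else ("unique_a" if in_a else "unique_b")
            expected[label].append((s, e))
        assert [(i.start, i.end) for i in v.shared] == expected["shared"]
        assert [(i.start, i.end) for i in v.unique_a] == expected["unique_a"]
        assert [(i.start, i.end) for i in v.unique_b] == expected["unique_b"]
        # conservation: the three lists tile the union exactly
        tiles = sorted(
            [(i.start, i.end) for i in v.shared + v.unique_a + v.unique_b]
        )
        assert tiles == oracle_regions(list(a) + list(b))


class TestPeakSizeSummary:
    def test_two_peak_example(self):
        s = peak_size_summary([Interval("chr1", 0, 100), Interval("chr1", 500, 800)])
        assert s["mean"] == 200 and s["median"] == 200 and s["n"] == 2

    def test_single_peak_statistics_collapse(self):
        s = peak_size_summary([Interval("chr1", 0, 123)])
        assert {s["mean"], s["median"], s["q1"], s["q3"]} == {123.0}

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            peak_size_summary([])

    def test_agreement_with_direct_recomputation(self):
        rng = np.random.default_rng(11)
        ivs = random_intervals(rng, 50)
        s = peak_size_summary(ivs)
        lengths = np.array([iv.length for iv in ivs])
        assert s["mean"] == pytest.approx(lengths.mean())
        assert s["median"] == pytest.approx(np.median(lengths))


def _gene(gid, strand, start, end, exons=(), chrom="chr1"):
    return GeneModel(gid, chrom, strand, start, end,
                     tuple(Interval(chrom, s, e) for s, e in exons))


class TestAnnotatePeaks:
    def test_promoter_window_upstream_of_plus_tss(self):
        g = _gene("g1", "+", 1000, 5000)
        (a,) = annotate_peaks([Interval("chr1", 450, 550)], [g], (1000, 100))
        assert a.annotation_class == "promoter" and a.tss_distance == -500

    def test_gene_body_without_exon_is_intron(self):
        g = _gene("g1", "+", 1000, 9000, exons=[(1000, 1200)])
        (a,) = annotate_peaks([Interval("chr1", 4950, 5050)], [g], (1000, 100))
        assert a.annotation_class == "intron"

    def test_precedence_promoter_over_exon(self):
        # midpoint inside both an exon of one gene and the promoter of another
        g1 = _gene("g1", "+", 0, 2000, exons=[(0, 2000)])
        g2 = _gene("g2", "+", 1500, 4000)
        (a,) = annotate_peaks([Interval("chr1", 950, 1050)], [g1, g2], (1000, 100))
        assert a.annotation_class == "promoter"

    def test_equidistant_tie_breaks_to_smaller_gene_id(self):
        ga = _gene("ga", "+", 2000, 3000)
        gb = _gene("gb", "-", 0, 1000)  # tss 999
        # midpoint 1500: |d| = 500 to ga's tss 2000 and ~501 to gb -> adjust to exact tie
        gb2 = _gene("gb", "-", 0, 1001)  # tss 1000, |d|=500
        (a,) = annotate_peaks([Interval("chr1", 1450, 1550)], [gb2, ga], (10, 10))
        assert a.nearest_gene_id == "ga"

    def test_classes_stable_under_coordinate_translation(self):
        rng = np.random.default_rng(5)
        genes = [
            _gene(f"g{i}", "+" if i % 2 else "-", 1000 * i + 100, 1000 * i + 900)
            for i in range(1, 6)
        ]
        peaks = random_intervals(rng, 30, max_pos=7000)
        base = [a.annotation_class for a in annotate_peaks(peaks, genes)]
        shift = 5000
        genes_t = [
            _gene(g.gene_id, g.strand, g.start + shift, g.end + shift,
                  [(e.start + shift, e.end + shift) for e in g.exons])
            for g in genes
        ]
        peaks_t = [Interval(p.chrom, p.start + shift, p.end + shift) for p in peaks]
        assert [a.annotation_class for a in annotate_peaks(peaks_t, genes_t)] == base

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_per_gene_scan(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(8):
            start = int(rng.integers(0, 8000))
            end = start + int(rng.integers(500, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            ex = [(start, min(start + 200, end))]
            genes.append(_gene(f"g{i:02d}", strand, start, end, ex))
        peaks = random_intervals(rng, 40)
        up, down, tts_w = 1000, 100, 100
        anns = annotate_peaks(peaks, genes, (up, down), tts_w)
        for peak, ann in zip(peaks, anns):
            mid = peak.midpoint
            promoter = tts = exon = intron = False
            best = None
            for g in genes:
                d = g.signed_tss_distance(mid)
                if best is None or abs(d) < abs(best[1]):
                    best = (g.gene_id, d)
                if -up <= d < down:
                    promoter = True
                if abs(mid - g.tes) <= tts_w:
                    tts = True
                if g.start <= mid < g.end:
                    if any(e.start <= mid < e.end for e in g.exons):
                        exon = True
                    else:
                        intron = True
            expect = (
                "promoter" if promoter else "tts" if tts else
                "exon" if exon else "intron" if intron else "intergenic"
            )
            assert ann.annotation_class == expect
            assert ann.nearest_gene_id == best[0] or abs(ann.tss_distance) == abs(best[1])
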