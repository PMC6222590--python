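"""Empirical p-values, percentile selection, merging, intersection, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import (
    GenomicRegion,
    annotate_regions,
    empirical_pvalues,
    intersect_regions,
    merge_windows,
    significant_windows,
)


def track_from_scores(scores, chrom="chr1", width=25_000):
    n = len(scores)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "score": scores,
        }
    )


class TestEmpiricalPvalues:
    def test_simple_ranking(self):
        out = empirical_pvalues(track_from_scores([5.0, 3.0, 1.0]))
        assert out["empirical_p"].tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_all_tied(self):
        out = empirical_pvalues(track_from_scores([2.0] * 7))
        assert (out["empirical_p"] == 1.0).all()

    def test_sort_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(1000).astype(float)
        out = empirical_pvalues(track_from_scores(scores))
        order = np.argsort(-scores)
        expect = np.empty(1000)
        expect[order] = (np.arange(1000) + 1) / 1000
        assert np.allclose(out["empirical_p"], expect)


class TestSignificantWindows:
    @pytest.mark.parametrize("N,expected", [(90_588, 1_811), (90_322, 1_806), (100, 2)])
    def test_distinct_score_counts(self, N, expected):
        """98th-percentile strict selection reproduces the printed window counts."""
        rng = np.random.default_rng(N)
        scores = rng.permutation(N).astype(float)
        sel = significant_windows(track_from_scores(scores))
        assert len(sel) == expected

    def test_arithmetic_exhaustive_small_n(self):
        """|selected| = N - ceil(0.98 N) for distinct scores, all N <= 1000."""
        for N in range(1, 1001):
            scores = np.arange(N, dtype=float)
            sel_n = N - int(np.ceil(0.98 * N))
            cutoff = np.sort(scores)[int(np.ceil(0.98 * N)) - 1]
            assert (scores > cutoff).sum() == sel_n

    @given(N=st.integers(1, 100_000))
    @settings(max_examples=200, deadline=None)
    def test_selected_count_formula(self, N):
        k = int(np.ceil(0.98 * N))
        assert 0 <= N - k < max(1, int(0.02 * N) + 1)

    def test_ties_select_fewer(self):
        scores = np.concatenate([np.zeros(98), [1.0, 1.0]])
        sel = significant_windows(track_from_scores(scores))
        assert len(sel) == 2  # both above the 98th order statistic (0)
        scores2 = np.concatenate([np.ones(99), [2.0]])
        assert len(significant_windows(track_from_scores(scores2))) == 1


def brute_force_merge(intervals, gap):
    """Union-style merge by pairwise scanning (oracle)."""
    out = []
    for iv in sorted(intervals):
        if out and iv[0] - out[-1][1] < gap:
            out[-1] = (out[-1][0], max(out[-1][1], iv[1]))
        else:
            out.append(iv)
    return out


class TestMergeWindows:
    def test_single_window(self):
        sel = track_from_scores([1.0])
        regions = merge_windows(sel)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 25_000)

    def test_gap_at_least_200kb_not_merged(self):
        sel = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 250_000],
             "end": [25_000, 275_000], "score": [1.0, 1.0]}
        )
        assert len(merge_windows(sel, gap_bp=200_000)) == 2
        sel2 = sel.assign(start=[0, 220_000], end=[25_000, 245_000])
        assert len(merge_windows(sel2, gap_bp=200_000)) == 1  # gap 195 kb

    def test_random_vs_brute_force(self):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.choice(np.arange(0, 25_000_000, 25_000), 500, replace=False))
        sel = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 25_000,
             "score": rng.random(500)}
        )
        got = [(r.start, r.end) for r in merge_windows(sel, gap_bp=200_000)]
        exp = brute_force_merge([(s, s + 25_000) for s in starts], 200_000)
        assert got == exp

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        starts = np.sort(rng.choice(np.arange(0, 2_000_000, 25_000), 40, replace=False))
        sel = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 25_000, "score": 1.0}
        )
        once = merge_windows(sel, gap_bp=200_000)
        frame = pd.DataFrame(
            {"chrom": [r.chrom for r in once], "start": [r.start for r in once],
             "end": [r.end for r in once], "score": 1.0}
        )
        twice = merge_windows(frame, gap_bp=200_000)
        assert [(r.start, r.end) for r in once] == [(r.start, r.end) for r in twice]


class TestIntersect:
    def R(self, chrom, s, e, src="CSR"):
        return GenomicRegion(chrom, s, e, src)

    def test_identity(self):
        got = intersect_regions([self.R("1", 10, 20)], [self.R("1", 10, 20)])
        assert [(r.start, r.end) for r in got] == [(10, 20)]

    def test_disjoint_empty(self):
        assert intersect_regions([self.R("1", 0, 10)], [self.R("1", 20, 30)]) == []
        assert intersect_regions([self.R("1", 0, 10)], [self.R("2", 0, 10)]) == []

    def test_random_vs_double_loop(self):
        rng = np.random.default_rng(3)

        def random_track(seed):
            r = np.random.default_rng(seed)
            starts = np.sort(r.choice(np.arange(0, 1_000_000, 1000), 100, replace=False))
            # widths chosen so the track stays internally non-overlapping
            return [
                GenomicRegion("chr1", int(s), int(s + r.integers(100, 900)), "CSR")
                for s in starts
            ]

        for seed in range(20):
            a = random_track(seed)
            b = random_track(seed + 1000)
            got = sorted(
                (r.start, r.end) for r in intersect_regions(a, b)
            )
            exp = []
            for ra in a:
                for rb in b:
                    s, e = max(ra.start, rb.start), min(ra.end, rb.end)
                    if s < e:
                        exp.append((s, e))
            assert got == sorted(exp)

    def test_union_of_two_fst_tracks(self):
        clr = [self.R("1", 0, 100)]
        fa = [self.R("1", 10, 20)]
        fb = [self.R("1", 50, 60)]
        got = intersect_regions(clr, fa, fb)
        assert sorted((r.start, r.end) for r in got) == [(10, 20), (50, 60)]
        assert intersect_regions(clr, fa, fb, require_both=True) != []
        assert intersect_regions(clr, fa, [self.R("1", 500, 600)], require_both=True) == []

    def test_commutes_with_chromosome_partition(self):
        rng = np.random.default_rng(4)
        a, b = [], []
        for chrom in ("chr1", "chr2"):
            for lst, off in ((a, 0), (b, 37)):
                starts = np.sort(rng.choice(np.arange(0, 100_000, 500), 30, replace=False))
                lst.extend(
                    GenomicRegion(chrom, int(s + off), int(s + off + 400), "CSR")
                    for s in starts
                )
        joint = sorted((r.chrom, r.start, r.end) for r in intersect_regions(a, b))
        split = []
        for chrom in ("chr1", "chr2"):
            ac = [r for r in a if r.chrom == chrom]
            bc = [r for r in b if r.chrom == chrom]
            split.extend((r.chrom, r.start, r.end) for r in intersect_regions(ac, bc))
        assert joint == sorted(split)


class TestAnnotate:
    GENES = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [50_000, 400_000, 1_000_000],
            "end": [60_000, 410_000, 1_010_000],
            "name": ["inside", "far", "veryfar"],
            "score": 0,
            "strand": "+",
        }
    )

    def test_gene_inside_region_listed(self):
        r = GenomicRegion("chr1", 40_000, 80_000, "CASR")
        out = annotate_regions([r], self.GENES, flank_bp=100_000)
        assert "inside" in out[0].genes

    def test_gene_beyond_flank_not_listed(self):
        # gene at 400k starts 150 kb past the region edge; flank is 100 kb
        r = GenomicRegion("chr1", 200_000, 250_000, "CASR")
        out = annotate_regions([r], self.GENES, flank_bp=100_000)
        assert "far" not in out[0].genes

    def test_brute_force_overlap_oracle(self):
        rng = np.random.default_rng(5)
        regions = [
            GenomicRegion("chr1", int(s), int(s + 20_000), "CASR")
            for s in rng.choice(np.arange(0, 5_000_000, 30_000), 40, replace=False)
        ]
        genes = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": (gs := rng.choice(np.arange(0, 5_000_000, 7_000), 200, replace=False)),
                "end": gs + 5_000,
                "name": [f"g{i}" for i in range(200)],
                "score": 0,
                "strand": "+",
            }
        )
        out = annotate_regions(regions, genes, flank_bp=100_000)
        for r in out:
            exp = sorted(
                row["name"]
                for _, row in genes.iterrows()
                if row["start"] < r.end + 100_000 and row["end"] > r.start - 100_000
            )
            assert sorted(r.genes) == exp

    def test_unknown_chromosome_skipped_with_warning(self, caplog):
        r = GenomicRegion("chrX", 0, 1000, "CASR")
        with caplog.at_level("WARNING"):
            out = annotate_regions([r], self.GENES)
        assert out[0].genes == []
        assert "chrX" in caplog.text

    def test_hits_assigned_to_nearest_region(self):
        regions = [
            GenomicRegion("chr1", 0, 10_000, "CASR"),
            GenomicRegion("chr1", 500_000, 510_000, "CASR"),
        ]
        assoc = pd.DataFrame({"chrom": ["chr1"], "pos": [495_001], "wald_p": [1e-9]})
        out = annotate_regions(regions, self.GENES, assoc=assoc, hit_dist_bp=100_000)
        assert out[0].nearby_hits == []
        assert out[1].nearby_hits == [("chr1:495001", 5_000)]
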