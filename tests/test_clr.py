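"""SFS machinery and the sweep-model CLR against enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sweepscan import (
    SFS,
    background_sfs,
    clr_at_gridpoint,
    clr_genome_scan,
    neutral_sfs,
    project_sfs,
    sweep_site_distribution,
)
from sweepscan.clr import default_alpha_grid


def hyp_pmf(k, N, K, m):
    """Hypergeometric pmf via exact integer combinatorics (oracle)."""
    if k < 0 or k > m or k > K or m - k > N - K:
        return 0.0
    return math.comb(K, k) * math.comb(N - K, m - k) / math.comb(N, m)


def project_oracle(probs, n, m):
    """Exhaustive projection by direct summation (oracle)."""
    q = [0.0] * (m + 1)
    for j in range(1, n):
        for k in range(m + 1):
            q[k] += probs[j - 1] * hyp_pmf(k, n, j, m)
    return np.array(q)


def sweep_oracle(probs, n, p_escape):
    """Brute-force enumeration of the lineage-escape mixture (oracle).

    Enumerates the number of escaped lineages e, the ancestral derived
    count j in the (e+1)-sample, and the sweep ancestor's allele, then
    conditions on modern polymorphism.
    """
    raw = np.zeros(n + 1)
    for e in range(n + 1):
        w_e = math.comb(n, e) * p_escape**e * (1 - p_escape) ** (n - e)
        if e == n:
            for b in range(1, n):
                raw[b] += w_e * probs[b - 1]
            continue
        m = e + 1
        qproj = project_oracle(probs, n, m)
        for j in range(m + 1):
            if qproj[j] == 0:
                continue
            p_anc_derived = j / m
            if j >= 1:
                raw[(j - 1) + (n - e)] += w_e * qproj[j] * p_anc_derived
            raw[j] += w_e * qproj[j] * (1 - p_anc_derived)
    poly = raw[1:n]
    return poly / poly.sum()


class TestBackgroundSfs:
    def test_counts_example(self):
        sfs = background_sfs(np.array([1] * 5 + [2] * 5), n=4)
        assert np.allclose(sfs.probs, [0.5, 0.5, 0.0])

    def test_normalization(self):
        rng = np.random.default_rng(0)
        sfs = background_sfs(rng.integers(1, 20, size=500), n=20)
        assert sfs.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_neutral_generator_shape(self):
        """Counts drawn from the 1/j law reproduce the neutral spectrum."""
        n = 20
        ref = neutral_sfs(n)
        rng = np.random.default_rng(1)
        counts = rng.choice(np.arange(1, n), p=ref.probs, size=20_000)
        est = background_sfs(counts, n=n)
        assert 0.5 * np.abs(est.probs - ref.probs).sum() < 0.05

    def test_no_polymorphic_sites(self):
        with pytest.raises(ValueError):
            background_sfs(np.array([0, 0, 20]), n=20)

    def test_missing_data_projection(self):
        """Sites with smaller observed n are folded in by projection."""
        counts = np.array([1, 2, 3, 1, 2])
        sizes = np.array([6, 6, 6, 4, 4])
        sfs = background_sfs(counts, n=6, sample_sizes=sizes)
        assert sfs.n == 4
        assert sfs.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestProjection:
    def test_identity_at_m_equals_n(self):
        sfs = neutral_sfs(8)
        q = project_sfs(sfs, 8)
        assert np.allclose(q[1:8], sfs.probs)

    def test_uniform_n4_to_m2(self):
        sfs = SFS(4, np.array([1 / 3, 1 / 3, 1 / 3]))
        q = project_sfs(sfs, 2)
        assert q == pytest.approx([0.2222, 0.5556, 0.2222], abs=1e-4)

    @pytest.mark.parametrize("n", range(3, 9))
    def test_exhaustive_small_n(self, n):
        """Agrees with integer-combinatorics enumeration for all m <= n <= 8."""
        rng = np.random.default_rng(n)
        probs = rng.dirichlet(np.ones(n - 1))
        sfs = SFS(n, probs)
        for m in range(2, n + 1):
            got = project_sfs(sfs, m)
            exp = project_oracle(probs, n, m)
            assert got == pytest.approx(exp, abs=1e-12)
            assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            project_sfs(neutral_sfs(8), 1)
        with pytest.raises(ValueError):
            project_sfs(neutral_sfs(8), 9)


class TestSweepDistribution:
    def test_limit_recovers_background(self):
        sfs = neutral_sfs(12)
        out = sweep_site_distribution(sfs, 12, alpha=1.0, d=100.0)  # alpha*d = 100
        assert out == pytest.approx(sfs.probs, abs=1e-6)

    def test_enumeration_oracle_n4(self):
        """n=4, uniform background, p_escape=0.5: exact enumeration."""
        probs = np.array([1 / 3, 1 / 3, 1 / 3])
        sfs = SFS(4, probs)
        d = 1000.0
        alpha = -math.log(0.5) / d  # p_escape = 1/2
        got = sweep_site_distribution(sfs, 4, alpha, d)
        exp = sweep_oracle(probs, 4, 0.5)
        assert got == pytest.approx(exp, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 8])
    @pytest.mark.parametrize("p_esc", [0.1, 0.5, 0.9])
    def test_enumeration_oracle_grid(self, n, p_esc):
        rng = np.random.default_rng(n)
        probs = rng.dirichlet(np.ones(n - 1))
        d = 500.0
        alpha = -math.log(1 - p_esc) / d
        got = sweep_site_distribution(SFS(n, probs), n, alpha, d)
        exp = sweep_oracle(probs, n, p_esc)
        assert got == pytest.approx(exp, abs=1e-12)

    def test_proper_distribution_and_extreme_excess(self):
        sfs = neutral_sfs(20)
        rng = np.random.default_rng(3)
        for alpha, d in [(1e-5, 1000), (1e-4, 500), (1e-3, 2000), (2e-6, 10_000)]:
            out = sweep_site_distribution(sfs, 20, alpha, d)
            assert out.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(out >= 0)
        near = sweep_site_distribution(sfs, 20, 1e-5, 1000)  # alpha*d = 0.01
        assert near[19 - 1] > sfs.probs[19 - 1]
        assert near[0] + near[18] > sfs.probs[0] + sfs.probs[18]

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            sweep_site_distribution(neutral_sfs(10), 10, 1e-4, 0.0)


class TestClrGridpoint:
    def test_null_sites_give_small_clr(self):
        """Background-drawn sites: median CLR over replicates stays near 0."""
        n = 20
        sfs = neutral_sfs(n)
        rng = np.random.default_rng(9)
        scores = []
        for _ in range(60):
            pos = np.sort(rng.choice(np.arange(1, 200_001), 100, replace=False))
            counts = rng.choice(np.arange(1, n), p=sfs.probs, size=100)
            tbl = pd.DataFrame({"position": pos, "count": counts})
            score, _ = clr_at_gridpoint(tbl, sfs, 100_000)
            scores.append(score)
        assert np.median(scores) < 2.0
        assert min(scores) >= 0.0  # nonnegative by construction

    def test_sweep_scores_higher_at_true_position(self):
        from sweepscan import simulate_sweep_sites

        n = 20
        sfs = neutral_sfs(n)
        rng = np.random.default_rng(4)
        wins = 0
        for _ in range(10):
            pos = np.sort(rng.choice(np.arange(1, 2_000_001), 1500, replace=False))
            tbl = simulate_sweep_sites(sfs, n, 2e-5, 1_000_000, pos, rng=rng)
            at_true, _ = clr_at_gridpoint(tbl, sfs, 1_000_000)
            far, _ = clr_at_gridpoint(tbl, sfs, 1_900_000)
            wins += at_true > far
        assert wins >= 9

    def test_count_out_of_range_rejected(self):
        sfs = neutral_sfs(10)
        tbl = pd.DataFrame({"position": [100], "count": [10]})
        with pytest.raises(ValueError):
            clr_at_gridpoint(tbl, sfs, 50)

    def test_alpha_grid_spans_escape_probabilities(self):
        grid = default_alpha_grid(1000.0)
        p_lo = 1 - math.exp(-grid[0] * 1000)
        p_hi = 1 - math.exp(-grid[-1] * 1000)
        assert p_lo == pytest.approx(0.01, rel=1e-6)
        assert p_hi == pytest.approx(0.999, rel=1e-6)
        assert len(grid) == 20


class TestGenomeScan:
    def test_grid_point_count(self):
        n = 10
        sfs = neutral_sfs(n)
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 10_000_001), 400, replace=False))
        tbl = pd.DataFrame(
            {"chrom": "chr1", "position": pos,
             "count": rng.choice(np.arange(1, n), p=sfs.probs, size=400)}
        )
        track = clr_genome_scan(tbl, sfs, grid_bp=25_000, chrom_lengths={"chr1": 10_000_000})
        assert len(track) == 400
        assert (track["end"] - track["start"] == 25_000).all()

    def test_short_chromosome_single_window(self):
        n = 10
        sfs = neutral_sfs(n)
        tbl = pd.DataFrame(
            {"chrom": "c", "position": [2_000, 7_000], "count": [1, 2]}
        )
        track = clr_genome_scan(tbl, sfs, grid_bp=25_000, chrom_lengths={"c": 10_000})
        assert len(track) == 1
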