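"""Composite-likelihood-ratio sweep scan.

The scan compares, at each point of a 25-kb genomic grid, the composite
likelihood of the observed derived-allele counts under a hard-sweep model
against their likelihood under the genome-wide background site-frequency
spectrum (SFS).  The sweep model is the classic lineage-escape mixture: a
lineage sampled at distance ``d`` from the swept site recombines away from
the sweeping haplotype ("escapes") with probability ``1 - exp(-alpha * d)``;
non-escaped lineages coalesce instantly into the single sweeping ancestor.
The number of escaped lineages ``e`` is Binomial(n, p_escape); the ``e``
escapees plus the sweep ancestor form an ancestral sample of size ``e + 1``
whose derived count follows the background SFS projected down by
hypergeometric sampling.

CLR(x) = 2 * [ max_alpha sum_i log P(b_i | alpha, d_i) - sum_i log p_bg(b_i) ]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

from .datatypes import GenotypeDataset, MISSING, window_track

__all__ = [
    "SFS",
    "background_sfs",
    "project_sfs",
    "sweep_site_distribution",
    "clr_at_gridpoint",
    "clr_genome_scan",
    "default_alpha_grid",
]


@dataclass(frozen=True)
class SFS:
    """Normalized site-frequency spectrum over polymorphic classes.

    ``probs[j - 1]`` is the probability of derived count ``j`` for
    ``j = 1 .. n-1`` (unfolded) or minor count ``j = 1 .. n//2`` (folded).
    """

    n: int
    probs: np.ndarray
    folded: bool = False

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        expected = self.n // 2 if self.folded else self.n - 1
        if probs.shape != (expected,):
            raise ValueError(f"probs must have length {expected}, got {probs.shape}")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValueError("probs must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", probs)


def neutral_sfs(n: int, folded: bool = False) -> SFS:
    """Standard neutral spectrum, p(j) proportional to 1/j."""
    j = np.arange(1, n)
    p = 1.0 / j
    p /= p.sum()
    if folded:
        half = n // 2
        fold = np.zeros(half)
        for jj in range(1, n):
            fold[min(jj, n - jj) - 1] += p[jj - 1]
        return SFS(n=n, probs=fold, folded=True)
    return SFS(n=n, probs=p)


def background_sfs(
    counts: np.ndarray | pd.Series,
    n: int,
    folded: bool = False,
    project_to: int | None = None,
    sample_sizes: np.ndarray | None = None,
) -> SFS:
    """Genome-wide background spectrum from per-site derived counts.

    Parameters
    ----------
    counts
        Derived (or alt) allele count per site.
    n
        Haploid sample size the counts refer to.  Sites with missing data
        may carry smaller observed sizes via ``sample_sizes``; those sites
        are projected down to ``project_to`` (hypergeometric) or dropped.
    folded
        Fold to minor-allele counts (use when ancestral state is unknown).
    project_to
        Common haploid size after projection; defaults to the minimum
        observed size when ``sample_sizes`` is given, else ``n``.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("no sites supplied")
    if sample_sizes is None:
        sizes = np.full(counts.shape, n, dtype=int)
    else:
        sizes = np.asarray(sample_sizes, dtype=int)
    m = project_to if project_to is not None else int(sizes.min())
    if m < 2:
        raise ValueError("projected sample size must be at least 2")

    mass = np.zeros(m + 1)
    for size in np.unique(sizes):
        sub = counts[sizes == size]
        hist = np.bincount(sub, minlength=size + 1).astype(float)
        if size == m:
            mass += hist
        else:
            # project each observed class down to m lineages
            jp = np.arange(m + 1)
            for j, cnt in enumerate(hist):
                if cnt:
                    mass += cnt * hypergeom.pmf(jp, size, j, m)
    poly = mass[1:m]
    if poly.sum() <= 0:
        raise ValueError("no polymorphic sites after projection")
    probs = poly / poly.sum()
    if folded:
        half = m // 2
        fold = np.zeros(half)
        for j in range(1, m):
            fold[min(j, m - j) - 1] += probs[j - 1]
        return SFS(n=m, probs=fold, folded=True)
    return SFS(n=m, probs=probs)


def background_sfs_from_dataset(
    dataset: GenotypeDataset,
    population: str | None = None,
    folded: bool = False,
    project_to: int | None = None,
) -> SFS:
    """Background SFS from a genotype dataset (one population or pooled)."""
    if population is not None:
        dataset = dataset.subset_samples(population)
    g = dataset.genotypes
    obs = g != MISSING
    counts = np.where(obs, g, 0).sum(axis=1)
    sizes = 2 * obs.sum(axis=1)
    keep = sizes >= 2
    return background_sfs(
        counts[keep], n=2 * dataset.n_samples, folded=folded,
        project_to=project_to, sample_sizes=sizes[keep],
    )


def _hypergeom_matrix(n: int, m: int) -> np.ndarray:
    """H[J, j'] = P(j' derived in m draws | J derived among n), J=0..n, j'=0..m."""
    J = np.arange(n + 1)[:, None]
    jp = np.arange(m + 1)[None, :]
    with np.errstate(invalid="ignore"):
        logh = (
            _log_binom(J, jp)
            + _log_binom(n - J, m - jp)
            - _log_binom(np.full_like(J, n), np.full((1, m + 1), m))
        )
    H = np.where(np.isfinite(logh), np.exp(logh), 0.0)
    return H


def _log_binom(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where((b < 0) | (b > a), -np.inf, out)


def project_sfs(sfs: SFS, m: int, condition: bool = False) -> np.ndarray:
    """Hypergeometric projection of the spectrum to ``m`` lineages.

    Returns the raw vector ``q[0..m]`` including the monomorphic classes,
    or, with ``condition=True``, the vector renormalized over ``1..m-1``.
    """
    if sfs.folded:
        raise ValueError("projection requires an unfolded spectrum")
    if not 2 <= m <= sfs.n:
        raise ValueError(f"target size m={m} outside 2..{sfs.n}")
    if m == sfs.n and not condition:
        q = np.zeros(m + 1)
        q[1:m] = sfs.probs
        return q
    full = np.zeros(sfs.n + 1)
    full[1:sfs.n] = sfs.probs
    q = full @ _hypergeom_matrix(sfs.n, m)
    if condition:
        poly = q[1:m]
        return poly / poly.sum()
    return q


class _SweepKernel:
    """Precomputed per-escape-count modern-class table for one background SFS.

    ``Q[e, b]`` is P(modern derived count = b | e escaped lineages), raw
    (including the monomorphic classes b = 0 and b = n); ``Z[e]`` is the
    polymorphism probability given ``e``.  Both depend only on the SFS, so
    the table is built once and reused across alphas, distances and grid
    points.
    """

    def __init__(self, sfs: SFS):
        if sfs.folded:
            raise ValueError("the sweep model requires an unfolded spectrum")
        n = sfs.n
        Q = np.zeros((n + 1, n + 1))
        for e in range(n + 1):
            if e == n:
                # every lineage escaped: the sweep ancestor has no modern
                # descendants and the sample is a background draw
                Q[e, 1:n] = sfs.probs
                continue
            m = e + 1
            qproj = project_sfs(sfs, m) if m >= 2 else _project_to_one(sfs)
            for j in range(m + 1):
                pj = qproj[j]
                if pj == 0.0:
                    continue
                w_anc = j / m  # sweep ancestor carries the derived allele
                if j >= 1:
                    Q[e, (j - 1) + (n - e)] += pj * w_anc
                Q[e, j] += pj * (1.0 - w_anc)
        self.n = n
        self.Q = Q
        self.Z = Q[:, 1:n].sum(axis=1)
        self.log_binom = gammaln(n + 1) - gammaln(np.arange(n + 1) + 1) - gammaln(
            n - np.arange(n + 1) + 1
        )

    def escape_weights(self, alpha: float | np.ndarray, d: np.ndarray) -> np.ndarray:
        """Binomial(n, 1-exp(-alpha d)) pmf over e.

        Returns shape ``(n_d, n+1)`` for scalar alpha, ``(n_alpha, n_d,
        n+1)`` for an alpha vector.
        """
        d = np.atleast_1d(np.asarray(d, dtype=float))
        scalar = np.isscalar(alpha) or np.ndim(alpha) == 0
        a = np.atleast_1d(np.asarray(alpha, dtype=float))
        ad = a[:, None] * d[None, :]  # (A, S)
        p_esc = -np.expm1(-ad)  # 1 - exp(-alpha d), accurate near 0
        e = np.arange(self.n + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(p_esc > 0, np.log(p_esc), -np.inf)
        # log(1 - p_esc) = -alpha d exactly
        logw = (
            self.log_binom[None, None, :]
            + e[None, None, :] * logp[:, :, None]
            - (self.n - e)[None, None, :] * ad[:, :, None]
        )
        # p_esc == 0 would need d == 0, which callers reject; guard anyway
        w = np.exp(logw)
        w[p_esc <= 0] = 0.0
        w[p_esc <= 0, 0] = 1.0
        return w[0] if scalar else w


def _project_to_one(sfs: SFS) -> np.ndarray:
    """Projection to a single lineage: P(derived) = sum_j p(j) j/n."""
    j = np.arange(1, sfs.n)
    p1 = float(np.sum(sfs.probs * j / sfs.n))
    return np.array([1.0 - p1, p1])


def sweep_site_distribution(
    sfs: SFS, n: int, alpha: float, d: float, _kernel: _SweepKernel | None = None
) -> np.ndarray:
    """Distribution of the derived count at distance ``d`` from a sweep.

    Returns probabilities over counts ``1 .. n-1`` (conditioned on
    polymorphism).  ``alpha`` is the sweep intensity per bp; ``d`` the
    physical distance in bp.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if d <= 0:
        raise ValueError("distance must be positive (polymorphism probability is 0 at d=0)")
    if n != sfs.n:
        raise ValueError(f"sample size {n} does not match spectrum size {sfs.n}")
    kern = _kernel if _kernel is not None else _SweepKernel(sfs)
    w = kern.escape_weights(alpha, np.array([d]))[0]
    raw = w @ kern.Q
    norm = float(w @ kern.Z)
    return raw[1:n] / norm


def default_alpha_grid(nearest_d: float, n_points: int = 20) -> np.ndarray:
    """Log-spaced alpha grid spanning p_escape(nearest site) in [0.01, 0.999].

    The largest alpha is near-neutral (almost every lineage escapes even at
    the nearest site); the smallest corresponds to a sweep engulfing the
    nearest site.  Grid is returned in increasing order.
    """
    if nearest_d <= 0:
        raise ValueError("nearest distance must be positive")
    lo = -np.log(1 - 0.01) / nearest_d
    hi = -np.log(1 - 0.999) / nearest_d
    return np.geomspace(lo, hi, n_points)


def clr_at_gridpoint(
    sites: pd.DataFrame,
    sfs: SFS,
    test_position: float,
    alpha_grid: np.ndarray | None = None,
    _kernel: _SweepKernel | None = None,
) -> tuple[float, float]:
    """CLR score and fitted alpha at one test position.

    ``sites`` must have columns ``position`` and ``count`` (derived count in
    ``1..n-1``).  Sites exactly at the test position are excluded.  The
    score is clipped at 0: the neutral model (alpha -> infinity) is always
    an admissible fit, in which case ``alpha_hat`` is ``inf``.
    """
    n = sfs.n
    pos = np.asarray(sites["position"], dtype=float)
    b = np.asarray(sites["count"], dtype=int)
    if np.any((b < 1) | (b > n - 1)):
        raise ValueError("derived counts must lie in 1..n-1")
    d = np.abs(pos - test_position)
    keep = d > 0
    b, d = b[keep], d[keep]
    if b.size == 0:
        return 0.0, np.inf
    kern = _kernel if _kernel is not None else _SweepKernel(sfs)
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(float(d.min()))
    ll0 = float(np.sum(np.log(sfs.probs[b - 1])))
    grid = np.sort(np.asarray(alpha_grid, dtype=float))
    Qb = kern.Q[:, b]  # (n+1, n_sites): raw mass at each observed count
    w = kern.escape_weights(grid, d)  # (A, n_sites, n+1)
    num = np.einsum("ase,es->as", w, Qb)
    den = w @ kern.Z
    ll = np.sum(np.log(num) - np.log(den), axis=1)
    i = int(np.argmax(ll + np.arange(len(grid))[::-1] * 1e-12))  # ties -> smallest alpha
    if ll[i] <= ll0:
        return 0.0, np.inf
    return 2.0 * float(ll[i] - ll0), float(grid[i])


def clr_genome_scan(
    dataset: GenotypeDataset | pd.DataFrame,
    sfs: SFS,
    grid_bp: int = 25_000,
    chrom_lengths: dict[str, int] | None = None,
    max_radius_bp: int = 1_000_000,
    n_alpha: int = 20,
    population: str | None = None,
) -> pd.DataFrame:
    """CLR at grid points every ``grid_bp`` along each chromosome.

    Accepts either a complete (imputed) :class:`GenotypeDataset`, in which
    case derived counts are alt-allele sums over the chosen population, or a
    DataFrame with columns ``chrom, position, count``.  Returns a window
    track with one row per grid point, the window being the ``grid_bp``
    interval centred on it.
    """
    if isinstance(dataset, GenotypeDataset):
        ds = dataset.subset_samples(population) if population else dataset
        if np.any(ds.genotypes == MISSING):
            raise ValueError("scan requires complete (imputed) genotypes")
        counts = ds.genotypes.sum(axis=1).astype(int)
        table = pd.DataFrame(
            {"chrom": ds.sites["chrom"], "position": ds.sites["pos"], "count": counts}
        )
        poly = (table["count"] >= 1) & (table["count"] <= sfs.n - 1)
        table = table.loc[poly]
    else:
        table = dataset
    kern = _SweepKernel(sfs)

    rows: list[tuple] = []
    for chrom, sub in table.groupby("chrom", sort=False):
        pos = sub["position"].to_numpy(dtype=float)
        length = (
            chrom_lengths[str(chrom)]
            if chrom_lengths and str(chrom) in chrom_lengths
            else int(pos.max())
        )
        if length < grid_bp:
            points = np.array([length / 2.0])
        else:
            points = np.arange(grid_bp / 2.0, length, grid_bp)
        order = np.argsort(pos)
        pos_s = pos[order]
        sub_s = sub.iloc[order]
        for pt in points:
            d_all = np.abs(pos_s - pt)
            nearest = d_all[d_all > 0].min() if np.any(d_all > 0) else np.nan
            if not np.isfinite(nearest):
                continue
            grid = default_alpha_grid(nearest, n_alpha)
            radius = min(max_radius_bp, np.log(1000.0) / grid.min())
            local = sub_s.loc[d_all <= radius, ["position", "count"]]
            score, alpha_hat = clr_at_gridpoint(local, sfs, pt, grid, _kernel=kern)
            rows.append(
                (chrom, int(pt - grid_bp / 2), int(pt + grid_bp / 2), score, alpha_hat)
            )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "alpha_hat"])
    return window_track(
        out["chrom"].to_numpy(), out["start"].to_numpy(), out["end"].to_numpy(),
        out["score"].to_numpy(), alpha_hat=out["alpha_hat"].to_numpy(),
    )
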