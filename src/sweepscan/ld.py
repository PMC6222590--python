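"""Pairwise dosage r-squared and the binned LD-decay curve.

r2 is the squared Pearson correlation of alt-allele dosages over samples
non-missing at both sites (genotypes are unphased, so no haplotype-EM
estimator is attempted).  Pairs where either site is monomorphic among the
complete observations are undefined and excluded from curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, MISSING

__all__ = ["pair_r2", "ld_decay_curve"]


def pair_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples.

    Returns NaN when fewer than two complete pairs remain or either site is
    monomorphic among them.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.size < 2:
        raise ValueError("dosage vectors must share a length of at least 2")
    ok = (g1 != MISSING) & (g2 != MISSING)
    x, y = g1[ok], g2[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_decay_curve(
    dataset: GenotypeDataset, max_dist_bp: int, bin_bp: int = 1000
) -> pd.DataFrame:
    """Mean r2 in half-open 1000-bp distance bins over intra-chromosome pairs.

    All pairs with distance <= ``max_dist_bp`` are scored; a pair at
    distance d lands in bin [k*bin_bp, (k+1)*bin_bp) with k = d // bin_bp.
    Empty bins are reported with ``n_pairs = 0`` and NaN mean.
    """
    if max_dist_bp < bin_bp:
        raise ValueError("max_dist_bp must be at least bin_bp")
    n_bins = max_dist_bp // bin_bp + (1 if max_dist_bp % bin_bp else 0)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    g = dataset.genotypes
    pos_all = dataset.sites["pos"].to_numpy()
    for _, sub in dataset.sites.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = pos_all[idx]
        for a in range(idx.size):
            # sites are position-sorted: advance until out of range
            for b in range(a + 1, idx.size):
                d = pos[b] - pos[a]
                if d > max_dist_bp:
                    break
                r2 = pair_r2(g[idx[a]], g[idx[b]])
                if np.isnan(r2):
                    continue
                k = int(d // bin_bp)
                if k >= n_bins:
                    continue
                sums[k] += r2
                counts[k] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_bp,
            "bin_end": (np.arange(n_bins) + 1) * bin_bp,
            "mean_r2": mean,
            "n_pairs": counts,
        }
    )
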