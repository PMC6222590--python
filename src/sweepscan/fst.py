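"""Weir & Cockerham (1984) F_ST for two populations.

Per-site variance components a (among populations), b (among individuals
within populations) and c (within individuals) are computed from genotype
counts; theta-hat = a / (a + b + c).  Sites monomorphic in both populations
have a zero denominator and are flagged undefined.  Negative estimates are
retained (clamping biases window means toward zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, window_track

__all__ = ["wc_fst_site", "fst_site_table", "fst_window_average", "multilocus_fst"]

_R = 2  # number of populations


def wc_fst_site(
    pop1: tuple[int, int, int], pop2: tuple[int, int, int]
) -> tuple[float, float, float, float]:
    """Variance components and theta-hat from per-population genotype counts.

    Each population is given as ``(n_AA, n_Aa, n_aa)`` counts of the three
    genotype classes over its non-missing diploids.  Returns ``(a, b, c,
    theta)``; ``theta`` is NaN when ``a + b + c == 0``.
    """
    comp = _components(
        np.array([[pop1[0], pop1[1], pop1[2]], [pop2[0], pop2[1], pop2[2]]], dtype=float)[None]
    )
    a, b, c = (float(comp[k][0]) for k in ("a", "b", "c"))
    tot = a + b + c
    theta = a / tot if tot != 0.0 else np.nan
    return a, b, c, theta


def _components(counts: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized W&C components; ``counts`` is (sites, 2 pops, 3 classes)."""
    n_i = counts.sum(axis=2)  # diploids per pop
    if np.any(n_i < 2):
        bad = np.argwhere(n_i < 2)
        raise ValueError(
            f"population with fewer than 2 non-missing diploids at site index {bad[0][0]}"
        )
    p_i = (2 * counts[:, :, 0] + counts[:, :, 1]) / (2 * n_i)  # freq of allele A
    h_i = counts[:, :, 1] / n_i  # observed het frequency

    nbar = n_i.mean(axis=1)
    nc = (_R * nbar - (n_i**2).sum(axis=1) / (_R * nbar)) / (_R - 1)
    pbar = (n_i * p_i).sum(axis=1) / (_R * nbar)
    s2 = (n_i * (p_i - pbar[:, None]) ** 2).sum(axis=1) / ((_R - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=1) / (_R * nbar)

    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1))
        * (pbar * (1 - pbar) - s2 * (_R - 1) / _R - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (_R - 1) / _R - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return {"a": a, "b": b, "c": c}


def fst_site_table(
    dataset: GenotypeDataset, pop1: str, pop2: str, min_diploids: int = 2
) -> pd.DataFrame:
    """Per-site components and theta-hat between two labelled populations.

    Sites where either population has fewer than ``min_diploids``
    non-missing genotypes are dropped; sites monomorphic in both
    populations carry ``theta = NaN``.
    """
    counts = np.stack(
        [
            _genotype_counts(dataset, pop1),
            _genotype_counts(dataset, pop2),
        ],
        axis=1,
    )  # (sites, 2, 3)
    ok = (counts.sum(axis=2) >= min_diploids).all(axis=1)
    comp = _components(counts[ok])
    tot = comp["a"] + comp["b"] + comp["c"]
    with np.errstate(invalid="ignore"):
        theta = np.where(tot != 0.0, comp["a"] / np.where(tot != 0.0, tot, 1.0), np.nan)
    sites = dataset.sites.loc[ok, ["chrom", "pos"]].reset_index(drop=True)
    return sites.assign(a=comp["a"], b=comp["b"], c=comp["c"], theta=theta)


def _genotype_counts(dataset: GenotypeDataset, pop: str) -> np.ndarray:
    g = dataset.genotypes[:, dataset.population_index(pop)]
    # classes by alt dosage: AA=0 copies, Aa=1, aa=2 (labels are arbitrary;
    # theta is invariant to ref/alt relabeling)
    return np.stack([(g == 0).sum(axis=1), (g == 1).sum(axis=1), (g == 2).sum(axis=1)], axis=1)


def multilocus_fst(site_table: pd.DataFrame) -> float:
    """Multi-locus Weir-Cockerham estimate, sum(a) / sum(a + b + c).

    This is the ratio-of-sums estimator W&C recommend for combining loci;
    unlike the mean of per-site theta-hat it is a consistent estimator of
    the differentiation parameter (the per-site ratio average is biased
    toward zero because site denominators vary and the ratio is nonlinear).
    Use window means for genome-wide *ranking*, this for *estimating* F.
    """
    tot = (site_table["a"] + site_table["b"] + site_table["c"]).sum()
    if tot == 0:
        raise ValueError("all sites monomorphic: differentiation undefined")
    return float(site_table["a"].sum() / tot)


def fst_window_average(
    site_table: pd.DataFrame,
    window_bp: int = 25_000,
    min_sites: int = 1,
    method: str = "mean_theta",
) -> pd.DataFrame:
    """Per-window F_ST score in non-overlapping half-open windows.

    Windows are ``[k * window_bp, (k+1) * window_bp)`` anchored at 0 on each
    chromosome; windows with fewer than ``min_sites`` defined (non-NaN)
    sites are omitted from the track.  ``method`` is ``"mean_theta"``
    (arithmetic mean of per-site theta-hat, the default ranking score) or
    ``"ratio_of_sums"`` (per-window multi-locus estimate).
    """
    if method not in ("mean_theta", "ratio_of_sums"):
        raise ValueError(f"unknown method {method!r}")
    tbl = site_table.dropna(subset=["theta"])
    if tbl.empty:
        return window_track(
            np.array([], dtype=object), np.array([], int), np.array([], int),
            np.array([], float), n_sites=np.array([], int),
        )
    win = (tbl["pos"].to_numpy() - 1) // window_bp  # pos is 1-based
    grouped = tbl.assign(win=win).groupby(["chrom", "win"], sort=True)
    if method == "mean_theta":
        agg = grouped["theta"].agg(["mean", "count"]).reset_index()
    else:
        agg = grouped.apply(
            lambda g: pd.Series({"mean": multilocus_fst(g), "count": len(g)}),
            include_groups=False,
        ).reset_index()
    agg = agg[agg["count"] >= min_sites]
    return window_track(
        agg["chrom"].to_numpy(),
        (agg["win"] * window_bp).to_numpy(dtype=int),
        ((agg["win"] + 1) * window_bp).to_numpy(dtype=int),
        agg["mean"].to_numpy(),
        n_sites=agg["count"].to_numpy(dtype=int),
    )
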