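"""VCF input and site-level quality control.

Filters follow the fixed order depth -> mapping quality -> adjacent-SNP
distance -> per-population missingness -> MAF -> (optionally) HWE, each
site being attributed to the first criterion it fails.  The HWE test is the
exact conditional test on genotype counts.  Missing genotypes are imputed
by drawing from Binomial(2, per-population allele frequency) — a simple,
documented stand-in for haplotype-based imputation, which is out of scope.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy.special import gammaln

from .datatypes import GenotypeDataset, MISSING, SITE_COLUMNS

__all__ = [
    "QcThresholds",
    "read_vcf",
    "hwe_exact_test",
    "filter_sites",
    "impute_missing",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Site-level filter thresholds.

    Defaults mirror common GBS practice: per-site depth >= 4, RMS mapping
    quality >= 20, adjacent SNPs >= 5 bp apart, within-population missing
    ratio < 0.5 (tightened to 0.2 for the selection scan), pooled MAF >=
    0.01, and an HWE exact-test floor of 1e-6 applied only to the GWAS set.
    """

    min_depth: float = 4.0
    min_mapq: float = 20.0
    min_adjacent_bp: int = 5
    max_missing: float = 0.5
    min_maf: float = 0.01
    hwe_p_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.max_missing <= 1.0):
            raise ValueError("max_missing must be in (0, 1]")
        if not (0.0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")
        if not (0.0 < self.hwe_p_floor < 1.0):
            raise ValueError("hwe_p_floor must be in (0, 1)")


FILTER_ORDER = ["depth", "mapq", "adjacency", "missingness", "maf", "hwe"]


def read_vcf(path: str | os.PathLike, population_map: dict[str, str]) -> GenotypeDataset:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeDataset`.

    Multi-allelic and non-SNP records are skipped (count logged).  Phased
    and unphased genotypes are treated identically; half-calls and missing
    calls become :data:`MISSING`.

    Parameters
    ----------
    population_map
        Maps every sample of interest to its population label; samples not
        in the map are dropped, samples in the map but absent from the file
        raise ``KeyError``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    file_samples = list(vcf.samples)
    absent = sorted(set(population_map) - set(file_samples))
    if absent:
        raise KeyError(f"samples in population map absent from VCF: {absent}")
    keep_idx = [i for i, s in enumerate(file_samples) if s in population_map]
    samples = [file_samples[i] for i in keep_idx]
    populations = np.array([population_map[s] for s in samples], dtype=object)

    rows, geno_rows, skipped = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        gts = np.asarray(rec.genotypes)  # (n_samples, 3): allele1, allele2, phased
        alleles = gts[keep_idx, :2]
        dos = alleles.sum(axis=1)
        dos[(alleles < 0).any(axis=1)] = MISSING
        geno_rows.append(dos.astype(np.int8))
        info = dict(rec.INFO)
        rows.append(
            (
                rec.CHROM,
                rec.POS,
                rec.REF,
                rec.ALT[0],
                float(info.get("DP", np.nan)),
                float(info.get("MQ", np.nan)),
            )
        )
    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return GenotypeDataset(
        samples=samples,
        populations=populations,
        sites=sites,
        genotypes=np.vstack(geno_rows),
    )


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact conditional test of Hardy-Weinberg equilibrium.

    Conditioning on the observed allele counts, the null distribution over
    heterozygote counts (of fixed parity) is

        P(n_Aa | n, n_A) propto n! / (n_AA! n_Aa! n_aa!) * 2**n_Aa

    and the p-value sums the probabilities of all configurations no more
    probable than the observed one (Wigginton et al. 2005 convention).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype observation required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = (max(n_A, n_a) - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(homs_rare + 1)
        - gammaln(hets + 1)
        - gammaln(homs_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa]
    if p_obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


@dataclass
class FilterReport:
    """Per-criterion removal counts, in application order."""

    counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"criterion": list(self.counts), "sites_removed": list(self.counts.values())}
        )

    @property
    def total_removed(self) -> int:
        return sum(self.counts.values())


def filter_sites(
    dataset: GenotypeDataset, thresholds: QcThresholds, hwe: bool = False
) -> tuple[GenotypeDataset, FilterReport]:
    """Apply the site filters in fixed order; returns dataset and report.

    The adjacency rule is greedy left-to-right: a site is dropped when its
    distance to the last *retained* site on the chromosome is below
    ``min_adjacent_bp``.  MAF is computed on pooled non-missing genotypes;
    missingness per population; HWE (pooled counts) only when ``hwe``.
    """
    report = FilterReport()
    ds = dataset

    def apply(name: str, keep: np.ndarray) -> None:
        nonlocal ds
        report.counts[name] = int((~keep).sum())
        ds = ds.subset_sites(keep)

    depth = ds.sites["depth"].to_numpy(dtype=float)
    apply("depth", ~(depth < thresholds.min_depth))  # NaN depth passes
    mapq = ds.sites["mapq"].to_numpy(dtype=float)
    apply("mapq", ~(mapq < thresholds.min_mapq))

    keep = np.ones(ds.n_sites, dtype=bool)
    for chrom, sub in ds.sites.groupby("chrom", sort=False):
        last = -np.inf
        for idx, pos in zip(sub.index, sub["pos"]):
            if pos - last < thresholds.min_adjacent_bp:
                keep[idx] = False
            else:
                last = pos
    apply("adjacency", keep)

    miss_ok = np.ones(ds.n_sites, dtype=bool)
    for pop in np.unique(ds.populations):
        g = ds.genotypes[:, ds.population_index(pop)]
        frac = (g == MISSING).mean(axis=1)
        miss_ok &= frac < thresholds.max_missing
    apply("missingness", miss_ok)

    g = ds.genotypes
    obs = g != MISSING
    n_obs = obs.sum(axis=1)
    alt = np.where(obs, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0, alt / np.maximum(2 * n_obs, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)
    apply("maf", (maf >= thresholds.min_maf) & (n_obs > 0))

    if hwe:
        # tested within each population: pooling differentiated populations
        # fails HWE at every divergent site (Wahlund effect)
        keep = np.ones(ds.n_sites, dtype=bool)
        for pop in np.unique(ds.populations):
            g = ds.genotypes[:, ds.population_index(pop)]
            obs = g != MISSING
            for i in range(ds.n_sites):
                row = g[i][obs[i]]
                if row.size == 0:
                    continue
                p = hwe_exact_test(
                    int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum())
                )
                keep[i] &= p >= thresholds.hwe_p_floor
        apply("hwe", keep)

    return ds, report


def impute_missing(
    dataset: GenotypeDataset, rng: np.random.Generator | int | None = 0
) -> GenotypeDataset:
    """Fill missing genotypes with Binomial(2, within-population frequency).

    Observed genotypes are never altered.  A site with no observed
    genotypes in some population is an error (its frequency is undefined).
    Deterministic for a fixed ``rng`` seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = dataset.genotypes.copy()
    for pop in np.unique(dataset.populations):
        cols = dataset.population_index(pop)
        sub = g[:, cols]
        obs = sub != MISSING
        n_obs = obs.sum(axis=1)
        need = ~obs
        if not need.any():
            continue
        empty = (n_obs == 0) & need.any(axis=1)
        if empty.any():
            i = int(np.flatnonzero(empty)[0])
            site = dataset.sites.iloc[i]
            raise ValueError(
                f"site {site['chrom']}:{site['pos']} entirely missing in population {pop!r}"
            )
        freq = np.where(obs, sub, 0).sum(axis=1) / np.maximum(2 * n_obs, 1)
        fill = rng.binomial(2, np.broadcast_to(freq[:, None], sub.shape)[need])
        sub = sub.copy()
        sub[need] = fill.astype(np.int8)
        g[:, cols] = sub
    return GenotypeDataset(
        samples=list(dataset.samples),
        populations=dataset.populations.copy(),
        sites=dataset.sites.copy(),
        genotypes=g,
    )
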