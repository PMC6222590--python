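"""Mixed-model association with a LOCO GRM and SimpleM multiple-testing correction.

Model per SNP:  y = u + S s + x b + g + e,  g ~ N(0, sigma2_a * G),
e ~ N(0, sigma2_e * I), with S the batch design and G the standardized
genomic relationship matrix built from all SNPs *except* those on the test
SNP's chromosome (leave-one-chromosome-out).  For each SNP the variance
ratio delta = sigma2_e / sigma2_a is estimated by 1-D restricted-likelihood
maximization after a single eigendecomposition of G per chromosome; b and
its standard error come from GLS at the optimum and are tested with a
1-df Wald chi-square.

The genome-wide threshold is alpha / M_eff where M_eff (SimpleM) counts,
per chromosome, the leading principal components explaining 99% of the
SNP-correlation-matrix variance, summed over chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .datatypes import GenotypeDataset, MISSING

__all__ = [
    "standardized_grm",
    "lmm_assoc",
    "loco_scan",
    "simpleM_eff",
    "significance_threshold",
]

logger = logging.getLogger(__name__)


def standardized_grm(
    genotypes: GenotypeDataset | np.ndarray, exclude_chromosome: str | None = None
) -> np.ndarray:
    """G = Z Z' / m over centered, unit-variance SNP columns.

    ``exclude_chromosome`` drops that chromosome's SNPs (LOCO).  Monomorphic
    SNPs are skipped with a logged count.  Genotypes must be complete.
    """
    if isinstance(genotypes, GenotypeDataset):
        mask = np.ones(genotypes.n_sites, dtype=bool)
        if exclude_chromosome is not None:
            mask &= (genotypes.sites["chrom"] != exclude_chromosome).to_numpy()
        g = genotypes.genotypes[mask].astype(float)
    else:
        g = np.asarray(genotypes, dtype=float)
    if np.any(g == MISSING):
        raise ValueError("GRM requires complete (imputed) genotypes")
    sd = g.std(axis=1)
    poly = sd > 0
    if (~poly).any():
        logger.info("standardized_grm: skipped %d monomorphic SNPs", int((~poly).sum()))
    g = g[poly]
    if g.shape[0] < 2:
        raise ValueError("fewer than 2 polymorphic SNPs available for the GRM")
    Z = (g - g.mean(axis=1, keepdims=True)) / sd[poly][:, None]
    return Z.T @ Z / Z.shape[0]


def batch_design(batches: np.ndarray | pd.Series) -> np.ndarray:
    """Intercept + treatment-coded batch dummies (first level as reference)."""
    b = pd.Series(np.asarray(batches)).astype("category")
    levels = list(b.cat.categories)
    X = np.ones((len(b), len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (b == lev).to_numpy(dtype=float)
    return X


class _EigenLMM:
    """Eigen-rotated restricted-likelihood machinery for one G matrix."""

    def __init__(self, G: np.ndarray, y: np.ndarray, C: np.ndarray):
        vals, vecs = np.linalg.eigh(G)
        self.D = np.clip(vals, 0.0, None)
        self.U = vecs
        self.y = self.U.T @ y
        self.C = self.U.T @ C
        self.n = y.size

    def neg_reml(self, log10_delta: float, x: np.ndarray) -> float:
        return -self.reml(10.0 ** log10_delta, x)[0]

    def reml(self, delta: float, x: np.ndarray):
        """REML criterion (up to constants) and GLS pieces at one delta."""
        F = np.column_stack([self.C, x])
        w = 1.0 / (self.D + delta)
        Fw = F * w[:, None]
        A = Fw.T @ F
        rhs = Fw.T @ self.y
        try:
            beta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular fixed-effect design (collinear covariates)") from exc
        resid = self.y - F @ beta
        rss = float(resid @ (w * resid))
        n, p = self.n, F.shape[1]
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0 or rss <= 0:
            return -np.inf, beta, A, rss
        ll = -0.5 * (
            (n - p) * np.log(rss) + np.sum(np.log(self.D + delta)) + logdet_A
        )
        return ll, beta, A, rss

    def fit_snp(self, x_rot: np.ndarray) -> tuple[float, float, float, float]:
        """(beta, se, wald_p, delta_hat) for one rotated SNP column."""
        grid = np.linspace(-5.0, 5.0, 21)
        vals = [self.neg_reml(g, x_rot) for g in grid]
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            self.neg_reml, args=(x_rot,), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        delta = 10.0 ** float(res.x)
        ll, beta, A, rss = self.reml(delta, x_rot)
        n, p = self.n, A.shape[0]
        sigma2_a = rss / (n - p)
        cov = sigma2_a * np.linalg.inv(A)
        b = float(beta[-1])
        se = float(np.sqrt(cov[-1, -1]))
        wald = (b / se) ** 2
        pval = float(chi2.sf(wald, df=1))
        return b, se, max(pval, np.finfo(float).tiny), delta


def lmm_assoc(
    y: np.ndarray,
    batches: np.ndarray,
    x: np.ndarray,
    G: np.ndarray,
) -> tuple[float, float, float]:
    """Single-SNP mixed-model Wald test.

    Returns ``(beta, se, wald_p)``; the SNP must be polymorphic.  With
    G = I the model collapses to OLS with iid errors.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if x.std() == 0:
        raise ValueError("monomorphic SNP: no test")
    C = batch_design(batches)
    if np.linalg.matrix_rank(np.column_stack([C, x])) < C.shape[1] + 1:
        raise ValueError("singular fixed-effect design (collinear covariates)")
    core = _EigenLMM(G, y, C)
    b, se, p, _ = core.fit_snp(core.U.T @ x)
    return b, se, p


def loco_scan(
    dataset: GenotypeDataset,
    phenotypes: pd.DataFrame,
    no_loco: bool = False,
    var_fraction: float = 0.99,
    alpha: float = 0.05,
) -> dict:
    """Genome-wide LOCO mixed-model scan plus SimpleM threshold.

    ``phenotypes`` must carry columns ``sample, trait, batch`` matching the
    dataset's samples.  Returns a dict with keys ``assoc`` (per-SNP table:
    chrom, pos, beta, se, wald_p), ``m_eff`` and ``threshold``.
    """
    pheno = phenotypes.set_index("sample")
    missing_ids = [s for s in dataset.samples if s not in pheno.index]
    if missing_ids:
        raise ValueError(f"samples missing from phenotype table: {missing_ids[:5]}")
    pheno = pheno.loc[dataset.samples]
    y = pheno["trait"].to_numpy(dtype=float)
    C = batch_design(pheno["batch"].to_numpy())

    chroms = dataset.sites["chrom"].drop_duplicates().tolist()
    if len(chroms) < 2 and not no_loco:
        raise ValueError(
            "LOCO needs at least 2 chromosomes; pass no_loco=True to use the full GRM"
        )
    if np.any(dataset.genotypes == MISSING):
        raise ValueError("scan requires complete (imputed) genotypes")

    rows = []
    for chrom in chroms:
        G = standardized_grm(dataset, exclude_chromosome=None if no_loco else chrom)
        core = _EigenLMM(G, y, C)
        on = (dataset.sites["chrom"] == chrom).to_numpy()
        g = dataset.genotypes[on].astype(float)
        pos = dataset.sites["pos"].to_numpy()[on]
        X_rot = core.U.T @ g.T  # (n, m_chrom)
        for j in range(g.shape[0]):
            if g[j].std() == 0:
                rows.append((chrom, int(pos[j]), np.nan, np.nan, np.nan))
                continue
            b, se, p, _ = core.fit_snp(X_rot[:, j])
            rows.append((chrom, int(pos[j]), b, se, p))
    assoc = pd.DataFrame(rows, columns=["chrom", "pos", "beta", "se", "wald_p"])
    m_eff = simpleM_eff(dataset, var_fraction=var_fraction)
    return {
        "assoc": assoc,
        "m_eff": m_eff,
        "threshold": significance_threshold(m_eff, alpha=alpha),
    }


def simpleM_eff(genotypes: GenotypeDataset | np.ndarray, var_fraction: float = 0.99,
                chrom: np.ndarray | None = None) -> int:
    """Effective number of independent tests (SimpleM).

    Per chromosome, the eigenvalues of the SNP x SNP correlation matrix are
    computed (via the sample-side Gram matrix when SNPs outnumber samples)
    and the smallest k whose leading eigenvalues reach ``var_fraction`` of
    the total variance is taken; M_eff is the sum over chromosomes.
    """
    if isinstance(genotypes, GenotypeDataset):
        g_all = genotypes.genotypes.astype(float)
        chrom = genotypes.sites["chrom"].to_numpy()
    else:
        g_all = np.asarray(genotypes, dtype=float)
        if chrom is None:
            chrom = np.zeros(g_all.shape[0], dtype=int)
    if np.any(g_all == MISSING):
        raise ValueError("SimpleM requires complete genotypes")
    total = 0
    for c in pd.unique(chrom):
        g = g_all[chrom == c]
        sd = g.std(axis=1)
        g = g[sd > 0]
        if g.shape[0] == 0:
            continue
        Z = (g - g.mean(axis=1, keepdims=True)) / g.std(axis=1)[:, None]
        m, n = Z.shape
        if m <= n:
            M = Z @ Z.T / n  # correlation matrix of SNPs
            vals = np.linalg.eigvalsh(M)
        else:
            vals = np.linalg.eigvalsh(Z.T @ Z / n)  # same nonzero spectrum
        vals = np.clip(vals, 0.0, None)[::-1]
        frac = np.cumsum(vals) / m  # total variance = trace = m
        k = int(np.searchsorted(frac, var_fraction * (1 - 1e-12)) + 1)
        total += min(k, m)
    if total == 0:
        raise ValueError("no polymorphic SNPs")
    return total


def significance_threshold(m_eff: int, alpha: float = 0.05) -> float:
    """Genome-wide threshold alpha / M_eff."""
    if m_eff < 1:
        raise ValueError("M_eff must be at least 1")
    return alpha / m_eff


def genomic_inflation(pvalues: np.ndarray) -> float:
    """lambda_GC: median chi-square of the observed p-values over 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / chi2.isf(0.5, df=1))
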