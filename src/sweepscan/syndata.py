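"""Synthetic two-population genotype and phenotype data.

The generator emulates the statistical structure the downstream stages
assume, with no external data:

* population differentiation via the Balding-Nichols model — per-site
  population allele frequencies drawn Beta(p(1-F)/F, (1-p)(1-F)/F) around
  an ancestral frequency p ~ Uniform(0.05, 0.95), so Weir-Cockerham theta
  estimates the chosen F;
* a hard sweep in the focal population, generated from exactly the
  lineage-escape model the CLR scan fits (parameter recovery is therefore
  a well-posed closed loop, not a forward-simulation approximation);
* GBS-like uniform missingness;
* quantitative phenotypes y = mu + batch + sum(causal dosage * effect) +
  polygenic term (MVN with covariance proportional to the realized
  standardized GRM) + iid noise, with causal and polygenic parts scaled to
  explain stated fractions of the realized trait variance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clr
from .datatypes import GenotypeDataset, MISSING, SITE_COLUMNS

__all__ = [
    "SimConfig",
    "simulate_divergent_genotypes",
    "simulate_sweep_sites",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
    "simulate_gene_models",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the standard study design this generator emulates: a
    focal (phenotyped) population of 200 diploids contrasted with a
    50-diploid reference across three 5-Mb chromosomes of 1,500 segregating
    sites each, differentiation F = 0.2, a hard sweep of intensity 2e-5 per
    bp at the middle of chromosome 1, 5% uniform missingness, and a trait
    with a single major causal SNP at the swept locus explaining 30% of
    variance plus a 30%-heritability polygenic background over three
    batches.
    """

    n_pop1: int = 200
    n_pop2: int = 50
    n_chrom: int = 3
    chrom_length_bp: int = 5_000_000
    n_sites: int = 1_500
    fst_param: float = 0.2
    sweep_alpha: float | None = 2e-5
    sweep_position_bp: int | None = 2_500_000
    sweep_chrom_index: int = 0
    missing_rate: float = 0.05
    n_causal: int = 1
    h2_snp: float = 0.3
    h2_poly: float = 0.3
    n_batches: int = 3
    batch_effects: tuple[float, ...] | None = None
    causal_at_sweep: bool = True
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst_param < 1.0):
            raise ValueError("fst_param must be in [0, 1)")
        if self.h2_snp + self.h2_poly >= 1.0:
            raise ValueError("h2_snp + h2_poly must be < 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("n_pop1", "n_pop2", "n_chrom", "chrom_length_bp", "n_sites", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sweep_alpha is not None and self.sweep_alpha <= 0:
            raise ValueError("sweep_alpha must be positive")

    @property
    def batch_values(self) -> np.ndarray:
        if self.batch_effects is not None:
            if len(self.batch_effects) != self.n_batches:
                raise ValueError("batch_effects length must equal n_batches")
            return np.asarray(self.batch_effects, dtype=float)
        if self.n_batches == 1:
            return np.zeros(1)
        return np.linspace(-0.5, 0.5, self.n_batches)


def _site_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    pos = rng.choice(np.arange(1, length + 1), size=n, replace=False)
    pos.sort()
    return pos


def simulate_divergent_genotypes(config: SimConfig) -> GenotypeDataset:
    """Balding-Nichols genotypes for two populations (no sweep, no missingness).

    For each site an ancestral frequency p is drawn Uniform over
    ``ancestral_freq_range``; each population's frequency is Beta(p(1-F)/F,
    (1-p)(1-F)/F) (F = 0 means both use p exactly); genotypes are
    Binomial(2, population frequency).  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    F = config.fst_param
    lo, hi = config.ancestral_freq_range
    n1, n2 = config.n_pop1, config.n_pop2

    chroms, positions, genos = [], [], []
    for c in range(config.n_chrom):
        pos = _site_positions(rng, config.chrom_length_bp, config.n_sites)
        p = rng.uniform(lo, hi, size=config.n_sites)
        if F == 0.0:
            p1 = p2 = p
        else:
            shape = (1.0 - F) / F
            p1 = rng.beta(p * shape, (1 - p) * shape)
            p2 = rng.beta(p * shape, (1 - p) * shape)
        g1 = rng.binomial(2, p1[:, None], size=(config.n_sites, n1))
        g2 = rng.binomial(2, p2[:, None], size=(config.n_sites, n2))
        chroms.append(np.full(config.n_sites, f"chr{c + 1}", dtype=object))
        positions.append(pos)
        genos.append(np.hstack([g1, g2]).astype(np.int8))

    sites = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(positions),
            "ref": "A",
            "alt": "G",
            "depth": 30.0,
            "mapq": 60.0,
        }
    )[SITE_COLUMNS]
    samples = [f"P1_{i:03d}" for i in range(n1)] + [f"P2_{i:03d}" for i in range(n2)]
    populations = np.array(["pop1"] * n1 + ["pop2"] * n2, dtype=object)
    return GenotypeDataset(samples, populations, sites, np.vstack(genos))


def simulate_sweep_sites(
    sfs: clr.SFS,
    n: int,
    alpha: float,
    sweep_position_bp: float,
    site_positions: np.ndarray,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Derived counts drawn from the sweep model at each site position.

    Each site's count is sampled from the lineage-escape mixture
    distribution at its distance from ``sweep_position_bp``, conditioned on
    polymorphism.  Sites exactly at the swept position are rejected (their
    polymorphism probability is zero under the model).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    site_positions = np.asarray(site_positions)
    if site_positions.size == 0:
        return pd.DataFrame({"position": [], "count": []}).astype(int)
    d = np.abs(site_positions - sweep_position_bp)
    if np.any(d == 0):
        raise ValueError("site at distance 0 from the sweep has polymorphism probability 0")
    kern = clr._SweepKernel(sfs)
    counts = np.empty(site_positions.size, dtype=int)
    classes = np.arange(1, n)
    for i, di in enumerate(d):
        probs = clr.sweep_site_distribution(sfs, n, alpha, float(di), _kernel=kern)
        counts[i] = rng.choice(classes, p=probs)
    return pd.DataFrame({"position": site_positions, "count": counts})


def _counts_to_genotypes(
    counts: np.ndarray, n_diploid: int, rng: np.random.Generator
) -> np.ndarray:
    """Distribute each site's derived copies uniformly over 2n chromosomes."""
    out = np.empty((counts.size, n_diploid), dtype=np.int8)
    hap = np.zeros(2 * n_diploid, dtype=np.int8)
    for i, b in enumerate(counts):
        hap[:] = 0
        hap[:b] = 1
        rng.shuffle(hap)
        out[i] = hap.reshape(n_diploid, 2).sum(axis=1)
    return out


def simulate_phenotypes(
    genotypes: GenotypeDataset,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    causal_idx: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Quantitative trait with batch effect, sparse causal SNPs and polygenic term.

    Causal and polygenic components are rescaled to explain exactly
    ``h2_snp`` and ``h2_poly`` of the realized trait variance (the batch
    effect comes on top).  Genotypes must be complete; missing entries are
    mean-filled for the purpose of trait construction.  Returns the
    phenotype table (sample, trait, batch) and the causal site indices.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = genotypes.n_samples
    m = genotypes.n_sites
    if config.n_causal > m:
        raise ValueError("n_causal exceeds the number of SNPs")

    g = genotypes.genotypes.astype(float)
    obs = genotypes.genotypes != MISSING
    col_mean = np.where(obs, g, 0).sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
    g = np.where(obs, g, col_mean[:, None])

    sd = g.std(axis=1)
    poly_ok = sd > 0
    if causal_idx is None:
        causal_idx = rng.choice(np.flatnonzero(poly_ok), size=config.n_causal, replace=False)
    causal_idx = np.asarray(causal_idx, dtype=int)

    y = np.zeros(n)
    if config.h2_snp > 0 and causal_idx.size:
        effects = rng.normal(size=causal_idx.size)
        causal = effects @ g[causal_idx]
        causal = _rescale(causal, config.h2_snp)
        y += causal
    if config.h2_poly > 0:
        Z = (g[poly_ok] - g[poly_ok].mean(axis=1, keepdims=True)) / sd[poly_ok, None]
        grm = Z.T @ Z / poly_ok.sum()
        L = np.linalg.cholesky(grm + 1e-8 * np.eye(n))
        y += _rescale(L @ rng.normal(size=n), config.h2_poly)
    noise_var = 1.0 - config.h2_snp - config.h2_poly
    y += rng.normal(scale=np.sqrt(noise_var), size=n)

    batches = rng.integers(config.n_batches, size=n)
    y = y + config.batch_values[batches]
    table = pd.DataFrame(
        {
            "sample": genotypes.samples,
            "trait": y,
            "batch": [f"b{b + 1}" for b in batches],
        }
    )
    return table, causal_idx


def _rescale(x: np.ndarray, target_var: float) -> np.ndarray:
    x = x - x.mean()
    s = x.std()
    if s == 0:
        return x
    return x * np.sqrt(target_var) / s


def simulate_dataset(config: SimConfig) -> dict:
    """End-to-end synthetic study: genotypes, sweep overlay, phenotypes.

    Returns a dict with keys ``dataset`` (with missingness), ``complete``
    (pre-missingness), ``phenotypes`` (focal population only), ``truth``
    (sweep chrom/position, causal site indices and positions, config).
    """
    rng = np.random.default_rng(config.seed)
    ds = simulate_divergent_genotypes(config)

    sweep_chrom = None
    if config.sweep_alpha is not None and config.sweep_position_bp is not None:
        sweep_chrom = f"chr{config.sweep_chrom_index + 1}"
        idx1 = ds.population_index("pop1")
        n_hap = 2 * len(idx1)
        sfs = clr.background_sfs_from_dataset(ds, population="pop1")
        on_chrom = np.flatnonzero((ds.sites["chrom"] == sweep_chrom).to_numpy())
        pos = ds.sites["pos"].to_numpy()[on_chrom]
        off0 = pos != config.sweep_position_bp
        on_chrom = on_chrom[off0]
        sweep_rng = np.random.default_rng(config.seed + 7)
        tbl = simulate_sweep_sites(
            sfs, n_hap, config.sweep_alpha, config.sweep_position_bp,
            pos[off0], rng=sweep_rng,
        )
        new_g = _counts_to_genotypes(
            tbl["count"].to_numpy(), len(idx1), sweep_rng
        )
        g = ds.genotypes.copy()
        g[np.ix_(on_chrom, idx1)] = new_g
        ds = GenotypeDataset(ds.samples, ds.populations, ds.sites, g)

    focal = ds.subset_samples("pop1")
    causal_idx = None
    if config.causal_at_sweep and sweep_chrom is not None and config.n_causal >= 1:
        on = (focal.sites["chrom"] == sweep_chrom).to_numpy()
        poly = focal.genotypes.std(axis=1) > 0
        # a testable causal variant: inside the sweep but not dragged to
        # near-fixation (a near-fixed SNP has no dosage variance to test)
        freq = focal.genotypes.mean(axis=1) / 2.0
        common = np.minimum(freq, 1 - freq) >= 0.1
        cand = np.flatnonzero(on & poly & common)
        if cand.size == 0:
            cand = np.flatnonzero(on & poly)
        nearest = cand[
            np.argmin(np.abs(focal.sites["pos"].to_numpy()[cand] - config.sweep_position_bp))
        ]
        others_pool = np.flatnonzero(poly & ~np.isin(np.arange(focal.n_sites), [nearest]))
        pick_rng = np.random.default_rng(config.seed + 2)
        others = pick_rng.choice(others_pool, size=config.n_causal - 1, replace=False)
        causal_idx = np.concatenate([[nearest], others])
    phenos, causal_idx = simulate_phenotypes(
        focal, config, rng=np.random.default_rng(config.seed + 1), causal_idx=causal_idx
    )

    complete = ds
    if config.missing_rate > 0:
        miss_rng = np.random.default_rng(config.seed + 3)
        mask = miss_rng.random(ds.genotypes.shape) < config.missing_rate
        g = ds.genotypes.copy()
        g[mask] = MISSING
        ds = GenotypeDataset(ds.samples, ds.populations, ds.sites, g)

    truth = {
        "sweep_chrom": sweep_chrom,
        "sweep_position_bp": config.sweep_position_bp if sweep_chrom else None,
        "causal_idx": causal_idx,
        "causal_chrom": focal.sites["chrom"].to_numpy()[causal_idx],
        "causal_pos": focal.sites["pos"].to_numpy()[causal_idx],
        "config": config,
    }
    return {"dataset": ds, "complete": complete, "phenotypes": phenos, "truth": truth}


def simulate_gene_models(
    config: SimConfig, spacing_bp: int = 250_000, gene_len_bp: int = 20_000
) -> pd.DataFrame:
    """Regularly spaced synthetic gene models as a BED6 table (0-based)."""
    rows = []
    k = 0
    for c in range(config.n_chrom):
        for start in range(spacing_bp // 2, config.chrom_length_bp - gene_len_bp, spacing_bp):
            k += 1
            rows.append((f"chr{c + 1}", start, start + gene_len_bp, f"gene_{k}", 0, "+"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_dataset(
    dataset: GenotypeDataset,
    phenotypes: pd.DataFrame | None,
    out_prefix: str | os.PathLike,
    gene_models: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write VCF 4.2 (+ phenotype TSV + gene BED) under ``out_prefix``.

    Round-trips losslessly through :func:`sweepscan.vcf_qc.read_vcf`.
    """
    if dataset.n_sites == 0:
        raise ValueError("refusing to write an empty dataset")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": prefix.with_suffix(".vcf")}

    chrom_order = dataset.sites["chrom"].drop_duplicates().tolist()
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Float,Description="Total depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chrom_order:
            length = int(dataset.sites.loc[dataset.sites["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i in range(dataset.n_sites):
            s = dataset.sites.iloc[i]
            info_parts = []
            if np.isfinite(s["depth"]):
                info_parts.append(f"DP={s['depth']:g}")
            if np.isfinite(s["mapq"]):
                info_parts.append(f"MQ={s['mapq']:g}")
            info = ";".join(info_parts) or "."
            gts = "\t".join(gt_str[int(v)] for v in dataset.genotypes[i])
            fh.write(
                f"{s['chrom']}\t{int(s['pos'])}\t.\t{s['ref']}\t{s['alt']}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )

    if phenotypes is not None:
        paths["phenotypes"] = prefix.parent / (prefix.name + ".pheno.tsv")
        phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    if gene_models is not None:
        paths["genes"] = prefix.parent / (prefix.name + ".genes.bed")
        gene_models.to_csv(paths["genes"], sep="\t", index=False, header=False)
    pops = pd.DataFrame({"sample": dataset.samples, "population": dataset.populations})
    paths["populations"] = prefix.parent / (prefix.name + ".pops.tsv")
    pops.to_csv(paths["populations"], sep="\t", index=False)
    return paths
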