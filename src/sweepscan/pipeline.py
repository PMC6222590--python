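"""Pipeline orchestration: QC -> selection scan -> regions, and QC -> GWAS.

Both entry points run from a single :class:`RunConfig`, which either names
input files (VCF, phenotype table, gene models, population map) or embeds a
:class:`~sweepscan.syndata.SimConfig` to generate them.  Every run writes a
JSON manifest with the parameters, seed and design decisions needed to
reproduce it bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clr, fst, gwas, regions as rg, syndata, vcf_qc
from .datatypes import GenotypeDataset, regions_to_bed

__all__ = ["RunConfig", "run_scan", "run_gwas", "load_config"]

logger = logging.getLogger(__name__)

DECISIONS = [
    "imputation: per-population Binomial(2, allele frequency) draws, not haplotype-based",
    "fst: mean of per-site theta-hat within windows (average-of-ratios)",
    "clr: unfolded spectrum; alpha grid 20 log-spaced points, p_escape(nearest) 0.01..0.999",
    "regions: 98th percentile strict; merge gap < 200 kb; CASR vs union of FST tracks",
    "gwas: per-SNP REML over delta, Wald test; SimpleM summed per chromosome",
]


@dataclass
class RunConfig:
    """Inputs and knobs for a pipeline run (file-based or synthetic)."""

    vcf: str | None = None
    phenotypes: str | None = None
    gene_models: str | None = None
    population_map: str | None = None
    sim: syndata.SimConfig | None = None
    focal_population: str = "pop1"
    reference_populations: tuple[str, ...] = ("pop2",)
    scan_sample_size: int | None = 25  # diploids used for the CLR scan
    scan_max_missing: float = 0.2
    qc: vcf_qc.QcThresholds = field(default_factory=vcf_qc.QcThresholds)
    grid_bp: int = 25_000
    window_bp: int = 25_000
    quantile: float = 0.98
    gap_bp: int = 200_000
    flank_bp: int = 100_000
    hit_dist_bp: int = 1_000_000
    var_fraction: float = 0.99
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.vcf is not None
        has_sim = self.sim is not None
        if has_files == has_sim:
            raise ValueError("exactly one of vcf/... paths or sim config must be given")


def load_config(path: str) -> RunConfig:
    """Read a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "sim" in raw and raw["sim"] is not None:
        raw["sim"] = syndata.SimConfig(**raw["sim"])
    if "qc" in raw and raw["qc"] is not None:
        raw["qc"] = vcf_qc.QcThresholds(**raw["qc"])
    if "reference_populations" in raw:
        raw["reference_populations"] = tuple(raw["reference_populations"])
    return RunConfig(**raw)


def _load_inputs(config: RunConfig, outdir: Path) -> dict:
    """Materialize the dataset (and companions) from files or the simulator."""
    if config.sim is not None:
        sim = syndata.SimConfig(**{**asdict(config.sim), "seed": config.seed})
        bundle = syndata.simulate_dataset(sim)
        genes = syndata.simulate_gene_models(sim)
        return {
            "dataset": bundle["dataset"],
            "phenotypes": bundle["phenotypes"],
            "genes": genes,
            "truth": bundle["truth"],
        }
    pops = pd.read_csv(config.population_map, sep="\t")
    pop_map = dict(zip(pops["sample"], pops["population"]))
    dataset = vcf_qc.read_vcf(config.vcf, pop_map)
    phenos = (
        pd.read_csv(config.phenotypes, sep="\t") if config.phenotypes else None
    )
    if phenos is not None and phenos.empty:
        raise ValueError(f"phenotype file {config.phenotypes} has no rows")
    genes = rg.read_gene_models(config.gene_models) if config.gene_models else None
    return {"dataset": dataset, "phenotypes": phenos, "genes": genes, "truth": None}


def _manifest(config: RunConfig, outdir: Path, stage: str, extra: dict) -> None:
    def _clean(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.ndarray, tuple, list)):
            return [_clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        return obj

    payload = {
        "stage": stage,
        "seed": config.seed,
        "config": _clean(asdict(config)),
        "decisions": DECISIONS,
        **_clean(extra),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=2)


def run_scan(config: RunConfig, outdir: str | Path) -> dict:
    """Selection scan: QC -> imputation -> CLR + F_ST -> CSRs -> CASRs.

    Writes window tracks, region BEDs and a manifest under ``outdir``;
    returns the in-memory results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(config, outdir)
    dataset: GenotypeDataset = inputs["dataset"]

    thresholds = vcf_qc.QcThresholds(
        **{**asdict(config.qc), "max_missing": config.scan_max_missing}
    )
    filtered, report = vcf_qc.filter_sites(dataset, thresholds, hwe=False)
    report.to_frame().to_csv(outdir / "qc_report_scan.tsv", sep="\t", index=False)
    complete = vcf_qc.impute_missing(filtered, rng=config.seed)

    focal = complete.subset_samples(config.focal_population)
    # CLR runs on a fixed-size subsample (whole-genome panels for sweep
    # scans are typically much smaller than the phenotyped GWAS cohort)
    if config.scan_sample_size and focal.n_samples > config.scan_sample_size:
        keep = np.zeros(focal.n_samples, dtype=bool)
        keep[: config.scan_sample_size] = True
        scan_pop = GenotypeDataset(
            [s for s, k in zip(focal.samples, keep) if k],
            focal.populations[keep],
            focal.sites,
            focal.genotypes[:, keep],
        )
    else:
        scan_pop = focal
    sfs = clr.background_sfs_from_dataset(scan_pop)
    chrom_lengths = None
    if config.sim is not None:
        chrom_lengths = {
            f"chr{c + 1}": config.sim.chrom_length_bp for c in range(config.sim.n_chrom)
        }
    clr_track = clr.clr_genome_scan(
        scan_pop, sfs, grid_bp=config.grid_bp, chrom_lengths=chrom_lengths
    )
    clr_track = rg.empirical_pvalues(clr_track)
    clr_track.to_csv(outdir / "clr_windows.tsv", sep="\t", index=False)
    clr_csrs = rg.merge_windows(
        rg.significant_windows(clr_track, config.quantile), config.gap_bp, source="CLR_CSR"
    )

    fst_tracks, fst_csr_tracks = {}, []
    for ref in config.reference_populations:
        table = fst.fst_site_table(complete, config.focal_population, ref)
        track = rg.empirical_pvalues(fst.fst_window_average(table, config.window_bp))
        track.to_csv(outdir / f"fst_windows_{ref}.tsv", sep="\t", index=False)
        fst_tracks[ref] = track
        fst_csr_tracks.append(
            rg.merge_windows(
                rg.significant_windows(track, config.quantile), config.gap_bp,
                source="FST_CSR",
            )
        )

    casrs = rg.intersect_regions(
        clr_csrs,
        fst_csr_tracks[0],
        fst_csr_tracks[1] if len(fst_csr_tracks) > 1 else None,
    )
    if inputs["genes"] is not None:
        casrs = rg.annotate_regions(casrs, inputs["genes"], flank_bp=config.flank_bp)

    regions_to_bed(clr_csrs).to_csv(outdir / "clr_csr.bed", sep="\t", index=False, header=False)
    for ref, track in zip(config.reference_populations, fst_csr_tracks):
        regions_to_bed(track).to_csv(
            outdir / f"fst_csr_{ref}.bed", sep="\t", index=False, header=False
        )
    bed = regions_to_bed(casrs)
    bed.to_csv(outdir / "casr.bed", sep="\t", index=False, header=False)

    _manifest(
        config, outdir, "scan",
        {
            "n_sites_input": dataset.n_sites,
            "n_sites_qc": filtered.n_sites,
            "n_windows_clr": len(clr_track),
            "n_casr": len(casrs),
        },
    )
    return {
        "dataset": complete,
        "clr_track": clr_track,
        "fst_tracks": fst_tracks,
        "clr_csrs": clr_csrs,
        "fst_csrs": fst_csr_tracks,
        "casrs": casrs,
        "truth": inputs["truth"],
        "qc_report": report,
    }


def run_gwas(
    config: RunConfig, outdir: str | Path, casrs: list | None = None
) -> dict:
    """GWAS branch: QC (+HWE) -> imputation -> LOCO LMM -> SimpleM -> overlap."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(config, outdir)
    dataset: GenotypeDataset = inputs["dataset"]
    phenos = inputs["phenotypes"]
    if phenos is None or phenos.empty:
        raise ValueError("GWAS requires a non-empty phenotype table")

    filtered, report = vcf_qc.filter_sites(dataset, config.qc, hwe=True)
    report.to_frame().to_csv(outdir / "qc_report_gwas.tsv", sep="\t", index=False)
    complete = vcf_qc.impute_missing(filtered, rng=config.seed)
    focal = complete.subset_samples(config.focal_population)

    extra = set(focal.samples) - set(phenos["sample"])
    if extra:
        raise ValueError(f"samples without phenotypes: {sorted(extra)[:5]}")
    result = gwas.loco_scan(
        focal, phenos, var_fraction=config.var_fraction, alpha=config.alpha
    )
    assoc = result["assoc"]
    assoc.to_csv(outdir / "assoc.tsv", sep="\t", index=False)

    ok = assoc["wald_p"].notna()
    manhattan = assoc.loc[ok, ["chrom", "pos"]].assign(
        neglog10_p=-np.log10(assoc.loc[ok, "wald_p"])
    )
    manhattan.to_csv(outdir / "manhattan.tsv", sep="\t", index=False)
    p_sorted = np.sort(assoc.loc[ok, "wald_p"].to_numpy())
    qq = pd.DataFrame(
        {
            "expected": -np.log10((np.arange(1, p_sorted.size + 1) - 0.5) / p_sorted.size),
            "observed": -np.log10(p_sorted),
        }
    )
    qq.to_csv(outdir / "qq.tsv", sep="\t", index=False)

    hits = assoc.loc[ok & (assoc["wald_p"] <= result["threshold"])]
    overlap = None
    if casrs:
        annotated = rg.annotate_regions(
            casrs,
            inputs["genes"]
            if inputs["genes"] is not None
            else pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"]),
            assoc=hits,
            flank_bp=config.flank_bp,
            hit_dist_bp=config.hit_dist_bp,
        )
        rows = [
            (r.chrom, r.start, r.end, hit, dist)
            for r in annotated
            for hit, dist in r.nearby_hits
        ]
        overlap = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "snp", "distance_bp"]
        )
        overlap.to_csv(outdir / "overlap.tsv", sep="\t", index=False)

    _manifest(
        config, outdir, "gwas",
        {
            "m_eff": result["m_eff"],
            "threshold": result["threshold"],
            "n_hits": int(len(hits)),
        },
    )
    return {
        "assoc": assoc,
        "m_eff": result["m_eff"],
        "threshold": result["threshold"],
        "hits": hits,
        "overlap": overlap,
        "truth": inputs["truth"],
    }
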