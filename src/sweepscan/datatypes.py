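"""Core in-memory containers shared across the pipeline.

Genotypes are stored as an alt-allele dosage matrix (sites x samples) with
values {0, 1, 2} and ``MISSING`` (-1) for uncalled genotypes.  Site metadata
travels in a pandas DataFrame so that filtering, windowing and I/O can lean
on ordinary DataFrame operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for an uncalled genotype in the dosage matrix.
MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "mapq"]


@dataclass
class GenotypeDataset:
    """Biallelic SNP genotypes for one or more labelled populations.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    populations
        Population label per sample, aligned with ``samples``.
    sites
        DataFrame with columns ``chrom, pos, ref, alt, depth, mapq``;
        ``pos`` is 1-based and strictly increasing within each chromosome.
        ``depth``/``mapq`` hold per-site (INFO-level) values, NaN if unknown.
    genotypes
        ``(n_sites, n_samples)`` int8 array of alt-allele dosages with
        :data:`MISSING` for uncalled entries.
    """

    samples: list[str]
    populations: np.ndarray
    sites: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if len(self.populations) != len(self.samples):
            raise ValueError("populations and samples differ in length")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,missing}")
        for _, pos in self.sites.groupby("chrom", sort=False)["pos"]:
            if not np.all(np.diff(pos.to_numpy()) > 0):
                raise ValueError("positions must strictly increase within chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def population_index(self, label: str) -> np.ndarray:
        """Column indices of the samples belonging to ``label``."""
        idx = np.flatnonzero(self.populations == label)
        if idx.size == 0:
            raise KeyError(f"no samples in population {label!r}")
        return idx

    def subset_samples(self, labels: list[str] | str) -> "GenotypeDataset":
        """New dataset restricted to samples of the given population(s)."""
        if isinstance(labels, str):
            labels = [labels]
        keep = np.flatnonzero(np.isin(self.populations, labels))
        return GenotypeDataset(
            samples=[self.samples[i] for i in keep],
            populations=self.populations[keep],
            sites=self.sites.reset_index(drop=True),
            genotypes=self.genotypes[:, keep],
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            samples=list(self.samples),
            populations=self.populations.copy(),
            sites=self.sites.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[mask],
        )


def window_track(
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    score: np.ndarray,
    **extra: np.ndarray,
) -> pd.DataFrame:
    """Assemble a per-window score track (half-open bp coordinates)."""
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": end, "score": score})
    for k, v in extra.items():
        df[k] = v
    return df


@dataclass
class GenomicRegion:
    """Half-open genomic interval with provenance and annotations."""

    chrom: str
    start: int
    end: int
    source: str  # CLR_CSR, FST_CSR or CASR
    member_windows: list[int] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    nearby_hits: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"degenerate region {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def with_(self, **kw) -> "GenomicRegion":
        return replace(self, **kw)


def regions_to_bed(regions: list[GenomicRegion]) -> pd.DataFrame:
    """BED6 table (0-based half-open) from a region list."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "name": [r.source for r in regions],
            "score": [0] * len(regions),
            "strand": ["."] * len(regions),
        }
    )
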