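"""Empirical p-values, percentile significance, region merging and overlap.

Window scores from either statistic are ranked genome-wide; the empirical
p-value of a window is its descending rank divided by the number of scored
windows (ties share the maximum rank).  Windows above the 98th percentile
are merged into candidate selection regions (CSRs) when separated by less
than 200 kb, and CLR CSRs overlapping F_ST CSRs become candidate
artificial-selection regions (CASRs).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import GenomicRegion

__all__ = [
    "empirical_pvalues",
    "significant_windows",
    "merge_windows",
    "intersect_regions",
    "annotate_regions",
    "read_gene_models",
]

logger = logging.getLogger(__name__)


def empirical_pvalues(track: pd.DataFrame) -> pd.DataFrame:
    """Attach genome-wide rank-based empirical p-values to a window track.

    p_i = rank_i / N with rank 1 for the largest score; tied scores share
    the maximum rank of their group, so an all-tied track gets p = 1.
    """
    if track.empty:
        raise ValueError("no scored windows")
    ranks = rankdata(-track["score"].to_numpy(), method="max")
    return track.assign(empirical_p=ranks / len(track))


def significant_windows(track: pd.DataFrame, quantile: float = 0.98) -> pd.DataFrame:
    """Windows whose score exceeds the empirical ``quantile`` cutoff.

    The cutoff is the ceil(q*N)-th smallest score; selection is strict, so
    with all-distinct scores exactly N - ceil(q*N) windows are returned.
    """
    scores = track["score"].to_numpy()
    N = scores.size
    if N == 0:
        raise ValueError("no scored windows")
    k = int(np.ceil(quantile * N))
    cutoff = np.sort(scores)[k - 1]
    return track.loc[scores > cutoff]


def merge_windows(selected: pd.DataFrame, gap_bp: int = 200_000, source: str = "CSR") -> list[GenomicRegion]:
    """Merge selected windows into CSRs when gaps are below ``gap_bp``.

    Consecutive windows on one chromosome join the same region when
    ``next.start - prev.end < gap_bp``; the region spans from the first
    window's start to the last window's end.
    """
    regions: list[GenomicRegion] = []
    if selected.empty:
        return regions
    sel = selected.sort_values(["chrom", "start"])
    for chrom, sub in sel.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = sub.index.to_numpy()
        cur_s, cur_e, members = int(starts[0]), int(ends[0]), [int(idx[0])]
        for s, e, i in zip(starts[1:], ends[1:], idx[1:]):
            if s - cur_e < gap_bp:
                cur_e = max(cur_e, int(e))
                members.append(int(i))
            else:
                regions.append(GenomicRegion(str(chrom), cur_s, cur_e, source, members))
                cur_s, cur_e, members = int(s), int(e), [int(i)]
        regions.append(GenomicRegion(str(chrom), cur_s, cur_e, source, members))
    return regions


def intersect_regions(
    clr_csrs: list[GenomicRegion],
    fst_csrs_a: list[GenomicRegion],
    fst_csrs_b: list[GenomicRegion] | None = None,
    require_both: bool = False,
) -> list[GenomicRegion]:
    """CASRs: intersections of CLR CSRs with the F_ST CSR track(s).

    A CLR CSR contributes a CASR wherever it overlaps (>= 1 bp) the union
    of the F_ST tracks; with ``require_both`` the overlap must be present
    in each track separately.  Emitted intervals are the intersections,
    with the matching track(s) recorded in ``genes``-free provenance via
    ``source``.
    """
    tracks = [("fst_a", fst_csrs_a)]
    if fst_csrs_b is not None:
        tracks.append(("fst_b", fst_csrs_b))

    out: list[GenomicRegion] = []
    for region in clr_csrs:
        pieces: dict[str, list[tuple[int, int]]] = {}
        for name, track in tracks:
            for other in track:
                if region.overlaps(other):
                    pieces.setdefault(name, []).append(
                        (max(region.start, other.start), min(region.end, other.end))
                    )
        if not pieces:
            continue
        if require_both and len(pieces) < len(tracks):
            continue
        ivs = sorted(iv for lst in pieces.values() for iv in lst)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        provenance = "+".join(sorted(pieces))
        for s, e in merged:
            out.append(
                GenomicRegion(region.chrom, s, e, "CASR", list(region.member_windows))
            )
            out[-1].nearby_hits = []
            out[-1].genes = []
            out[-1].provenance = provenance  # type: ignore[attr-defined]
    return out


def read_gene_models(path: str) -> pd.DataFrame:
    """Gene models from BED6 (0-based) or GFF3 (1-based, 'gene' features)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                name = attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}"))
                rows.append((f[0], int(f[3]) - 1, int(f[4]), name, 0, f[6]))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )


def annotate_regions(
    regions: list[GenomicRegion],
    gene_models: pd.DataFrame,
    assoc: pd.DataFrame | None = None,
    flank_bp: int = 100_000,
    hit_dist_bp: int = 1_000_000,
) -> list[GenomicRegion]:
    """Attach overlapping genes and nearby association hits to each region.

    Genes overlapping region +/- ``flank_bp`` (a 200-kb window around the
    signature by default) are listed.  When an association table with
    columns ``chrom, pos, wald_p`` and attribute-selected significant rows
    is given, each hit is assigned to its nearest region and flagged
    nearby when the distance is <= ``hit_dist_bp``.
    """
    known = set(gene_models["chrom"].unique())
    out = []
    for r in regions:
        if r.chrom not in known:
            logger.warning("chromosome %s absent from gene models; genes skipped", r.chrom)
            genes: list[str] = []
        else:
            sub = gene_models[gene_models["chrom"] == r.chrom]
            hit = (sub["start"] < r.end + flank_bp) & (sub["end"] > r.start - flank_bp)
            genes = sub.loc[hit, "name"].tolist()
        out.append(r.with_(genes=genes, nearby_hits=[]))

    if assoc is not None and len(out):
        for _, snp in assoc.iterrows():
            best, best_d = None, None
            for r in out:
                if r.chrom != snp["chrom"]:
                    continue
                pos0 = int(snp["pos"]) - 1  # to 0-based
                d = 0 if r.start <= pos0 < r.end else min(
                    abs(pos0 - r.start), abs(pos0 - (r.end - 1))
                )
                if best_d is None or d < best_d:
                    best, best_d = r, d
            if best is not None and best_d is not None and best_d <= hit_dist_bp:
                best.nearby_hits.append((f"{snp['chrom']}:{int(snp['pos'])}", int(best_d)))
    return out
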