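"""Candidate selected-region calling from smoothed composite scores.

A region is a run of top-1% SNPs whose consecutive members are no more
than 1 Mb apart, kept when it holds at least five such SNPs and (in strict
mode) at least one top-0.1% SNP. Runs closer than 1 Mb are merged, regions
are ranked by their best smoothed score, and genes overlapping the region
plus a +-0.5 Mb flank are attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionCall",
    "top_fraction_threshold",
    "call_clusters",
    "merge_clusters",
    "annotate_regions",
    "call_regions",
    "read_genes",
    "regions_to_frame",
]


@dataclass
class RegionCall:
    """A called region spanning its member SNPs (1-based inclusive bp)."""

    chrom: str
    start_bp: int
    end_bp: int
    snp_indices: np.ndarray  # panel indices of member top-1% SNPs
    snp_ids: list
    n_top1: int
    n_top01: int
    top_css_value: float
    cluster_rank: int = 0
    genes: list = field(default_factory=list)

    @property
    def n_top_snps(self) -> int:
        return self.n_top1


def top_fraction_threshold(
    scores: np.ndarray, fraction: float, valid: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Cutoff and member indices for the top ``fraction`` of valid scores.

    k = ceil(fraction * n_valid); every score tied with the k-th highest is
    included, so the member set may exceed k.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    if valid is None:
        valid = ~np.isnan(scores)
    idx = np.flatnonzero(valid & ~np.isnan(scores))
    if idx.size == 0:
        raise ValueError("no valid scores")
    k = math.ceil(fraction * idx.size)
    order = np.sort(scores[idx])[::-1]
    cutoff = float(order[k - 1])
    members = idx[scores[idx] >= cutoff]
    return cutoff, members


def call_clusters(
    snp_map: pd.DataFrame,
    top1: np.ndarray,
    top01: np.ndarray,
    window_bp: int = 1_000_000,
    min_top1: int = 5,
    require_top01: bool = True,
    scores: np.ndarray | None = None,
) -> list[RegionCall]:
    """Group top-1% SNPs into clusters and apply the membership rules.

    A cluster is a maximal same-chromosome run of top-1% SNPs whose
    consecutive members are <= ``window_bp`` apart. It is kept when it has
    at least ``min_top1`` members and, if ``require_top01`` (strict mode),
    contains at least one top-0.1% SNP.
    """
    top1 = np.sort(np.asarray(top1))
    top01_set = set(np.asarray(top01).tolist())
    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_bp"].to_numpy()
    clusters: list[RegionCall] = []
    for chrom in pd.unique(chroms[top1]) if top1.size else []:
        members = top1[chroms[top1] == chrom]
        if members.size == 0:
            continue
        gaps = np.diff(pos[members])
        breaks = np.flatnonzero(gaps > window_bp)
        for run in np.split(members, breaks + 1):
            n01 = sum(int(i) in top01_set for i in run)
            if run.size < min_top1:
                continue
            if require_top01 and n01 == 0:
                continue
            top_val = float(np.nanmax(scores[run])) if scores is not None else np.nan
            clusters.append(
                RegionCall(
                    chrom=str(chrom),
                    start_bp=int(pos[run[0]]),
                    end_bp=int(pos[run[-1]]),
                    snp_indices=run,
                    snp_ids=snp_map["id"].to_numpy()[run].tolist(),
                    n_top1=int(run.size),
                    n_top01=n01,
                    top_css_value=top_val,
                )
            )
    return clusters


def merge_clusters(
    clusters: list[RegionCall], max_gap_bp: int = 1_000_000
) -> list[RegionCall]:
    """Merge same-chromosome clusters separated by < ``max_gap_bp`` (strict),
    then rank regions 1..k descending by top_css_value."""
    merged: list[RegionCall] = []
    by_chrom: dict[str, list[RegionCall]] = {}
    for c in sorted(clusters, key=lambda c: (c.chrom, c.start_bp)):
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom_clusters in by_chrom.values():
        current = chrom_clusters[0]
        for nxt in chrom_clusters[1:]:
            if nxt.start_bp - current.end_bp < max_gap_bp:
                current = RegionCall(
                    chrom=current.chrom,
                    start_bp=current.start_bp,
                    end_bp=max(current.end_bp, nxt.end_bp),
                    snp_indices=np.concatenate([current.snp_indices, nxt.snp_indices]),
                    snp_ids=current.snp_ids + nxt.snp_ids,
                    n_top1=current.n_top1 + nxt.n_top1,
                    n_top01=current.n_top01 + nxt.n_top01,
                    top_css_value=float(np.nanmax([current.top_css_value, nxt.top_css_value])),
                )
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    order = np.argsort([-r.top_css_value for r in merged], kind="stable")
    ranked = [merged[i] for i in order]
    for rank, region in enumerate(ranked, start=1):
        region.cluster_rank = rank
    return ranked


def annotate_regions(
    regions: list[RegionCall], genes: pd.DataFrame, flank_bp: int = 500_000
) -> list[RegionCall]:
    """Attach genes whose interval shares >=1 bp with region +- flank.

    ``genes`` needs columns (gene, chrom, start_bp, end_bp), 1-based
    inclusive coordinates.
    """
    for region in regions:
        lo = region.start_bp - flank_bp
        hi = region.end_bp + flank_bp
        hits = genes[
            (genes["chrom"].astype(str) == region.chrom)
            & (genes["start_bp"] <= hi)
            & (genes["end_bp"] >= lo)
        ]
        region.genes = hits["gene"].tolist()
    return regions


def call_regions(
    snp_map: pd.DataFrame,
    scores: np.ndarray,
    valid: np.ndarray | None = None,
    top_fraction: float = 0.01,
    sig_fraction: float = 0.001,
    window_bp: int = 1_000_000,
    min_top1: int = 5,
    mode: str = "strict",
    genes: pd.DataFrame | None = None,
    flank_bp: int = 500_000,
) -> list[RegionCall]:
    """Threshold -> cluster -> merge -> rank -> (optionally) annotate."""
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    _, top1 = top_fraction_threshold(scores, top_fraction, valid)
    _, top01 = top_fraction_threshold(scores, sig_fraction, valid)
    clusters = call_clusters(
        snp_map, top1, top01,
        window_bp=window_bp, min_top1=min_top1,
        require_top01=(mode == "strict"), scores=scores,
    )
    regions = merge_clusters(clusters, max_gap_bp=window_bp)
    if genes is not None:
        regions = annotate_regions(regions, genes, flank_bp=flank_bp)
    return regions


def read_genes(path, format: str | None = None) -> pd.DataFrame:
    """Gene annotation from BED (0-based half-open) or GFF3 (gene features).

    Returns columns (gene, chrom, start_bp, end_bp) with 1-based inclusive
    coordinates, sorted.
    """
    path = str(path)
    if format is None:
        format = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    if format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
            dtype={0: str},
        )
        out = pd.DataFrame(
            {"gene": df["name"], "chrom": df["chrom"].astype(str),
             "start_bp": df["start"].astype(int) + 1, "end_bp": df["end"].astype(int)}
        )
    elif format == "gff3":
        import pyranges as pr

        gr = pr.read_gff3(path).df
        gr = gr[gr["Feature"] == "gene"]
        name_col = "Name" if "Name" in gr.columns else "ID"
        out = pd.DataFrame(
            {"gene": gr[name_col].astype(str), "chrom": gr["Chromosome"].astype(str),
             "start_bp": gr["Start"].astype(int) + 1, "end_bp": gr["End"].astype(int)}
        )
    else:
        raise ValueError(f"unknown gene annotation format {format!r}")
    return out.sort_values(["chrom", "start_bp"]).reset_index(drop=True)


def regions_to_frame(regions: list[RegionCall]) -> pd.DataFrame:
    """Region calls as a table mirroring the scan's summary schema."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start_bp": [r.start_bp for r in regions],
            "end_bp": [r.end_bp for r in regions],
            "n_top1": [r.n_top1 for r in regions],
            "n_top01": [r.n_top01 for r in regions],
            "top_css_value": [r.top_css_value for r in regions],
            "cluster_rank": [r.cluster_rank for r in regions],
            "genes": [";".join(r.genes) for r in regions],
            "snp_ids": [";".join(map(str, r.snp_ids)) for r in regions],
        }
    )
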