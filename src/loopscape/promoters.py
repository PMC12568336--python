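"""Promoter interval construction and promoter-anchored interaction subsetting.

A gene's promoter is either the union of accessible-chromatin (ATAC) peaks
overlapping its TSS or, failing that, a strand-aware window (2000 bp
upstream, 500 bp downstream by default).  Significant-interaction records
carry bin midpoints; each side is re-inflated to its bin before the overlap
test against the promoter set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ConfigError, GenomeSpec
from .intervals import build_trees, overlap_names


@dataclass(frozen=True)
class PromoterInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gene: str
    strand: str
    source: str  # "atac_peak" or "window"


def build_promoters(
    tss: pd.DataFrame,
    atac_peaks: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 500,
    genome: GenomeSpec | None = None,
) -> list[PromoterInterval]:
    """One promoter interval per TSS record.

    If the TSS base overlaps >= 1 peak, the promoter is the union (envelope)
    of the overlapping peaks' coordinates; otherwise it is the strand-aware
    window [TSS - upstream, TSS + downstream) on + and
    [TSS - downstream, TSS + upstream) on -, clipped to the chromosome.
    Records with missing strand are treated as + with a warning; a TSS past
    the chromosome end is rejected.
    """
    peak_trees = build_trees(atac_peaks)
    peak_lookup = {
        (row.chrom, row.name_): (row.start, row.end)
        for row in atac_peaks.rename(columns={"name": "name_"}).itertuples()
    }
    out: list[PromoterInterval] = []
    n_unstranded = 0
    for row in tss.itertuples():
        pos = int(row.start)  # TSS base, 0-based
        chrom = row.chrom
        if genome is not None:
            if chrom not in genome.lengths:
                raise ConfigError(f"TSS on unknown chromosome {chrom!r}")
            if pos >= genome.lengths[chrom]:
                raise ConfigError(f"TSS for {row.name} at {pos} beyond end of {chrom}")
        strand = row.strand
        if strand not in ("+", "-"):
            n_unstranded += 1
            strand = "+"
        hits = overlap_names(peak_trees, chrom, pos, pos + 1)
        if hits:
            coords = [peak_lookup[(chrom, h)] for h in hits]
            start = min(s for s, _ in coords)
            end = max(e for _, e in coords)
            source = "atac_peak"
        else:
            if strand == "+":
                start, end = pos - upstream, pos + downstream
            else:
                start, end = pos - downstream, pos + upstream
            source = "window"
        start = max(0, start)
        if genome is not None:
            end = min(end, genome.lengths[chrom])
        out.append(PromoterInterval(chrom, start, end, row.name, strand, source))
    if n_unstranded:
        warnings.warn(f"{n_unstranded} TSS record(s) without strand treated as +")
    return out


def promoters_to_bed(promoters: list[PromoterInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.chrom, p.start, p.end, p.gene, 0, p.strand) for p in promoters],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def subset_promoter_interactions(
    interactions: pd.DataFrame,
    promoters: list[PromoterInterval],
    resolution: int,
) -> pd.DataFrame:
    """Keep interactions where >= 1 side's bin overlaps >= 1 promoter.

    Side intervals are [midpoint - resolution/2, midpoint + resolution/2)
    (half-open, >= 1 bp overlap rule).  Adds ``genes1``/``genes2`` columns
    with comma-joined symbols of the promoters each side overlaps.
    """
    if interactions.empty:
        out = interactions.copy()
        out["genes1"] = pd.Series(dtype=str)
        out["genes2"] = pd.Series(dtype=str)
        return out
    if resolution <= 0:
        raise ConfigError("resolution must be positive")
    # midpoints must sit on this resolution's bin-center grid
    if ((interactions["mid1"] % resolution) != resolution // 2).any():
        raise ConfigError("interaction midpoints do not match the requested resolution")
    trees = build_trees(promoters_to_bed(promoters)) if promoters else {}
    half = resolution // 2
    genes1, genes2, keep = [], [], []
    for row in interactions.itertuples():
        g1 = overlap_names(trees, row.chrom, int(row.mid1) - half, int(row.mid1) + half)
        g2 = overlap_names(trees, row.chrom, int(row.mid2) - half, int(row.mid2) + half)
        genes1.append(",".join(g1))
        genes2.append(",".join(g2))
        keep.append(bool(g1 or g2))
    out = interactions.copy()
    out["genes1"] = genes1
    out["genes2"] = genes2
    return out[np.array(keep, dtype=bool)].reset_index(drop=True)


def filter_by_genes(promoter_interactions: pd.DataFrame, gene_list) -> pd.DataFrame:
    """Retain records annotated with >= 1 gene from the list (exact match)."""
    genes = set(gene_list)

    def _hit(cell: str) -> bool:
        return any(g in genes for g in cell.split(",") if g)

    if promoter_interactions.empty:
        return promoter_interactions.copy()
    m = promoter_interactions["genes1"].map(_hit) | promoter_interactions["genes2"].map(_hit)
    return promoter_interactions[m].reset_index(drop=True)
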