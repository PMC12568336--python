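"""Interval-overlap helpers over BED-style half-open coordinates."""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree


def build_trees(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees from a BED frame (0-based half-open).

    Zero-length intervals are inflated by nothing — they cannot overlap
    anything under the half-open rule and are skipped.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in zip(bed["chrom"], bed["start"], bed["end"], bed["name"]):
        if end <= start:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end), name)
    return trees


def overlap_names(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> list[str]:
    """Names of intervals overlapping [start, end) by >= 1 bp, sorted."""
    if chrom not in trees or end <= start:
        return []
    hits = trees[chrom].overlap(start, end)
    return sorted({h.data for h in hits})


def any_overlap(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> bool:
    if chrom not in trees or end <= start:
        return False
    return bool(trees[chrom].overlaps(start, end))
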