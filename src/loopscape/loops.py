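"""Focal chromatin-loop calling and anchor annotation.

The caller scores every cis pixel against four local-neighborhood expected
values (donut, lower-left, horizontal, vertical — the classic dot-calling
neighborhoods), computed on the distance-normalized map so the steep P(s)
decay does not masquerade as enrichment.  A pixel is a candidate when it is
a local maximum exceeding every neighborhood expectation; its p-value is
the upper-tail Poisson probability of the raw count against the most
conservative neighborhood, with Benjamini-Hochberg FDR across candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter
from scipy.signal import oaconvolve
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .genome import ConfigError
from .intervals import build_trees, overlap_names
from .matrixops import ContactMatrix

DISTANCE_CATEGORIES = ("<200 kb", "200-400 kb", "400-600 kb", "600-800 kb", "800 kb-1 Mb", ">1 Mb")


@dataclass
class LoopCall:
    """A dot call: two anchor bins with enrichment statistics."""

    chrom: str
    bin1: int
    bin2: int
    resolution: int
    observed: float
    expected_donut: float
    expected_lowerleft: float
    expected_horizontal: float
    expected_vertical: float
    p: float
    q: float

    @property
    def start1(self) -> int:
        return self.bin1 * self.resolution

    @property
    def end1(self) -> int:
        return (self.bin1 + 1) * self.resolution

    @property
    def start2(self) -> int:
        return self.bin2 * self.resolution

    @property
    def end2(self) -> int:
        return (self.bin2 + 1) * self.resolution

    @property
    def distance(self) -> int:
        """Midpoint-to-midpoint separation in bp."""
        return (self.bin2 - self.bin1) * self.resolution


def _neighborhood_kernels(outer: int, inner: int) -> dict[str, np.ndarray]:
    size = 2 * outer + 1
    di, dj = np.meshgrid(np.arange(-outer, outer + 1), np.arange(-outer, outer + 1), indexing="ij")
    cheb = np.maximum(np.abs(di), np.abs(dj))
    donut = (cheb > inner) & (cheb <= outer)
    lowerleft = (di >= 1) & (di <= outer) & (dj <= -1) & (dj >= -outer) & (cheb > inner)
    horizontal = (np.abs(di) <= 1) & (np.abs(dj) > inner) & (np.abs(dj) <= outer)
    vertical = (np.abs(dj) <= 1) & (np.abs(di) > inner) & (np.abs(di) <= outer)
    out = {}
    for name, m in (
        ("donut", donut),
        ("lowerleft", lowerleft),
        ("horizontal", horizontal),
        ("vertical", vertical),
    ):
        k = m.astype(np.float64)
        # correlation via convolution needs the kernel flipped
        out[name] = k[::-1, ::-1]
    assert all(k.shape == (size, size) for k in out.values())
    return out


def call_loops(
    matrix: ContactMatrix,
    q_threshold: float = 0.1,
    donut_outer: int = 5,
    donut_inner: int = 2,
    min_distance_bins: int = 2,
    max_distance: int = 10_000_000,
    merge_bins: int = 2,
    min_observed: int = 4,
) -> list[LoopCall]:
    """Dot calls on one balanced cis matrix at its native resolution.

    Only pixel distances in [``min_distance_bins`` bins, ``max_distance``]
    are tested.  Calls within ``merge_bins`` (Chebyshev) collapse onto the
    strongest (smallest p, then largest count).  ``min_observed`` floors
    the raw count of a reported dot (the FDR still runs over all nonzero
    candidates): in ultra-sparse maps nearly every nonzero pixel is a
    "local maximum" whose identical tiny discrete p-value would otherwise
    pass the FDR wholesale.
    """
    if matrix.weights is None:
        raise ConfigError("call_loops needs a balanced matrix (for the bin mask)")
    if not (0 < q_threshold < 1):
        raise ConfigError("q_threshold must be in (0, 1)")
    n = matrix.n_bins
    res = matrix.resolution
    if n <= 2 * donut_outer + 1:
        return []
    raw = matrix.dense()
    mask = matrix.mask if matrix.mask is not None else np.zeros(n, bool)
    valid = ~mask
    valid2d = valid[:, None] & valid[None, :]

    # distance-normalized map: raw / per-diagonal mean over valid pixels
    i_idx, j_idx = np.indices((n, n))
    d_idx = np.abs(j_idx - i_idx)
    sums = np.bincount(d_idx[valid2d], weights=raw[valid2d], minlength=n)
    cnts = np.bincount(d_idx[valid2d], minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_d = np.where(cnts > 0, sums / cnts, 0.0)
    E = e_d[d_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where((E > 0) & valid2d, raw / np.where(E > 0, E, 1.0), 0.0)
    Rvalid = ((E > 0) & valid2d).astype(np.float64)

    kernels = _neighborhood_kernels(donut_outer, donut_inner)
    exp_maps = {}
    for name, k in kernels.items():
        num = oaconvolve(R * Rvalid, k, mode="same")
        den = oaconvolve(Rvalid, k, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_r = np.where(den > 0.5, num / np.maximum(den, 1e-12), np.nan)
        exp_maps[name] = mean_r * E

    local_max = R >= maximum_filter(R, size=3, mode="constant", cval=0.0) - 1e-12

    max_d_bins = max_distance // res
    dist_ok = (d_idx >= min_distance_bins) & (d_idx <= max_d_bins)
    upper = j_idx > i_idx
    cand = upper & dist_ok & valid2d & (raw > 0) & local_max
    for name in exp_maps:
        cand &= np.isfinite(exp_maps[name]) & (raw > exp_maps[name])
    ci, cj = np.nonzero(cand)
    if ci.size == 0:
        return []
    # the global distance expected floors lambda: a sparse local neighborhood
    # must not yield a spuriously tiny Poisson rate
    lam = np.maximum.reduce([exp_maps[name][ci, cj] for name in exp_maps] + [E[ci, cj]])
    obs = raw[ci, cj]
    p = poisson.sf(obs - 1, np.maximum(lam, 1e-300))
    q = multipletests(p, method="fdr_bh")[1]
    # FDR runs over every candidate; the count floor only gates reporting
    keep = (q < q_threshold) & (obs >= min_observed)
    calls = [
        LoopCall(
            matrix.chrom1,
            int(a),
            int(b),
            res,
            float(raw[a, b]),
            float(exp_maps["donut"][a, b]),
            float(exp_maps["lowerleft"][a, b]),
            float(exp_maps["horizontal"][a, b]),
            float(exp_maps["vertical"][a, b]),
            float(pp),
            float(qq),
        )
        for a, b, pp, qq in zip(ci[keep], cj[keep], p[keep], q[keep])
    ]
    # merge nearby calls onto the strongest
    calls.sort(key=lambda c: (c.p, -c.observed, c.bin1, c.bin2))
    kept: list[LoopCall] = []
    for c in calls:
        if any(abs(c.bin1 - k.bin1) <= merge_bins and abs(c.bin2 - k.bin2) <= merge_bins for k in kept):
            continue
        kept.append(c)
    kept.sort(key=lambda c: (c.bin1, c.bin2))
    return kept


def loops_to_bedpe(loops: list[LoopCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.chrom, c.start1, c.end1, c.chrom, c.start2, c.end2,
                f"loop_{k}", c.observed, c.p, c.q, c.distance,
            )
            for k, c in enumerate(loops)
        ],
        columns=[
            "chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "observed", "p", "q", "distance",
        ],
    )


def distance_histogram(loops: list[LoopCall]) -> pd.DataFrame:
    """Six-category loop-distance histogram (counts and fractions).

    Categories are lower-inclusive / upper-exclusive except the last, which
    is strictly > 1 Mb (so exactly 1 Mb falls in "800 kb-1 Mb").
    """
    edges = [0, 200_000, 400_000, 600_000, 800_000]
    counts = [0] * 6
    for c in loops:
        d = c.distance
        if d > 1_000_000:
            counts[5] += 1
        else:
            k = sum(d >= e for e in edges) - 1
            counts[k] += 1
    total = len(loops)
    fracs = [ct / total if total else 0.0 for ct in counts]
    return pd.DataFrame({"category": DISTANCE_CATEGORIES, "count": counts, "fraction": fracs})


@dataclass
class AnchorAnnotation:
    chrom: str
    start: int
    end: int
    accessible: bool
    marks: frozenset[str]  # subset of the supplied mark names
    class_label: str  # me1_only / me3_only / both / neither ('' if inaccessible)


def _unique_anchors(loops: list[LoopCall]) -> list[tuple[str, int, int]]:
    seen = set()
    out = []
    for c in loops:
        for s, e in ((c.start1, c.end1), (c.start2, c.end2)):
            key = (c.chrom, s, e)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def annotate_anchors(
    loops: list[LoopCall],
    atac: pd.DataFrame,
    mark_beds: dict[str, pd.DataFrame],
) -> tuple[list[AnchorAnnotation], pd.DataFrame]:
    """Classify unique loop anchors by accessibility and chromatin marks.

    An anchor is accessible iff it overlaps >= 1 ATAC interval by >= 1 bp
    (half-open); each mark is flagged the same way.  The summary reports,
    over accessible anchors only, per-mark positives and the four-way
    H3K4me1/H3K4me3 partition, with percentages at one decimal.
    """
    atac_trees = build_trees(atac)
    mark_trees = {name: build_trees(bed) for name, bed in mark_beds.items()}
    annos: list[AnchorAnnotation] = []
    for chrom, start, end in _unique_anchors(loops):
        accessible = bool(overlap_names(atac_trees, chrom, start, end))
        marks = frozenset(
            name for name, trees in mark_trees.items() if overlap_names(trees, chrom, start, end)
        )
        if accessible:
            me1 = "H3K4me1" in marks
            me3 = "H3K4me3" in marks
            label = "both" if (me1 and me3) else "me1_only" if me1 else "me3_only" if me3 else "neither"
        else:
            label = ""
        annos.append(AnchorAnnotation(chrom, start, end, accessible, marks, label))

    acc = [a for a in annos if a.accessible]
    n_acc = len(acc)

    def _pct(k: int) -> float:
        return round(100.0 * k / n_acc, 1) if n_acc else 0.0

    rows = [("accessible_anchors", n_acc, 100.0 if n_acc else 0.0)]
    for mark in mark_beds:
        k = sum(1 for a in acc if mark in a.marks)
        rows.append((f"{mark}_positive", k, _pct(k)))
    for label in ("me1_only", "me3_only", "both", "neither"):
        k = sum(1 for a in acc if a.class_label == label)
        rows.append((f"class_{label}", k, _pct(k)))
    summary = pd.DataFrame(rows, columns=["group", "count", "percent_of_accessible"])
    return annos, summary


def anchor_class_percentages(counts: dict[str, int], n_accessible: int) -> dict[str, float]:
    """Percentages (one decimal) of accessible anchors per mark/class count."""
    if n_accessible <= 0:
        raise ConfigError("n_accessible must be positive")
    return {k: round(100.0 * v / n_accessible, 1) for k, v in counts.items()}


def overlap_variants(
    loops: list[LoopCall],
    deletions: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Structural deletions intersecting loop anchors (>= 1 bp, half-open).

    Returns a per-loop table with the deduplicated list of deletion names
    hitting either anchor, and the reverse map deletion -> loop indices.
    """
    trees = build_trees(deletions)
    rows = []
    by_del: dict[str, list[int]] = {}
    for idx, c in enumerate(loops):
        hits1 = overlap_names(trees, c.chrom, c.start1, c.end1)
        hits2 = overlap_names(trees, c.chrom, c.start2, c.end2)
        names = sorted(set(hits1) | set(hits2))
        for nm in names:
            by_del.setdefault(nm, []).append(idx)
        rows.append(
            (idx, c.chrom, c.start1, c.end1, c.start2, c.end2, ",".join(names), len(names))
        )
    table = pd.DataFrame(
        rows,
        columns=["loop", "chrom", "start1", "end1", "start2", "end2", "deletions", "n_deletions"],
    )
    return table, by_del
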