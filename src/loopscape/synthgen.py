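"""Synthetic Micro-C fixture generator.

Emulates the statistical structure of a ligation-pair dataset well enough to
exercise every downstream stage: power-law decay of cis contact probability,
a planted A/B compartment checkerboard, planted TAD blocks, focal planted
loops, a trans-contact background, exact PCR duplicates, unmapped records
(4DN sentinel chromosome ``!``), and a sub-1 kb same-strand fraction that
mimics self-ligation artifacts.  Alongside the pair stream it returns the
ground truth (compartment labels, boundary positions, loop list) used by the
recovery tests.

Default rates mirror the accounting of the real cochlear library this
package was designed around: ~12% unmapped, ~53% PCR duplicates among mapped
reads, ~30% trans among unique mapped pairs, and a P(s) decay exponent of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ConfigError, GenomeSpec

PAIR_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
UNMAPPED_CHROM = "!"


@dataclass(frozen=True)
class PlantedLoop:
    """A focal enrichment between two loci on one chromosome.

    ``multiplier`` scales the planted pixel's count relative to the
    distance-matched local background (must be > 1 to plant anything).
    """

    chrom: str
    pos1: int
    pos2: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 1:
            raise ConfigError("loop multiplier must be > 1")
        if self.pos1 <= 0 or self.pos2 <= 0:
            raise ConfigError("loop anchor positions must be positive")


@dataclass(frozen=True)
class SimParams:
    """Generator knobs.  All probabilities are per-record rates."""

    n_pairs: int
    alpha: float = 1.0
    trans_fraction: float = 0.30
    duplicate_rate: float = 0.53
    unmapped_rate: float = 0.12
    short_fraction: float = 0.05
    compartment_size: int = 2_000_000
    compartment_strength: float = 1.0
    tad_boundaries: dict[str, tuple[int, ...]] = field(default_factory=dict)
    tad_strength: float = 1.0
    loops: tuple[PlantedLoop, ...] = ()
    bin_size: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if self.alpha <= 0:
            raise ConfigError("alpha must be > 0")
        if not (0.0 <= self.trans_fraction <= 1.0):
            raise ConfigError("trans_fraction must be in [0, 1]")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ConfigError("duplicate_rate must be in [0, 1)")
        if not (0.0 <= self.unmapped_rate < 1.0):
            raise ConfigError("unmapped_rate must be in [0, 1)")
        if not (0.0 <= self.short_fraction <= 1.0):
            raise ConfigError("short_fraction must be in [0, 1]")
        if self.compartment_strength < 1.0:
            raise ConfigError("compartment_strength must be >= 1")
        if self.tad_strength < 1.0:
            raise ConfigError("tad_strength must be >= 1")
        if self.compartment_size <= 0 or self.bin_size <= 0:
            raise ConfigError("compartment_size and bin_size must be positive")


@dataclass
class SyntheticTruth:
    """Planted structure, on the generator's ``bin_size`` grid."""

    compartment_labels: dict[str, np.ndarray]  # per analysis chrom, 'A'/'B' per bin
    boundaries: dict[str, tuple[int, ...]]  # boundary positions (bp) per chrom
    loops: tuple[PlantedLoop, ...]  # sorted by (chrom order, pos1, pos2)
    params: SimParams

    def loop_bins(self, chrom: str) -> list[tuple[int, int, float]]:
        res = self.params.bin_size
        out = []
        for lp in self.loops:
            if lp.chrom == chrom:
                b1, b2 = sorted(((lp.pos1 - 1) // res, (lp.pos2 - 1) // res))
                out.append((b1, b2, lp.multiplier))
        return out


@dataclass
class AnnotationSet:
    """BED-style fixtures matched to a SyntheticTruth.

    Every frame has columns (chrom, start, end, name, score, strand) with
    0-based half-open coordinates.
    """

    atac: pd.DataFrame
    h3k4me1: pd.DataFrame
    h3k4me3: pd.DataFrame
    h3k27ac: pd.DataFrame
    ctcf: pd.DataFrame
    tss: pd.DataFrame
    deletions: pd.DataFrame


def generate_genome(
    n_chroms: int,
    length_range: tuple[int, int],
    seed: int,
    min_length: int = 100_000,
    with_blacklist: bool = False,
) -> GenomeSpec:
    """Random genome of ``n_chroms`` autosomes, deterministic for a seed.

    ``with_blacklist`` appends a short ``chrM`` flagged as blacklisted, to
    exercise the parser's drop path.
    """
    if n_chroms < 1:
        raise ConfigError("n_chroms must be >= 1")
    lo, hi = length_range
    if lo < min_length:
        raise ConfigError(f"minimum chromosome length {lo} is below the floor {min_length}")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    lengths = {n: int(rng.integers(lo, hi + 1)) for n in names}
    blacklist: frozenset[str] = frozenset()
    if with_blacklist:
        names.append("chrM")
        lengths["chrM"] = 16_299
        blacklist = frozenset({"chrM"})
    return GenomeSpec(tuple(names), lengths, blacklist)


def _power_law_cdf(length: int, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Discretized cis-distance law at 1 kb granularity on [1 kb, length)."""
    s = np.arange(1000, max(length, 2001), 1000, dtype=np.float64)
    pmf = s ** (-alpha)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    return s.astype(np.int64), cdf


def _comp_label_of_pos(pos: np.ndarray, block: int) -> np.ndarray:
    """0/1 checkerboard label of 1-based positions."""
    return ((pos - 1) // block) % 2


def _within_same_tad(pos1, pos2, boundaries: np.ndarray) -> np.ndarray:
    """True where no boundary falls strictly between the two positions."""
    if boundaries.size == 0:
        return np.ones(len(pos1), dtype=bool)
    i1 = np.searchsorted(boundaries, pos1, side="right")
    i2 = np.searchsorted(boundaries, pos2, side="right")
    return i1 == i2


def _sample_cis(genome, params, n, rng):
    """Cis pair coordinates honouring decay, compartments and TADs."""
    names = list(genome.names)
    lens = np.array([genome.lengths[n] for n in names], dtype=np.float64)
    # usable chromosomes for cis: long enough for >=1 kb separation
    usable = lens >= 2000
    probs = np.where(usable, lens, 0.0)
    probs /= probs.sum()
    cdfs = {nm: _power_law_cdf(genome.lengths[nm], params.alpha) for i, nm in enumerate(names) if usable[i]}
    bnd = {nm: np.asarray(sorted(params.tad_boundaries.get(nm, ())), dtype=np.int64) for nm in names}

    w_max = params.compartment_strength * params.tad_strength
    out_c: list[np.ndarray] = []
    out_p1: list[np.ndarray] = []
    out_p2: list[np.ndarray] = []
    got = 0
    while got < n:
        chunk = int((n - got) * w_max * 1.3) + 16
        chunk = min(chunk, 4_000_000)
        ci = rng.choice(len(names), size=chunk, p=probs)
        L = lens[ci].astype(np.int64)
        s = np.empty(chunk, dtype=np.int64)
        for k in np.unique(ci):
            nm = names[k]
            grid, cdf = cdfs[nm]
            m = ci == k
            s[m] = grid[np.searchsorted(cdf, rng.random(m.sum()))]
        s = np.minimum(s, L - 1)
        p1 = (rng.random(chunk) * (L - s)).astype(np.int64) + 1
        p2 = p1 + s
        # acceptance weights: compartment checkerboard x TAD block
        w = np.ones(chunk)
        if params.compartment_strength > 1.0:
            same = _comp_label_of_pos(p1, params.compartment_size) == _comp_label_of_pos(
                p2, params.compartment_size
            )
            w *= np.where(same, params.compartment_strength, 1.0)
        if params.tad_strength > 1.0:
            same_tad = np.empty(chunk, dtype=bool)
            for k in np.unique(ci):
                nm = names[k]
                m = ci == k
                same_tad[m] = _within_same_tad(p1[m], p2[m], bnd[nm])
            w *= np.where(same_tad, params.tad_strength, 1.0)
        keep = rng.random(chunk) < w / w_max
        out_c.append(ci[keep])
        out_p1.append(p1[keep])
        out_p2.append(p2[keep])
        got += int(keep.sum())
    ci = np.concatenate(out_c)[:n]
    p1 = np.concatenate(out_p1)[:n]
    p2 = np.concatenate(out_p2)[:n]
    return np.array(names, dtype=object)[ci], p1, p2


def _plant_loops(genome, params, chrom, p1, p2, rng):
    """Replace a few background cis pairs with focal loop-pixel pairs.

    The extra mass per planted pixel is calibrated against the empirical
    distance-matched local background (pixels on the same off-diagonal within
    +-20 bins), so the pixel's final count is ~multiplier x background.
    """
    res = params.bin_size
    extra_c: list[str] = []
    extra_p1: list[int] = []
    extra_p2: list[int] = []
    for lp in params.loops:
        if lp.chrom not in genome.names:
            raise ConfigError(f"loop anchor on unknown chromosome {lp.chrom!r}")
        L = genome.lengths[lp.chrom]
        if lp.pos1 > L or lp.pos2 > L:
            raise ConfigError(f"loop anchor outside chromosome {lp.chrom!r}")
        lo, hi = sorted((lp.pos1, lp.pos2))
        b1, b2 = (lo - 1) // res, (hi - 1) // res
        d = b2 - b1
        if d == 0:
            raise ConfigError("loop anchors fall in the same bin")
        m = chrom == lp.chrom
        bb1 = (p1[m] - 1) // res
        bb2 = (p2[m] - 1) // res
        n_bins = genome.n_bins(lp.chrom, res)
        # background at the same bin distance, near the loop
        cand = np.arange(max(0, b1 - 20), min(n_bins - d, b1 + 21))
        cand = cand[cand != b1]
        on_diag = bb2 - bb1 == d
        diag_starts = bb1[on_diag]
        bg_counts = np.array([(diag_starts == i).sum() for i in cand], dtype=np.float64)
        background = bg_counts.mean() if bg_counts.size else 0.0
        n_extra = int(np.round((lp.multiplier - 1.0) * max(background, 1.0)))
        if n_extra <= 0:
            continue
        lo1 = b1 * res + 1
        hi1 = min((b1 + 1) * res, L)
        lo2 = b2 * res + 1
        hi2 = min((b2 + 1) * res, L)
        extra_c.extend([lp.chrom] * n_extra)
        extra_p1.extend((rng.integers(lo1, hi1 + 1, n_extra)).tolist())
        extra_p2.extend((rng.integers(lo2, hi2 + 1, n_extra)).tolist())
    n_extra = len(extra_c)
    if n_extra == 0:
        return chrom, p1, p2
    # carve the extras out of the background so the cis count is preserved
    if n_extra >= len(chrom):
        raise ConfigError("planted loop mass exceeds the cis pair budget")
    drop = rng.choice(len(chrom), size=n_extra, replace=False)
    keep = np.ones(len(chrom), dtype=bool)
    keep[drop] = False
    chrom = np.concatenate([chrom[keep], np.array(extra_c, dtype=object)])
    p1 = np.concatenate([p1[keep], np.array(extra_p1, dtype=np.int64)])
    p2 = np.concatenate([p2[keep], np.array(extra_p2, dtype=np.int64)])
    return chrom, p1, p2


def _make_truth(genome: GenomeSpec, params: SimParams) -> SyntheticTruth:
    labels: dict[str, np.ndarray] = {}
    res = params.bin_size
    for nm in genome.analysis_names:
        nb = genome.n_bins(nm, res)
        starts = np.arange(nb, dtype=np.int64) * res + 1
        lab01 = _comp_label_of_pos(starts, params.compartment_size)
        labels[nm] = np.where(lab01 == 0, "A", "B")
    bounds = {
        nm: tuple(sorted(params.tad_boundaries.get(nm, ())))
        for nm in genome.analysis_names
        if params.tad_boundaries.get(nm)
    }
    order = {nm: i for i, nm in enumerate(genome.names)}
    loops = tuple(sorted(params.loops, key=lambda lp: (order[lp.chrom], min(lp.pos1, lp.pos2), max(lp.pos1, lp.pos2))))
    return SyntheticTruth(labels, bounds, loops, params)


def simulate_pairs(genome: GenomeSpec, params: SimParams) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw ``params.n_pairs`` ligation-pair records plus the planted truth.

    Record layout follows the 4DN .pairs convention (read id, two sides with
    strands); sides are emitted in random order so the parser's
    upper-triangle normalization is exercised.  Deterministic for a seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_pairs
    truth = _make_truth(genome, params)

    n_multi = len(genome.names) > 1
    if params.trans_fraction > 0 and not n_multi:
        raise ConfigError("trans_fraction > 0 requires at least two chromosomes")

    # one categorical role draw per record, so each empirical rate is a plain
    # binomial proportion: duplicates/total, unmapped/total, trans/mapped-unique
    if params.duplicate_rate + params.unmapped_rate >= 1.0:
        raise ConfigError("duplicate_rate + unmapped_rate must be < 1")
    r = rng.random(n)
    is_dup = r < params.duplicate_rate
    is_dup[0] = False  # first record has nothing to duplicate
    is_unmapped = (~is_dup) & (r < params.duplicate_rate + params.unmapped_rate)
    n_orig = int((~is_dup).sum())
    n_mapped = n_orig - int(is_unmapped.sum())
    t = rng.random(n_mapped) < params.trans_fraction
    n_trans = int(t.sum())
    n_cis = n_mapped - n_trans

    # cis originals
    if n_cis > 0:
        n_short = int(np.round(params.short_fraction * n_cis))
        n_long = n_cis - n_short
        c_chrom, c_p1, c_p2 = _sample_cis(genome, params, n_long, rng) if n_long else (
            np.array([], dtype=object), np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        c_chrom, c_p1, c_p2 = _plant_loops(genome, params, c_chrom, c_p1, c_p2, rng)
        c_s1 = np.where(rng.random(len(c_chrom)) < 0.5, "+", "-").astype(object)
        c_s2 = np.where(rng.random(len(c_chrom)) < 0.5, "+", "-").astype(object)
        if n_short:
            names = list(genome.names)
            lens = np.array([genome.lengths[nm] for nm in names], dtype=np.float64)
            pr = lens / lens.sum()
            ci = rng.choice(len(names), size=n_short, p=pr)
            L = lens[ci].astype(np.int64)
            s = rng.integers(50, 1000, n_short)
            s = np.minimum(s, L - 1)
            sp1 = (rng.random(n_short) * (L - s)).astype(np.int64) + 1
            sp2 = sp1 + s
            sstr = np.where(rng.random(n_short) < 0.5, "+", "-").astype(object)
            c_chrom = np.concatenate([c_chrom, np.array(names, dtype=object)[ci]])
            c_p1 = np.concatenate([c_p1, sp1])
            c_p2 = np.concatenate([c_p2, sp2])
            c_s1 = np.concatenate([c_s1, sstr])
            c_s2 = np.concatenate([c_s2, sstr])  # same strand: self-ligation-like
    else:
        c_chrom = np.array([], dtype=object)
        c_p1 = c_p2 = np.array([], dtype=np.int64)
        c_s1 = c_s2 = np.array([], dtype=object)

    # trans originals
    if n_trans > 0:
        names = list(genome.names)
        lens = np.array([genome.lengths[nm] for nm in names], dtype=np.float64)
        pr = lens / lens.sum()
        ca = rng.choice(len(names), size=n_trans, p=pr)
        cb = rng.choice(len(names), size=n_trans, p=pr)
        clash = ca == cb
        while clash.any():
            cb[clash] = rng.choice(len(names), size=int(clash.sum()), p=pr)
            clash = ca == cb
        t_p1 = (rng.random(n_trans) * lens[ca]).astype(np.int64) + 1
        t_p2 = (rng.random(n_trans) * lens[cb]).astype(np.int64) + 1
        t_c1 = np.array(names, dtype=object)[ca]
        t_c2 = np.array(names, dtype=object)[cb]
        t_s1 = np.where(rng.random(n_trans) < 0.5, "+", "-").astype(object)
        t_s2 = np.where(rng.random(n_trans) < 0.5, "+", "-").astype(object)
    else:
        t_c1 = t_c2 = np.array([], dtype=object)
        t_p1 = t_p2 = np.array([], dtype=np.int64)
        t_s1 = t_s2 = np.array([], dtype=object)

    # assemble originals: mapped cis, mapped trans, unmapped
    n_unmapped = n_orig - n_mapped
    chrom1 = np.concatenate([c_chrom, t_c1, np.full(n_unmapped, UNMAPPED_CHROM, dtype=object)])
    chrom2 = np.concatenate([c_chrom, t_c2, np.full(n_unmapped, UNMAPPED_CHROM, dtype=object)])
    pos1 = np.concatenate([c_p1, t_p1, np.zeros(n_unmapped, dtype=np.int64)])
    pos2 = np.concatenate([c_p2, t_p2, np.zeros(n_unmapped, dtype=np.int64)])
    strand1 = np.concatenate([c_s1, t_s1, np.full(n_unmapped, "+", dtype=object)])
    strand2 = np.concatenate([c_s2, t_s2, np.full(n_unmapped, "+", dtype=object)])

    # random side order for mapped records (parser re-normalizes)
    n_map_emitted = len(chrom1) - n_unmapped
    flip = rng.random(len(chrom1)) < 0.5
    flip[n_map_emitted:] = False
    chrom1[flip], chrom2[flip] = chrom2[flip].copy(), chrom1[flip].copy()
    pos1[flip], pos2[flip] = pos2[flip].copy(), pos1[flip].copy()
    strand1[flip], strand2[flip] = strand2[flip].copy(), strand1[flip].copy()

    perm = rng.permutation(len(chrom1))
    chrom1, chrom2 = chrom1[perm], chrom2[perm]
    pos1, pos2 = pos1[perm], pos2[perm]
    strand1, strand2 = strand1[perm], strand2[perm]

    orig = pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(chrom1))],
            "chrom1": chrom1,
            "pos1": pos1,
            "chrom2": chrom2,
            "pos2": pos2,
            "strand1": strand1,
            "strand2": strand2,
        }
    )

    # duplicates: verbatim re-emissions of mapped originals
    n_dup = n - len(orig)
    mapped_idx = np.flatnonzero((orig["chrom1"] != UNMAPPED_CHROM) & (orig["chrom2"] != UNMAPPED_CHROM))
    frames = [orig]
    if n_dup > 0:
        if mapped_idx.size == 0:
            raise ConfigError("cannot emit duplicates: no mapped originals")
        src = rng.choice(mapped_idx, size=n_dup, replace=True)
        dup = orig.iloc[src].copy().reset_index(drop=True)
        dup["read_id"] = [f"d{i}" for i in range(n_dup)]
        frames.append(dup)
    pairs = pd.concat(frames, ignore_index=True)
    pairs = pairs.iloc[rng.permutation(len(pairs))].reset_index(drop=True)
    return pairs[PAIR_COLUMNS], truth


def _bed_frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def generate_annotations(
    genome: GenomeSpec,
    truth: SyntheticTruth,
    seed: int,
    anchor_peak_fraction: float = 1.0,
    h3k4me1_fraction: float = 0.5,
    h3k4me3_fraction: float = 0.3,
    n_background_peaks: int = 40,
    deletion_over_loops: tuple[int, ...] = (),
    n_extra_tss: int = 20,
) -> AnnotationSet:
    """Peak/TSS/deletion BED fixtures matched to the planted truth.

    A fraction of planted loop anchors receive overlapping ATAC peaks (and,
    among those, H3K4me1/H3K4me3 peaks); CTCF peaks sit on planted TAD
    boundaries; background peaks avoid all anchors so a fraction of 0 means
    no anchor is covered.  ``deletion_over_loops`` lists loop indices (into
    ``truth.loops``) whose second anchor is covered by a deletion interval.
    """
    rng = np.random.default_rng(seed)
    res = truth.params.bin_size
    # unique anchor intervals (0-based half-open bins), in loop order
    anchors: list[tuple[str, int, int]] = []
    seen = set()
    for lp in truth.loops:
        for pos in sorted((lp.pos1, lp.pos2)):
            b = (pos - 1) // res
            key = (lp.chrom, b)
            if key not in seen:
                seen.add(key)
                anchors.append((lp.chrom, b * res, min((b + 1) * res, genome.lengths[lp.chrom])))

    n_anchor = len(anchors)
    n_cov = int(np.round(anchor_peak_fraction * n_anchor))
    covered = list(rng.permutation(n_anchor)[:n_cov]) if n_anchor else []

    atac_rows, me1_rows, me3_rows = [], [], []
    for j, ai in enumerate(sorted(covered)):
        chrom, a_start, a_end = anchors[ai]
        mid = (a_start + a_end) // 2
        atac_rows.append((chrom, max(0, mid - 300), mid + 300, f"atac_anchor_{ai}", 0, "."))
        if rng.random() < h3k4me1_fraction:
            me1_rows.append((chrom, max(0, mid - 500), mid + 500, f"me1_anchor_{ai}", 0, "."))
        if rng.random() < h3k4me3_fraction:
            me3_rows.append((chrom, max(0, mid - 400), mid + 400, f"me3_anchor_{ai}", 0, "."))

    def _background(prefix: str, width: int, n: int) -> list[tuple]:
        rows = []
        anchor_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in anchors:
            anchor_by_chrom.setdefault(chrom, []).append((s, e))
        names = list(genome.analysis_names)
        lens = np.array([genome.lengths[nm] for nm in names], dtype=np.float64)
        pr = lens / lens.sum()
        made = 0
        while made < n:
            nm = names[int(rng.choice(len(names), p=pr))]
            start = int(rng.integers(0, max(1, genome.lengths[nm] - width)))
            end = start + width
            if any(start < ae and a_s < end for a_s, ae in anchor_by_chrom.get(nm, [])):
                continue
            rows.append((nm, start, end, f"{prefix}_{made}", 0, "."))
            made += 1
        return rows

    atac_rows += _background("atac_bg", 600, n_background_peaks)
    me1_rows += _background("me1_bg", 1000, n_background_peaks // 2)
    me3_rows += _background("me3_bg", 800, n_background_peaks // 2)
    k27_rows = _background("k27_bg", 800, n_background_peaks)

    ctcf_rows = []
    for chrom, bps in truth.boundaries.items():
        for i, bp in enumerate(bps):
            ctcf_rows.append((chrom, max(0, bp - 200), bp + 200, f"ctcf_bnd_{chrom}_{i}", 0, "."))
    ctcf_rows += _background("ctcf_bg", 400, n_background_peaks // 2)

    tss_rows = []
    for ai, (chrom, a_start, a_end) in enumerate(anchors):
        pos = (a_start + a_end) // 2
        strand = "+" if ai % 2 == 0 else "-"
        tss_rows.append((chrom, pos, pos + 1, f"GENE{ai}", 0, strand))
    for j in range(n_extra_tss):
        names = list(genome.analysis_names)
        nm = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(5000, genome.lengths[nm] - 5000))
        tss_rows.append((nm, pos, pos + 1, f"BGGENE{j}", 0, "+" if j % 2 else "-"))

    del_rows = []
    for k, li in enumerate(deletion_over_loops):
        lp = truth.loops[li]
        pos = max(lp.pos1, lp.pos2)
        b = (pos - 1) // res
        start = max(0, b * res - 5000)
        end = min(genome.lengths[lp.chrom], (b + 1) * res + 5000)
        del_rows.append((lp.chrom, start, end, f"del_loop_{li}", 0, "."))

    return AnnotationSet(
        atac=_bed_frame(atac_rows),
        h3k4me1=_bed_frame(me1_rows),
        h3k4me3=_bed_frame(me3_rows),
        h3k27ac=_bed_frame(k27_rows),
        ctcf=_bed_frame(ctcf_rows),
        tss=_bed_frame(tss_rows),
        deletions=_bed_frame(del_rows),
    )
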