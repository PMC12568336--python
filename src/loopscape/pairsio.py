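"""Pair parsing, chimeric filtering, deduplication, classification, QC.

The processing order mirrors a ligation-junction QC pipeline: parse and
normalize record sides, keep chimeric (candidate long-range) products, drop
PCR duplicates, then classify each surviving pair as trans or by cis
distance.  ``summarize`` renders the per-stage accounting with the same row
layout and proportion bases as a read-accounting table (percentages of
total read pairs for the mapping/dedup rows, of no-dup pairs for the
interaction-class rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome import ConfigError, GenomeSpec
from .synthgen import PAIR_COLUMNS, UNMAPPED_CHROM

VALID_CATEGORIES = ("unmapped", "duplicate", "trans", "cis_lt_1kb", "cis_1kb_10kb", "cis_ge_10kb")


class SummaryValidationError(ValueError):
    """Raised when summary counts violate one of the accounting identities."""


@dataclass(frozen=True)
class PairRecord:
    """One ligation junction: two mapped-or-not genomic sides with strands."""

    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    mapped: bool = True
    duplicate: bool = False


@dataclass
class ParseStats:
    n_input: int = 0
    n_kept: int = 0
    n_unmapped: int = 0
    n_dropped_blacklist: int = 0
    n_rejected_unknown_chrom: int = 0
    n_rejected_out_of_bounds: int = 0
    malformed: list[tuple[int, str]] = field(default_factory=list)


def _lines_to_frame(lines, stats: ParseStats) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) < 7:
            stats.malformed.append((lineno, "fewer than 7 columns"))
            continue
        rid, c1, p1, c2, p2, s1, s2 = parts[:7]
        try:
            p1, p2 = int(p1), int(p2)
        except ValueError:
            stats.malformed.append((lineno, "non-integer position"))
            continue
        if s1 not in "+-" or s2 not in "+-":
            stats.malformed.append((lineno, "bad strand"))
            continue
        rows.append((rid, c1, p1, c2, p2, s1, s2))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def parse_pairs(source, genome: GenomeSpec) -> tuple[pd.DataFrame, ParseStats]:
    """Parse and normalize pair records.

    ``source`` may be a DataFrame in the generator's layout, a path to a
    4DN-style .pairs text file, or an iterable of lines.  Returns the kept
    records (sides swapped into upper-triangle genome order, ``mapped``
    column added) and per-reason rejection counts.  Malformed lines are
    collected as (line number, reason) rather than aborting the parse.
    """
    stats = ParseStats()
    if isinstance(source, pd.DataFrame):
        df = source[PAIR_COLUMNS].copy()
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            df = _lines_to_frame(fh, stats)
    else:
        df = _lines_to_frame(source, stats)
    stats.n_input = len(df) + len(stats.malformed)

    unmapped = (df["chrom1"] == UNMAPPED_CHROM) | (df["chrom2"] == UNMAPPED_CHROM)
    known = set(genome.names) | {UNMAPPED_CHROM}
    bad_chrom = ~(df["chrom1"].isin(known) & df["chrom2"].isin(known))
    stats.n_rejected_unknown_chrom = int(bad_chrom.sum())
    df = df[~bad_chrom]
    unmapped = unmapped[~bad_chrom]

    # bounds check on mapped sides
    len1 = df["chrom1"].map(lambda c: genome.lengths.get(c, np.iinfo(np.int64).max))
    len2 = df["chrom2"].map(lambda c: genome.lengths.get(c, np.iinfo(np.int64).max))
    oob = (~unmapped) & ((df["pos1"] < 1) | (df["pos2"] < 1) | (df["pos1"] > len1) | (df["pos2"] > len2))
    stats.n_rejected_out_of_bounds = int(oob.sum())
    df = df[~oob]
    unmapped = unmapped[~oob]

    blacklisted = (~unmapped) & (df["chrom1"].isin(genome.blacklist) | df["chrom2"].isin(genome.blacklist))
    stats.n_dropped_blacklist = int(blacklisted.sum())
    df = df[~blacklisted].copy()
    unmapped = unmapped[~blacklisted]

    # upper-triangle side order for mapped records
    order = {nm: i for i, nm in enumerate(genome.names)}
    o1 = df["chrom1"].map(order).fillna(-1).to_numpy()
    o2 = df["chrom2"].map(order).fillna(-1).to_numpy()
    swap = (~unmapped.to_numpy()) & ((o1 > o2) | ((o1 == o2) & (df["pos1"].to_numpy() > df["pos2"].to_numpy())))
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        va, vb = df[a].to_numpy().copy(), df[b].to_numpy().copy()
        df[a] = np.where(swap, vb, va)
        df[b] = np.where(swap, va, vb)
    df["pos1"] = df["pos1"].astype(np.int64)
    df["pos2"] = df["pos2"].astype(np.int64)
    df["mapped"] = ~unmapped.to_numpy()
    stats.n_kept = len(df)
    stats.n_unmapped = int((~df["mapped"]).sum())
    return df.reset_index(drop=True), stats


def is_chimeric_frame(df: pd.DataFrame, distance_threshold: int = 2000) -> np.ndarray:
    """Vectorized chimeric flag; requires every record mapped on both sides.

    Chimeric (a candidate true ligation junction) iff the sides are on
    different chromosomes, the orientation is atypical (anything other than
    inward-facing convergent: + on the leftmost side, - on the rightmost),
    or the separation strictly exceeds the distance threshold.
    """
    if "mapped" in df.columns and not df["mapped"].all():
        raise ValueError("is_chimeric is undefined for unmapped records")
    diff_chrom = (df["chrom1"] != df["chrom2"]).to_numpy()
    p1 = df["pos1"].to_numpy()
    p2 = df["pos2"].to_numpy()
    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()
    # normalize orientation by position within the pair (sides may be unsorted)
    left_first = p1 <= p2
    sl = np.where(left_first, s1, s2)
    sr = np.where(left_first, s2, s1)
    atypical = ~((sl == "+") & (sr == "-"))
    far = np.abs(p2 - p1) > distance_threshold
    return diff_chrom | atypical | far


def is_chimeric(record: PairRecord, distance_threshold: int = 2000) -> bool:
    if not record.mapped:
        raise ValueError("is_chimeric is undefined for unmapped records")
    df = pd.DataFrame(
        [
            {
                "chrom1": record.chrom1,
                "pos1": record.pos1,
                "strand1": record.strand1,
                "chrom2": record.chrom2,
                "pos2": record.pos2,
                "strand2": record.strand2,
            }
        ]
    )
    return bool(is_chimeric_frame(df, distance_threshold)[0])


def filter_chimeric(df: pd.DataFrame, distance_threshold: int = 2000) -> tuple[pd.DataFrame, int]:
    """Keep unmapped records plus mapped records flagged chimeric.

    Returns the filtered frame and the number of non-chimeric mapped records
    removed (self-ligation / undigested products).
    """
    mapped = df["mapped"].to_numpy() if "mapped" in df.columns else np.ones(len(df), bool)
    chim = np.zeros(len(df), dtype=bool)
    if mapped.any():
        chim[mapped] = is_chimeric_frame(df[mapped], distance_threshold)
    keep = ~mapped | chim
    return df[keep].reset_index(drop=True), int((~keep).sum())


DEDUP_KEY = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
SORT_KEY = ["chrom1", "pos1", "chrom2", "pos2"]


def sort_pairs(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(SORT_KEY, kind="stable").reset_index(drop=True)


def deduplicate(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Flag exact PCR duplicates among mapped records.

    Records must arrive sorted by (chrom1, pos1, chrom2, pos2).  Within each
    group sharing the full 6-tuple of coordinates and strands, exactly one
    record stays unflagged.  Unmapped records are never duplicates.
    """
    order = df.sort_values(SORT_KEY, kind="stable").index.to_numpy()
    if not np.array_equal(order, np.arange(len(df))):
        raise ValueError("deduplicate requires input sorted by (chrom1, pos1, chrom2, pos2)")
    out = df.copy()
    mapped = out["mapped"] if "mapped" in out.columns else pd.Series(True, index=out.index)
    dup = out.duplicated(subset=DEDUP_KEY, keep="first") & mapped
    out["duplicate"] = dup.to_numpy()
    return out, int(dup.sum())


def classify(df: pd.DataFrame) -> pd.DataFrame:
    """Assign each record exactly one category and a validity flag.

    Cis strata (distance = \\|pos2 - pos1\\|): <1 kb; [1 kb, 10 kb); >=10 kb.
    Valid = (trans or cis >=1 kb) and neither unmapped nor duplicate.
    """
    out = df.copy()
    mapped = out["mapped"].to_numpy() if "mapped" in out.columns else np.ones(len(out), bool)
    dup = out["duplicate"].to_numpy() if "duplicate" in out.columns else np.zeros(len(out), bool)
    dist = np.abs(out["pos2"].to_numpy() - out["pos1"].to_numpy())
    trans = (out["chrom1"] != out["chrom2"]).to_numpy()
    cat = np.where(dist < 1000, "cis_lt_1kb", np.where(dist < 10000, "cis_1kb_10kb", "cis_ge_10kb"))
    cat = np.where(trans, "trans", cat)
    cat = np.where(dup, "duplicate", cat)
    cat = np.where(~mapped, "unmapped", cat)
    out["category"] = cat
    out["valid"] = np.isin(cat, ("trans", "cis_1kb_10kb", "cis_ge_10kb"))
    return out


@dataclass
class SummaryReport:
    """Table-style read accounting with explicit proportion bases."""

    counts: dict[str, int]
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


_ROWS = [
    ("Total Read Pairs", "total", "total"),
    ("Unmapped Read Pairs", "unmapped", "total"),
    ("Mapped Read Pairs", "mapped", "total"),
    ("PCR Dup Read Pairs", "duplicate", "total"),
    ("No-Dup Read Pairs", "nodup", "total"),
    ("No-Dup Cis Read Pairs", "cis", "nodup"),
    ("No-Dup Trans Read Pairs", "trans", "nodup"),
    ("No-Dup Valid Read Pairs (cis >= 1 kb + trans)", "valid", "nodup"),
    ("No-Dup Cis Read Pairs < 1 kb", "cis_lt_1kb", "nodup"),
    ("No-Dup Cis Read Pairs >= 1 kb", "cis_ge_1kb", "nodup"),
    ("No-Dup Cis Read Pairs >= 10 kb", "cis_ge_10kb", "nodup"),
]


def counts_from_classified(df: pd.DataFrame) -> dict[str, int]:
    cat = df["category"]
    total = len(df)
    unmapped = int((cat == "unmapped").sum())
    duplicate = int((cat == "duplicate").sum())
    mapped = total - unmapped
    nodup = mapped - duplicate
    trans = int((cat == "trans").sum())
    cis_lt = int((cat == "cis_lt_1kb").sum())
    cis_mid = int((cat == "cis_1kb_10kb").sum())
    cis_hi = int((cat == "cis_ge_10kb").sum())
    return {
        "total": total,
        "unmapped": unmapped,
        "mapped": mapped,
        "duplicate": duplicate,
        "nodup": nodup,
        "cis": cis_lt + cis_mid + cis_hi,
        "trans": trans,
        "valid": trans + cis_mid + cis_hi,
        "cis_lt_1kb": cis_lt,
        "cis_ge_1kb": cis_mid + cis_hi,
        "cis_ge_10kb": cis_hi,
    }


def summarize(source) -> SummaryReport:
    """Accounting table from classified records or a raw count dict.

    Counts are validated against the accounting identities before any
    percentage is computed; a violated identity is named in the error.
    Percentages are rounded to two decimals at the row's stated basis.
    """
    counts = counts_from_classified(source) if isinstance(source, pd.DataFrame) else dict(source)
    c = counts
    identities = [
        ("mapped + unmapped <= total", c["mapped"] + c["unmapped"] <= c["total"] if "unmapped" in c else True),
        ("duplicate + nodup == mapped", c["duplicate"] + c["nodup"] == c["mapped"]),
        ("cis + trans == nodup", c["cis"] + c["trans"] == c["nodup"]),
        ("cis_lt_1kb + cis_ge_1kb == cis", c["cis_lt_1kb"] + c["cis_ge_1kb"] == c["cis"]),
        ("cis_ge_10kb <= cis_ge_1kb", c["cis_ge_10kb"] <= c["cis_ge_1kb"]),
        ("valid == trans + cis_ge_1kb", c["valid"] == c["trans"] + c["cis_ge_1kb"]),
    ]
    for name, ok in identities:
        if not ok:
            raise SummaryValidationError(f"count identity violated: {name}")
    if c["total"] == 0 or c["nodup"] == 0:
        warnings.warn("degenerate proportion basis (zero counts); percentages reported as 0")
    rows = []
    basis_label = {"total": "Proportion of Total Read Pairs", "nodup": "Proportion of No-Dup Read Pairs"}
    for label, key, basis in _ROWS:
        denom = c[basis]
        pct = round(100.0 * c[key] / denom, 2) if denom else 0.0
        rows.append((label, c[key], pct, basis_label[basis]))
    table = pd.DataFrame(rows, columns=["Category", "Count", "Percent", "Basis of proportion"])
    return SummaryReport(counts=c, table=table)


@dataclass
class ComplexityCurve:
    """Lander-Waterman saturation curve C(N) = L(1 - exp(-N/L))."""

    depths: np.ndarray
    expected_distinct: np.ndarray
    library_size: float  # inf when no saturation is detectable
    message: str = ""

    def at(self, depth: float) -> float:
        L = self.library_size
        if np.isinf(L):
            return float(depth)
        return float(L * (1.0 - np.exp(-depth / L)))


def complexity_curve(total_reads: float, distinct_reads: float, depth_grid) -> ComplexityCurve:
    """Fit the one-parameter Lander-Waterman model to one (total, distinct)
    observation and extrapolate expected distinct pairs over a depth grid.

    ``distinct = L (1 - exp(-total/L))`` is solved for the library size L by
    monotone root-finding.  ``distinct == total`` has no finite solution and
    is reported as "no saturation detectable" with the identity curve.
    """
    if not (0 < distinct_reads <= total_reads):
        raise ConfigError("need 0 < distinct_reads <= total_reads")
    depths = np.asarray(depth_grid, dtype=np.float64)
    if distinct_reads == total_reads:
        return ComplexityCurve(depths, depths.copy(), np.inf, "no saturation detectable")

    def f(L: float) -> float:
        return L * (1.0 - np.exp(-total_reads / L)) - distinct_reads

    lo = distinct_reads
    hi = max(2.0 * distinct_reads, total_reads)
    while f(hi) <= 0:
        hi *= 2.0
        if hi > 1e18:
            return ComplexityCurve(depths, depths.copy(), np.inf, "no saturation detectable")
    L = brentq(f, lo, hi, xtol=1e-9, rtol=1e-12)
    curve = L * (1.0 - np.exp(-depths / L))
    return ComplexityCurve(depths, curve, float(L))
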