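"""Distance-stratified binomial significance of cis contacts, plus
trans-contact ranking.

The expected model follows the first-pass logic of count-based interaction
callers: possible bin pairs are grouped into equal-occupancy distance
strata, each stratum gets a contact probability (stratum counts / (N x bin
pairs in stratum), N = total cis contacts of the chromosome), and a
monotone non-increasing (isotonic) fit across strata enforces decay.  Each
nonzero bin pair is then tested with an upper-tail binomial p-value and
Benjamini-Hochberg FDR within its chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .genome import ConfigError
from .matrixops import ContactMatrix, MatrixSet


@dataclass
class ExpectedModel:
    """Equal-occupancy distance strata with monotone contact probabilities."""

    chrom: str
    resolution: int
    n_contacts: int  # N: total cis counts on the chromosome
    min_distance_bins: int
    probs: np.ndarray  # per-stratum contact probability (non-increasing)
    pairs_per_stratum: np.ndarray  # occupancies, within 1 of each other
    dist_probs: np.ndarray  # per-bin-distance probability, index d - min_distance_bins

    def prob_at(self, bin_distance: np.ndarray) -> np.ndarray:
        k = np.clip(
            np.asarray(bin_distance, dtype=np.int64) - self.min_distance_bins,
            0,
            len(self.dist_probs) - 1,
        )
        return self.dist_probs[k]


def fit_expected(matrix: ContactMatrix, n_strata: int = 100, min_distance_bins: int = 1) -> ExpectedModel:
    """Fit the distance-expected contact probability of one cis matrix.

    All possible bin pairs at distance >= ``min_distance_bins`` are sorted
    by distance and split into ``n_strata`` groups whose bin-pair
    occupancies agree to within one pair (ties at one distance may straddle
    two strata; their counts are allocated proportionally).  Per-distance
    probabilities are the occupancy-weighted mix of their strata.
    """
    if not matrix.is_cis:
        raise ConfigError("fit_expected needs a cis matrix")
    n = matrix.n_bins
    dists = np.arange(min_distance_bins, n)
    mult = (n - dists).astype(np.int64)  # bin pairs per distance
    total_pairs = int(mult.sum())
    if total_pairs == 0:
        raise ConfigError("chromosome too short for the requested distances")
    if total_pairs < n_strata:
        warnings.warn(f"only {total_pairs} bin pairs; reducing strata from {n_strata}")
        n_strata = total_pairs
    coo = matrix.counts.tocoo()
    keep = (coo.col - coo.row) >= min_distance_bins
    counts_by_d = np.bincount(
        coo.col[keep] - coo.row[keep] - min_distance_bins,
        weights=coo.data[keep],
        minlength=len(dists),
    )
    N = int(counts_by_d.sum())

    cum = np.concatenate(([0], np.cumsum(mult)))  # pair-index range per distance
    bounds = (np.arange(n_strata + 1, dtype=np.int64) * total_pairs) // n_strata
    pairs = np.diff(bounds)
    probs = np.empty(n_strata)
    mids = np.empty(n_strata)
    frac = np.zeros((n_strata, len(dists)))  # share of distance d inside stratum s
    for s in range(n_strata):
        ov = np.minimum(cum[1:], bounds[s + 1]) - np.maximum(cum[:-1], bounds[s])
        ov = np.clip(ov, 0, None).astype(np.float64)
        frac[s] = ov / mult
        counts_s = float((counts_by_d * frac[s]).sum())
        probs[s] = counts_s / (max(N, 1) * pairs[s])
        mids[s] = float((dists * ov).sum() / ov.sum()) if ov.sum() else 0.0
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    probs = iso.fit_transform(mids, probs, sample_weight=pairs)
    dist_probs = frac.T @ probs  # occupancy-weighted mix per distance
    return ExpectedModel(matrix.chrom1, matrix.resolution, N, min_distance_bins, probs, pairs, dist_probs)


def test_interactions(matrix: ContactMatrix, model: ExpectedModel) -> pd.DataFrame:
    """Binomial upper-tail significance for every nonzero bin pair.

    Columns: chrom, bin1, bin2, mid1, mid2 (bin centers, bp), observed,
    expected, oe, p, q.  q is Benjamini-Hochberg over the tested (nonzero)
    pairs of this chromosome.  Bin pairs with zero expected probability but
    positive observed counts are flagged ``infinite_enrichment``.
    """
    if matrix.chrom1 != model.chrom or matrix.resolution != model.resolution:
        raise ConfigError("model was fitted on a different matrix")
    coo = matrix.counts.tocoo()
    keep = (coo.col - coo.row) >= model.min_distance_bins
    b1, b2, obs = coo.row[keep], coo.col[keep], coo.data[keep].astype(np.int64)
    prob = model.prob_at(b2 - b1)
    N = model.n_contacts
    expected = N * prob
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, obs / expected, np.inf)
    p = np.ones(len(obs))
    ok = prob > 0
    p[ok] = binom.sf(obs[ok] - 1, N, prob[ok])
    p[~ok & (obs > 0)] = 0.0
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    res = matrix.resolution
    return pd.DataFrame(
        {
            "chrom": matrix.chrom1,
            "bin1": b1,
            "bin2": b2,
            "mid1": b1 * res + res // 2,
            "mid2": b2 * res + res // 2,
            "observed": obs,
            "expected": expected,
            "oe": oe,
            "p": p,
            "q": q,
            "infinite_enrichment": ~ok & (obs > 0),
        }
    ).sort_values(["bin1", "bin2"]).reset_index(drop=True)


@dataclass
class LocusQuery:
    """Result of looking one interaction up by a pair of intervals."""

    found: bool
    hits: pd.DataFrame
    ambiguous: bool = False


def query_locus(
    interactions: pd.DataFrame,
    anchor1: tuple[str, int, int],
    anchor2: tuple[str, int, int],
    resolution: int | None = None,
) -> LocusQuery:
    """Find interaction record(s) whose bin midpoints fall in two intervals.

    Each midpoint is extended by half the resolution on both sides before
    the overlap test (half-open intervals).  Multiple hits are all returned
    and flagged ambiguous; no hit yields an explicit not-found result.
    """
    c1, s1, e1 = anchor1
    c2, s2, e2 = anchor2
    if interactions.empty:
        return LocusQuery(False, interactions)
    if resolution is None:
        resolution = int(interactions["mid2"].sub(interactions["mid1"]).abs().replace(0, np.nan).min())
    half = resolution // 2

    def _over(mid, lo, hi):
        return (mid - half < hi) & (mid + half > lo)

    df = interactions
    fwd = (df["chrom"] == c1) & (df["chrom"] == c2) & _over(df["mid1"], s1, e1) & _over(df["mid2"], s2, e2)
    rev = (df["chrom"] == c1) & (df["chrom"] == c2) & _over(df["mid1"], s2, e2) & _over(df["mid2"], s1, e1)
    hits = df[fwd | rev]
    return LocusQuery(found=not hits.empty, hits=hits.reset_index(drop=True), ambiguous=len(hits) > 1)


def rank_trans(matrix_set: MatrixSet, k: int = 500) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k trans bin pairs by raw count + chromosome-pair mean intensity.

    Ties break by (chrom1, bin1, chrom2, bin2) in genome order for
    determinism.  The intensity matrix holds the mean count over all bin
    pairs of each chromosome pair (symmetric, NaN diagonal).
    """
    order = {nm: i for i, nm in enumerate(matrix_set.genome.analysis_names)}
    rows = []
    for (ca, cb), cm in matrix_set.trans.items():
        coo = cm.counts.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            rows.append((ca, int(i), cb, int(j), float(v)))
    contacts = pd.DataFrame(rows, columns=["chrom1", "bin1", "chrom2", "bin2", "count"])
    if len(contacts) < k and len(contacts) > 0:
        warnings.warn(f"only {len(contacts)} nonzero trans pairs available (k={k})")
    if not contacts.empty:
        contacts["_o1"] = contacts["chrom1"].map(order)
        contacts["_o2"] = contacts["chrom2"].map(order)
        contacts = contacts.sort_values(
            ["count", "_o1", "bin1", "_o2", "bin2"], ascending=[False, True, True, True, True]
        ).drop(columns=["_o1", "_o2"])
    top = contacts.head(k).reset_index(drop=True)

    names = list(matrix_set.genome.analysis_names)
    intensity = pd.DataFrame(np.nan, index=names, columns=names)
    for (ca, cb), cm in matrix_set.trans.items():
        total = float(cm.counts.sum())
        cells = cm.counts.shape[0] * cm.counts.shape[1]
        mean = total / cells if cells else np.nan
        intensity.loc[ca, cb] = mean
        intensity.loc[cb, ca] = mean
    return top, intensity
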