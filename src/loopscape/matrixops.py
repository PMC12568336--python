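"""Contact matrices: binning, ICE balancing, coverage, decay, aggregation.

Bins are 0-based half-open ``[i*res, (i+1)*res)``; pair positions are
1-based and converted at binning (``bin = (pos - 1) // res``).  Cis
matrices store each contact once in the upper triangle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import pearsonr

from .genome import ConfigError, GenomeSpec


@dataclass
class ContactMatrix:
    """Sparse binned counts for one chromosome (cis) or chromosome pair."""

    resolution: int
    chrom1: str
    chrom2: str
    counts: sp.csr_matrix  # cis: upper triangular
    weights: np.ndarray | None = None  # per-bin balancing weight (cis only)
    mask: np.ndarray | None = None  # True where the bin is unusable
    balance_converged: bool | None = None

    @property
    def is_cis(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def dense(self) -> np.ndarray:
        """Symmetrized dense counts (cis) or the rectangular block (trans)."""
        d = self.counts.toarray().astype(np.float64)
        if self.is_cis:
            d = d + np.triu(d, 1).T
        return d

    def balanced_dense(self) -> np.ndarray:
        if self.weights is None:
            raise ValueError("matrix is not balanced; call balance() first")
        d = self.dense()
        w = np.where(np.isnan(self.weights), 0.0, self.weights)
        return d * w[:, None] * w[None, :]

    def marginals(self) -> np.ndarray:
        d = self.dense()
        if self.is_cis:
            return d.sum(axis=1)
        raise ValueError("marginals() is defined for cis matrices")

    def side_counts(self) -> np.ndarray:
        """Pair sides per bin: diagonal pixels contribute both sides."""
        d = self.dense()
        if not self.is_cis:
            raise ValueError("side_counts() is defined for cis matrices")
        return d.sum(axis=1) + np.diag(d)


@dataclass
class MatrixSet:
    """All cis and trans matrices of one dataset at one resolution."""

    resolution: int
    genome: GenomeSpec
    cis: dict[str, ContactMatrix]
    trans: dict[tuple[str, str], ContactMatrix]
    n_pairs: int

    def total_mass(self) -> int:
        tot = sum(int(m.counts.sum()) for m in self.cis.values())
        tot += sum(int(m.counts.sum()) for m in self.trans.values())
        return tot


def bin_pairs(records: pd.DataFrame, genome: GenomeSpec, resolution: int) -> MatrixSet:
    """Bin valid pair records into per-chromosome(-pair) sparse matrices.

    If the frame carries a ``valid`` column only valid records are used.
    Total matrix mass equals the number of binned pairs (conservation).
    """
    if resolution <= 0:
        raise ConfigError(f"resolution must be positive, got {resolution}")
    df = records[records["valid"]] if "valid" in records.columns else records
    names = list(genome.analysis_names)
    cis: dict[str, ContactMatrix] = {}
    trans: dict[tuple[str, str], ContactMatrix] = {}
    b1 = ((df["pos1"].to_numpy() - 1) // resolution).astype(np.int64)
    b2 = ((df["pos2"].to_numpy() - 1) // resolution).astype(np.int64)
    c1 = df["chrom1"].to_numpy()
    c2 = df["chrom2"].to_numpy()
    for chrom in names:
        nb = genome.n_bins(chrom, resolution)
        m = (c1 == chrom) & (c2 == chrom)
        i, j = b1[m], b2[m]
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        mat = sp.coo_matrix((np.ones(len(lo)), (lo, hi)), shape=(nb, nb)).tocsr()
        cis[chrom] = ContactMatrix(resolution, chrom, chrom, mat)
    for ai, ca in enumerate(names):
        for cb in names[ai + 1 :]:
            m = (c1 == ca) & (c2 == cb)
            if not m.any():
                mat = sp.csr_matrix((genome.n_bins(ca, resolution), genome.n_bins(cb, resolution)))
            else:
                mat = sp.coo_matrix(
                    (np.ones(int(m.sum())), (b1[m], b2[m])),
                    shape=(genome.n_bins(ca, resolution), genome.n_bins(cb, resolution)),
                ).tocsr()
            trans[(ca, cb)] = ContactMatrix(resolution, ca, cb, mat)
    return MatrixSet(resolution, genome, cis, trans, n_pairs=len(df))


def balance(
    matrix: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 200,
    mask_percentile: float = 2.0,
) -> ContactMatrix:
    """Iterative proportional fitting (ICE) of a cis matrix.

    Bins with zero coverage, or coverage strictly below the given percentile
    of nonzero coverages, are masked out.  Weights are scaled so balanced
    marginals are ~1 on unmasked bins.  Raw counts are preserved; the
    weights are stored on the returned matrix.
    """
    if not matrix.is_cis:
        raise ConfigError("balance() applies to cis matrices")
    d = matrix.dense()
    marg = d.sum(axis=1)
    mask = marg <= 0
    nz = marg[marg > 0]
    if nz.size:
        # low-coverage outliers only: the percentile cut must not bite into a
        # uniformly covered chromosome, so it is capped at half the median
        cut = min(np.percentile(nz, mask_percentile), 0.5 * np.median(nz))
        mask |= marg < cut
    if (~mask).sum() == 0:
        out = ContactMatrix(matrix.resolution, matrix.chrom1, matrix.chrom2, matrix.counts)
        out.weights = np.full(matrix.n_bins, np.nan)
        out.mask = mask
        out.balance_converged = False
        return out
    w = np.ones(matrix.n_bins)
    w[mask] = 0.0
    converged = False
    for _ in range(max_iter):
        cur = d * w[:, None] * w[None, :]
        s = cur.sum(axis=1)
        active = ~mask
        mean_s = s[active].mean()
        if mean_s == 0:
            break
        rel = np.abs(s[active] / mean_s - 1.0).max()
        if rel < tol:
            converged = True
            break
        adj = np.ones_like(s)
        adj[active] = s[active] / mean_s
        w = w / adj
    if not converged:
        warnings.warn("ICE did not converge within max_iter; weights are partial")
    # scale so unmasked balanced marginals ~ 1
    cur = d * w[:, None] * w[None, :]
    mean_marg = cur.sum(axis=1)[~mask].mean()
    if mean_marg > 0:
        w = w / np.sqrt(mean_marg)
    weights = np.where(mask, np.nan, w)
    out = ContactMatrix(matrix.resolution, matrix.chrom1, matrix.chrom2, matrix.counts)
    out.weights = weights
    out.mask = mask
    out.balance_converged = converged
    return out


@dataclass
class CoverageTrack:
    """Per-bin cis / total contact coverage and their ratio."""

    resolution: int
    cis: dict[str, np.ndarray]
    total: dict[str, np.ndarray]
    ratio: dict[str, np.ndarray]  # NaN where total == 0
    mean_ratio: float


def coverage(matrix_set: MatrixSet) -> CoverageTrack:
    """Per-bin sums of cis and of all contact sides; genome mean cis/total."""
    cis_cov: dict[str, np.ndarray] = {}
    tot_cov: dict[str, np.ndarray] = {}
    for chrom, cm in matrix_set.cis.items():
        c = cm.side_counts()
        cis_cov[chrom] = c
        tot_cov[chrom] = c.copy()
    for (ca, cb), cm in matrix_set.trans.items():
        d = cm.counts.toarray()
        if ca in tot_cov:
            tot_cov[ca] += d.sum(axis=1)
        if cb in tot_cov:
            tot_cov[cb] += d.sum(axis=0)
    ratio = {}
    num = 0.0
    den = 0
    for chrom in cis_cov:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(tot_cov[chrom] > 0, cis_cov[chrom] / tot_cov[chrom], np.nan)
        ratio[chrom] = r
        num += np.nansum(r)
        den += int(np.isfinite(r).sum())
    mean_ratio = num / den if den else float("nan")
    return CoverageTrack(matrix_set.resolution, cis_cov, tot_cov, ratio, mean_ratio)


@dataclass
class DecayCurve:
    """Contact probability P(s) on log-spaced distance bins."""

    chrom: str  # chromosome label or "all"
    edges: np.ndarray  # distance bin edges, bp
    mids: np.ndarray
    prob: np.ndarray  # mean per-bin-pair contact probability
    npairs: np.ndarray  # bin width in bin-pairs

    def slope(self, fit_range: tuple[float, float] = (30_000.0, 3_000_000.0)) -> float:
        """log-log regression slope of P(s) over a distance range."""
        lo, hi = fit_range
        m = (self.mids >= lo) & (self.mids <= hi) & (self.prob > 0)
        if m.sum() < 3:
            return float("nan")
        x = np.log10(self.mids[m])
        y = np.log10(self.prob[m])
        return float(np.polyfit(x, y, 1)[0])


def _diag_counts(cm: ContactMatrix) -> np.ndarray:
    """Counts per bin-distance d = 0..n-1 (upper triangle)."""
    coo = cm.counts.tocoo()
    d = coo.col - coo.row
    return np.bincount(d, weights=coo.data, minlength=cm.n_bins)


def contact_decay(
    matrix_set: MatrixSet,
    bins_per_decade: int = 8,
    smooth_bins: int = 0,
) -> dict[str, DecayCurve]:
    """P(s) per chromosome and pooled ("all"), normalized to unit cis mass.

    For each log-spaced distance bin, ``prob`` is the mean contact
    probability per bin pair: (counts in bin / total cis counts) / number of
    bin pairs in the bin, so sum(prob * npairs) = 1 over d >= 1.
    """
    res = matrix_set.resolution
    max_len = max(cm.n_bins for cm in matrix_set.cis.values()) * res
    n_edges = int(np.ceil(bins_per_decade * np.log10(max_len / res))) + 1
    edges = res * 10 ** (np.arange(n_edges + 1) / bins_per_decade)
    curves: dict[str, DecayCurve] = {}
    pooled_cnt = np.zeros(n_edges)
    pooled_np = np.zeros(n_edges)
    total_all = 0.0
    for chrom, cm in matrix_set.cis.items():
        n = cm.n_bins
        if n < 2:
            warnings.warn(f"{chrom}: fewer than 2 bins, skipped in decay")
            continue
        diag = _diag_counts(cm)
        d = np.arange(1, n)
        dist = d * res
        np_d = (n - d).astype(np.float64)
        which = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, n_edges - 1)
        cnt_b = np.bincount(which, weights=diag[1:], minlength=n_edges)
        np_b = np.bincount(which, weights=np_d, minlength=n_edges)
        total = diag[1:].sum()
        pooled_cnt += cnt_b
        pooled_np += np_b
        total_all += total
        with np.errstate(invalid="ignore", divide="ignore"):
            prob = np.where(np_b > 0, (cnt_b / max(total, 1.0)) / np.maximum(np_b, 1.0), 0.0)
        prob = _maybe_smooth(prob, smooth_bins)
        mids = np.sqrt(edges[:-1] * edges[1:])
        curves[chrom] = DecayCurve(chrom, edges, mids, prob, np_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(pooled_np > 0, (pooled_cnt / max(total_all, 1.0)) / np.maximum(pooled_np, 1.0), 0.0)
    prob = _maybe_smooth(prob, smooth_bins)
    mids = np.sqrt(edges[:-1] * edges[1:])
    curves["all"] = DecayCurve("all", edges, mids, prob, pooled_np)
    return curves


def _maybe_smooth(prob: np.ndarray, smooth_bins: int) -> np.ndarray:
    if smooth_bins and smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        pos = prob > 0
        logp = np.where(pos, np.log10(np.where(pos, prob, 1.0)), np.nan)
        sm = np.convolve(np.nan_to_num(logp), kernel, mode="same")
        norm = np.convolve(np.isfinite(logp).astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(norm > 0, 10 ** (sm / np.maximum(norm, 1e-12)), 0.0)
        return np.where(pos, out, 0.0)
    return prob


def fixed_bin_view(matrix_set: MatrixSet, n_bins: int = 100) -> tuple[np.ndarray, list[str]]:
    """Genome-wide matrix with every chromosome squeezed to ``n_bins`` bins.

    Returns the dense (n_bins * n_chroms)^2 matrix and per-coarse-bin
    chromosome labels.  Mass is conserved under the aggregation.
    """
    names = [c for c in matrix_set.genome.analysis_names if c in matrix_set.cis]
    offsets = {c: k * n_bins for k, c in enumerate(names)}
    size = n_bins * len(names)
    out = np.zeros((size, size))

    def coarse(chrom: str, bins: np.ndarray) -> np.ndarray:
        nb = matrix_set.cis[chrom].n_bins
        if nb < n_bins:
            warnings.warn(f"{chrom}: {nb} native bins aggregated onto {n_bins} coarse bins")
        return (bins.astype(np.int64) * n_bins) // nb

    for chrom, cm in matrix_set.cis.items():
        if chrom not in offsets:
            continue
        coo = cm.counts.tocoo()
        i = coarse(chrom, coo.row) + offsets[chrom]
        j = coarse(chrom, coo.col) + offsets[chrom]
        np.add.at(out, (i, j), coo.data)
    for (ca, cb), cm in matrix_set.trans.items():
        if ca not in offsets or cb not in offsets:
            continue
        coo = cm.counts.tocoo()
        nb_a = matrix_set.genome.n_bins(ca, matrix_set.resolution)
        nb_b = matrix_set.genome.n_bins(cb, matrix_set.resolution)
        i = (coo.row.astype(np.int64) * n_bins) // nb_a + offsets[ca]
        j = (coo.col.astype(np.int64) * n_bins) // nb_b + offsets[cb]
        np.add.at(out, (i, j), coo.data)
    labels = [c for c in names for _ in range(n_bins)]
    return out, labels


def correlate_replicates(
    set_a: MatrixSet,
    set_b: MatrixSet,
    max_distance: int = 5_000_000,
) -> float:
    """Pearson r between two replicates over jointly covered cis pixels.

    Pixels where either replicate is nonzero, within the distance cap, are
    log(1+x)-transformed before correlating.  Returns NaN when the supports
    are disjoint or degenerate.
    """
    if set_a.resolution != set_b.resolution:
        raise ConfigError("replicates must share a resolution")
    xs, ys = [], []
    cap = max_distance // set_a.resolution
    for chrom in set_a.cis:
        if chrom not in set_b.cis:
            continue
        a = set_a.cis[chrom].counts
        b = set_b.cis[chrom].counts
        union = (a + b).tocoo()
        keep = (union.col - union.row) <= cap
        rows, cols = union.row[keep], union.col[keep]
        xs.append(np.asarray(a[rows, cols]).ravel())
        ys.append(np.asarray(b[rows, cols]).ravel())
    if not xs:
        return float("nan")
    x = np.log1p(np.concatenate(xs))
    y = np.log1p(np.concatenate(ys))
    joint = (x > 0) & (y > 0)
    if x.size < 3 or not joint.any() or x.std() == 0 or y.std() == 0:
        return float("nan")  # disjoint or degenerate supports
    return float(pearsonr(x, y)[0])
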