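"""A/B compartment calling and saddle-plot compartmentalization strength.

The per-chromosome first eigenvector (E1) of the Pearson correlation matrix
of the distance-normalized (O/E) balanced contact map separates active (A,
positive after orientation) from inactive (B, negative) chromatin.  Because
the eigenvector sign is arbitrary, it is oriented against an external
per-bin activity track (e.g. ATAC peak density or gene density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .genome import ConfigError
from .matrixops import ContactMatrix


class DegenerateMatrixError(ValueError):
    """Matrix has no usable compartment signal (uniform or too sparse)."""


@dataclass
class CompartmentTrack:
    """Per-bin E1 with A/B labels (A where E1 > 0 after orientation)."""

    chrom: str
    e1: np.ndarray  # NaN on masked bins
    labels: np.ndarray  # 'A'/'B'/'' per bin
    orientation_r: float
    ambiguous: bool  # |r| < 0.1 against the orientation track


def observed_over_expected(matrix: ContactMatrix) -> np.ndarray:
    """Balanced map with each diagonal divided by its mean over usable bins.

    Masked bins are NaN.  Diagonals with zero mean stay NaN.
    """
    if matrix.weights is None:
        raise ConfigError("compartment analysis needs a balanced matrix")
    d = matrix.balanced_dense()
    mask = matrix.mask if matrix.mask is not None else np.zeros(matrix.n_bins, bool)
    d[mask, :] = np.nan
    d[:, mask] = np.nan
    n = d.shape[0]
    oe = np.full_like(d, np.nan)
    for k in range(n):
        diag = np.diagonal(d, offset=k)
        mu = np.nanmean(diag) if np.isfinite(diag).any() else np.nan
        if not np.isfinite(mu) or mu == 0:
            continue
        idx = np.arange(n - k)
        oe[idx, idx + k] = diag / mu
        oe[idx + k, idx] = diag / mu
    return oe


def compartment_eigenvector(
    matrix: ContactMatrix,
    orientation_track: np.ndarray,
    min_bins: int = 20,
    ambiguity_r: float = 0.1,
) -> CompartmentTrack:
    """E1 of the O/E Pearson-correlation matrix, sign-oriented.

    The eigenvector of the largest-magnitude eigenvalue is flipped so its
    correlation with ``orientation_track`` is >= 0; an absolute correlation
    below ``ambiguity_r`` flags the orientation as ambiguous.
    """
    oe = observed_over_expected(matrix)
    usable = np.isfinite(oe).any(axis=1)
    if int(usable.sum()) < min_bins:
        raise DegenerateMatrixError(
            f"only {int(usable.sum())} usable bins (< {min_bins}); eigenvector unstable"
        )
    sub = oe[np.ix_(usable, usable)]
    sub = np.where(np.isfinite(sub), sub, np.nanmean(sub))
    sd = sub.std(axis=0)
    if np.allclose(sd, 0):
        raise DegenerateMatrixError("degenerate spectrum: O/E map has no variance")
    corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr)
    evals, evecs = np.linalg.eigh(corr)
    lead = int(np.argmax(np.abs(evals)))
    v = evecs[:, lead]
    e1 = np.full(matrix.n_bins, np.nan)
    e1[usable] = v
    track = np.asarray(orientation_track, dtype=np.float64)
    if track.shape[0] != matrix.n_bins:
        raise ConfigError("orientation track must have one value per bin")
    m = usable & np.isfinite(track)
    if m.sum() >= 2 and np.std(track[m]) > 0 and np.std(e1[m]) > 0:
        r = float(pearsonr(e1[m], track[m])[0])
    else:
        r = float("nan")
    if np.isfinite(r) and r < 0:
        e1 = -e1
        r = -r
    labels = np.where(np.isnan(e1), "", np.where(e1 > 0, "A", "B"))
    ambiguous = (not np.isfinite(r)) or r < ambiguity_r
    return CompartmentTrack(matrix.chrom1, e1, labels, r, ambiguous)


@dataclass
class SaddleResult:
    """O/E averaged over E1-rank quantile pairs, plus strength profile."""

    saddle: np.ndarray  # (n_quantiles, n_quantiles), low E1 rank first
    strength: float  # (AA + BB) / (AB + BA) over corner blocks
    band_strength: dict[tuple[float, float], float]  # per distance band (bp)


def saddle(
    matrix: ContactMatrix,
    e1: np.ndarray,
    n_quantiles: int = 50,
    distance_bands: tuple[tuple[float, float], ...] = ((1e6, 5e6), (5e6, 1e8)),
    corner_fraction: float = 0.25,
) -> SaddleResult:
    """Rank bins by E1 and average O/E per rank-pair cell.

    Strength is the mean of the two same-compartment corner blocks divided
    by the mean of the two cross-compartment blocks, computed overall and
    per genomic-distance band.
    """
    oe = observed_over_expected(matrix)
    e1 = np.asarray(e1, dtype=np.float64)
    usable = np.isfinite(e1) & np.isfinite(oe).any(axis=1)
    n_use = int(usable.sum())
    if n_quantiles > n_use:
        raise ConfigError(f"n_quantiles={n_quantiles} exceeds usable bins ({n_use})")
    idx = np.flatnonzero(usable)
    order = idx[np.argsort(e1[idx], kind="stable")]
    groups = np.array_split(order, n_quantiles)
    res = matrix.resolution

    def _saddle_for(pairs_filter) -> np.ndarray:
        s = np.full((n_quantiles, n_quantiles), np.nan)
        for a in range(n_quantiles):
            for b in range(n_quantiles):
                block = oe[np.ix_(groups[a], groups[b])]
                if pairs_filter is not None:
                    di = np.abs(groups[a][:, None] - groups[b][None, :]) * res
                    block = np.where(pairs_filter(di), block, np.nan)
                if np.isfinite(block).any():
                    s[a, b] = np.nanmean(block)
        return s

    sad = _saddle_for(None)

    def _strength(s: np.ndarray) -> float:
        k = max(1, int(round(corner_fraction * n_quantiles)))
        bb = np.nanmean(s[:k, :k])
        aa = np.nanmean(s[-k:, -k:])
        ab = np.nanmean(s[:k, -k:])
        ba = np.nanmean(s[-k:, :k])
        denom = ab + ba
        return float((aa + bb) / denom) if denom and np.isfinite(denom) else float("nan")

    band_strength = {}
    for lo, hi in distance_bands:
        s_band = _saddle_for(lambda d, lo=lo, hi=hi: (d >= lo) & (d < hi))
        band_strength[(lo, hi)] = _strength(s_band)
    return SaddleResult(sad, _strength(sad), band_strength)
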