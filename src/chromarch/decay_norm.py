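"""Distance-decay expectation, Z-score maps, difference maps and decay curves.

The expected model pools all cis cells genome-wide per genomic-distance
stratum, optionally drops zero cells and IQR outliers, computes the stratum
mean and standard deviation, and smooths both across log-distance with a
LOWESS of small span.  Z-scores standardize each nonzero cis cell by its
stratum; difference maps are computed on Z-scores only, never raw counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome_io import BinTable
from .matrix_ops import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExpectedProfile",
    "ZScoreMatrix",
    "expected_profile",
    "zscore_transform",
    "differential_map",
    "decay_curve",
    "fit_decay_exponent",
]


@dataclass
class ExpectedProfile:
    """Per-distance expected contact mean/spread at one bin size."""

    bin_size: int
    distance: np.ndarray  # bp, strictly increasing
    lowess_average: np.ndarray
    lowess_stdev: np.ndarray
    n_obs: np.ndarray
    valid: np.ndarray  # stratum usable for Z-transform

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance": self.distance,
            "lowess_average": self.lowess_average,
            "lowess_stdev": self.lowess_stdev,
            "n_obs": self.n_obs,
            "valid": self.valid,
        })

    def lookup(self, dist_bins: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mean, std, valid) for distances given in bin units."""
        idx = np.searchsorted(self.distance // self.bin_size, dist_bins)
        idx = np.clip(idx, 0, len(self.distance) - 1)
        ok = (self.distance[idx] // self.bin_size) == dist_bins
        return (self.lowess_average[idx], self.lowess_stdev[idx],
                ok & self.valid[idx])


@dataclass
class ZScoreMatrix:
    bins: BinTable
    z: sp.csr_matrix  # symmetric; meaningful only where valid
    valid: sp.csr_matrix  # symmetric 0/1 cell mask

    def dense_cis(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.bins.chrom_range(chrom)
        return (np.asarray(self.z[lo:hi, lo:hi].todense()),
                np.asarray(self.valid[lo:hi, lo:hi].todense()).astype(bool))


def _cis_cells(m: ContactMatrix, use_balanced: bool):
    """Concatenate (distance_bins, value) over unmasked cis upper-triangle
    nonzero cells, genome-wide."""
    mat = m.balanced if (use_balanced and m.balanced is not None) else m.counts
    dists, vals, rows, cols, offs = [], [], [], [], []
    for chrom in m.bins.chroms.names:
        lo, hi = m.bins.chrom_range(chrom)
        block = sp.triu(mat[lo:hi, lo:hi]).tocoo()
        ok = m.mask[lo + block.row] & m.mask[lo + block.col]
        dists.append((block.col - block.row)[ok])
        vals.append(block.data[ok])
        rows.append(block.row[ok] + lo)
        cols.append(block.col[ok] + lo)
    return (np.concatenate(dists), np.concatenate(vals),
            np.concatenate(rows), np.concatenate(cols))


def _n_possible_by_distance(m: ContactMatrix) -> np.ndarray:
    """Number of unmasked cis bin pairs per distance (bin units)."""
    max_d = max(hi - lo for c in m.bins.chroms.names
                for lo, hi in [m.bins.chrom_range(c)])
    out = np.zeros(max_d, dtype=np.int64)
    for chrom in m.bins.chroms.names:
        lo, hi = m.bins.chrom_range(chrom)
        mk = m.mask[lo:hi]
        n = hi - lo
        for d in range(n):
            out[d] += int(np.sum(mk[: n - d] & mk[d:]))
    return out


def expected_profile(m: ContactMatrix, alpha: float = 0.005,
                     ignore_zeros: bool = True, iqr_filter: bool = True,
                     iqr_multiplier: float = 1.5,
                     use_balanced: bool = False) -> ExpectedProfile:
    """Genome-pooled per-distance mean and stdev, LOWESS-smoothed.

    Per stratum: zero cells are dropped when ``ignore_zeros``; values outside
    [Q1 - k*IQR, Q3 + k*IQR] are dropped when ``iqr_filter``; then the
    stratum means and stdevs are smoothed across log-distance with span
    ``alpha`` (fraction of strata; the effective window never falls below
    3 strata).  Strata with no observations are flagged invalid.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    dist_bins, vals, _, _ = _cis_cells(m, use_balanced)
    n_poss = _n_possible_by_distance(m)
    max_d = len(n_poss)

    mean = np.full(max_d, np.nan)
    std = np.full(max_d, np.nan)
    n_obs = np.zeros(max_d, dtype=np.int64)
    order = np.argsort(dist_bins, kind="stable")
    dist_sorted = dist_bins[order]
    vals_sorted = vals[order]
    bounds = np.searchsorted(dist_sorted, np.arange(max_d + 1))
    for d in range(max_d):
        v = vals_sorted[bounds[d]:bounds[d + 1]]
        if not ignore_zeros:
            n_zero = n_poss[d] - len(v)
            if n_zero > 0:
                v = np.concatenate([v, np.zeros(n_zero)])
        if iqr_filter and v.size >= 4:
            q1, q3 = np.percentile(v, [25, 75])
            iqr = q3 - q1
            lo_f, hi_f = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
            v = v[(v >= lo_f) & (v <= hi_f)]
        n_obs[d] = v.size
        if v.size:
            mean[d] = v.mean()
            sd = v.std(ddof=1) if v.size > 1 else 0.0
            # constant strata: round-off can leave a ~1e-15 residual spread
            std[d] = 0.0 if sd <= 1e-9 * abs(mean[d]) else sd

    have = n_obs > 0
    idx = np.flatnonzero(have)
    if idx.size >= 2:
        # smooth in log-log space: a power-law decay is locally linear there,
        # so the local fit is close to interpolating and does not bias the
        # per-stratum standardization
        logd = np.log(idx + 1.0)  # distance 0 maps to log(1)
        frac = max(alpha, min(1.0, 3.0 / idx.size))
        pos = mean[idx] > 0
        if pos.sum() >= 2:
            sm = lowess(np.log(mean[idx][pos]), logd[pos], frac=frac, it=0,
                        return_sorted=False)
            mean[idx[pos]] = np.exp(sm)
        spos = std[idx] > 0
        if spos.sum() >= 2:
            sm = lowess(np.log(std[idx][spos]), logd[spos], frac=frac, it=0,
                        return_sorted=False)
            std[idx[spos]] = np.exp(sm)
    valid = have & np.isfinite(mean) & np.isfinite(std)
    return ExpectedProfile(
        bin_size=m.bins.bin_size,
        distance=np.arange(max_d, dtype=np.int64) * m.bins.bin_size,
        lowess_average=mean, lowess_stdev=std, n_obs=n_obs, valid=valid)


def zscore_transform(m: ContactMatrix, e: ExpectedProfile,
                     use_balanced: bool = False) -> ZScoreMatrix:
    """Standardize nonzero cis cells by the distance-matched mean/stdev.

    Cells with a raw count of 0, or falling in strata with no observations or
    zero smoothed spread, are excluded from the valid mask (never +/-inf).
    """
    if e.bin_size != m.bins.bin_size:
        raise ValueError(
            f"profile bin size {e.bin_size} != matrix bin size {m.bins.bin_size}")
    dist_bins, vals, rows, cols = _cis_cells(m, use_balanced)
    mu, sd, ok = e.lookup(dist_bins)
    ok = ok & (sd > 0) & (vals != 0)
    z = np.zeros(len(vals))
    z[ok] = (vals[ok] - mu[ok]) / sd[ok]
    n = m.bins.n_bins
    r, c = rows[ok], cols[ok]
    zu = sp.coo_matrix((z[ok], (r, c)), shape=(n, n))
    vu = sp.coo_matrix((np.ones(ok.sum()), (r, c)), shape=(n, n))
    off = (r != c)
    zmat = (zu + sp.coo_matrix((z[ok][off], (c[off], r[off])), shape=(n, n))).tocsr()
    vmat = (vu + sp.coo_matrix((np.ones(off.sum()), (c[off], r[off])),
                               shape=(n, n))).tocsr()
    return ZScoreMatrix(bins=m.bins, z=zmat, valid=vmat)


def differential_map(z1: ZScoreMatrix, z2: ZScoreMatrix) -> ZScoreMatrix:
    """Z-score difference z1 - z2 on the intersection of valid cells."""
    if not z1.bins.frame.equals(z2.bins.frame):
        raise ValueError("bin tables differ")
    both = z1.valid.multiply(z2.valid)
    both.data = np.ones_like(both.data)
    diff = (z1.z - z2.z).multiply(both)
    return ZScoreMatrix(bins=z1.bins, z=diff.tocsr(), valid=both.tocsr())


def decay_curve(m: ContactMatrix, use_balanced: bool = False) -> pd.DataFrame:
    """Mean contact frequency per genomic distance, genome-pooled.

    The mean at distance d is the total count over all unmasked cis pairs at
    d divided by the number of such pairs (zeros included).
    """
    dist_bins, vals, _, _ = _cis_cells(m, use_balanced)
    n_poss = _n_possible_by_distance(m)
    sums = np.zeros(len(n_poss))
    np.add.at(sums, dist_bins, vals)
    have = n_poss > 0
    return pd.DataFrame({
        "distance": np.flatnonzero(have) * m.bins.bin_size,
        "mean_frequency": sums[have] / n_poss[have],
    })


def fit_decay_exponent(curve: pd.DataFrame, min_distance: int = 1) -> float:
    """Slope of log(mean frequency) vs log(distance); a power-law map with
    exponent alpha yields approximately -alpha."""
    sel = (curve["distance"] >= min_distance) & (curve["mean_frequency"] > 0)
    x = np.log(curve.loc[sel, "distance"].to_numpy(dtype=float))
    y = np.log(curve.loc[sel, "mean_frequency"].to_numpy(dtype=float))
    if len(x) < 2:
        raise ValueError("need at least two positive strata to fit a slope")
    return float(stats.linregress(x, y).slope)
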