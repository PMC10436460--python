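"""Build, mask, balance and characterize binned contact matrices.

A :class:`ContactMatrix` holds one genome-wide symmetric sparse count matrix
(cis and trans blocks together) over a :class:`~chromarch.genome_io.BinTable`,
a per-bin usability mask, and — after iterative correction — a per-bin bias
vector alongside the balanced matrix.  Raw counts are always retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome_io import BinTable, make_bins, ChromTable

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "read_pairs",
    "bin_pairs",
    "mask_low_coverage",
    "ice_balance",
    "coarsen",
    "estimate_map_resolution",
    "read_coo",
    "write_coo",
]


@dataclass
class ContactMatrix:
    bins: BinTable
    counts: sp.csr_matrix  # symmetric, raw counts
    mask: np.ndarray  # True = usable bin
    bias: np.ndarray | None = None  # mean-1 over unmasked bins
    balanced: sp.csr_matrix | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def cis_block(self, chrom: str, balanced: bool = False) -> sp.csr_matrix:
        lo, hi = self.bins.chrom_range(chrom)
        m = self.balanced if balanced else self.counts
        if balanced and m is None:
            raise ValueError("matrix has not been balanced")
        return m[lo:hi, lo:hi]

    def cis_marginals(self) -> np.ndarray:
        """Per-bin sum of cis contacts (same-chromosome row sums)."""
        out = np.zeros(self.n_bins)
        for chrom in self.bins.chroms.names:
            lo, hi = self.bins.chrom_range(chrom)
            out[lo:hi] = np.asarray(
                self.counts[lo:hi, lo:hi].sum(axis=1)).ravel()
        return out

    def marginals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def dense_cis(self, chrom: str, balanced: bool = False) -> np.ndarray:
        return np.asarray(self.cis_block(chrom, balanced=balanced).todense())


def read_pairs(path, chroms: ChromTable) -> pd.DataFrame:
    """Read a 4+-column pairs TSV (chrom1 pos1 chrom2 pos2).

    Lines starting with '#' (4DN-style headers) are skipped.  Positions are
    validated against the chromosome table.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom1", "pos1", "chrom2", "pos2"],
                     dtype={"chrom1": str, "chrom2": str})
    lengths = dict(chroms.items())
    for c, p in (("chrom1", "pos1"), ("chrom2", "pos2")):
        unknown = set(df[c]) - set(chroms.names)
        if unknown:
            raise ValueError(f"pairs reference unknown chromosome(s) {sorted(unknown)}")
        if ((df[p] < 0) | (df[p] >= df[c].map(lengths))).any():
            raise ValueError("pair position outside chromosome bounds")
    return df


def bin_pairs(pairs: pd.DataFrame, bins: BinTable,
              min_cis_distance: int = 4000,
              metadata: dict | None = None) -> ContactMatrix:
    """Accumulate read pairs into a symmetric binned contact matrix.

    Cis pairs closer than ``min_cis_distance`` bp are discarded (short-range
    ligation artefacts); trans pairs are never distance-filtered.  Each
    retained pair increments exactly one (i <= j) cell.
    """
    if min_cis_distance < 0:
        raise ValueError("min_cis_distance must be >= 0")
    same = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    dist = np.abs(pairs["pos1"].to_numpy() - pairs["pos2"].to_numpy())
    keep = ~same | (dist >= min_cis_distance)
    kept = pairs.loc[keep]

    n = bins.n_bins
    bi = np.empty(len(kept), dtype=np.int64)
    bj = np.empty(len(kept), dtype=np.int64)
    for chrom in bins.chroms.names:
        for side, (c, p, arr) in enumerate(
                (("chrom1", "pos1", bi), ("chrom2", "pos2", bj))):
            selmask = (kept[c] == chrom).to_numpy()
            if selmask.any():
                arr[selmask] = bins.bin_id(chrom, kept[p].to_numpy()[selmask])
    lo = np.minimum(bi, bj)
    hi = np.maximum(bi, bj)
    upper = sp.coo_matrix((np.ones(len(kept)), (lo, hi)), shape=(n, n)).tocsr()
    counts = upper + upper.T - sp.diags(upper.diagonal())
    m = ContactMatrix(bins=bins, counts=counts.tocsr(),
                      mask=np.ones(n, dtype=bool),
                      metadata=dict(metadata or {}))
    cis = m.cis_marginals().sum() / 2
    m.metadata.update(bin_size=bins.bin_size,
                      total=float(kept.shape[0]),
                      total_cis=float(cis),
                      total_trans=float(kept.shape[0] - cis))
    return m


def mask_low_coverage(m: ContactMatrix,
                      min_marginal_quantile: float = 0.02) -> ContactMatrix:
    """Mask bins with zero cis coverage or coverage below a low quantile.

    The threshold is the given quantile of the *nonzero* cis marginals of the
    full matrix, so the operation is idempotent.
    """
    if not (0 <= min_marginal_quantile < 0.5):
        raise ValueError("quantile must be in [0, 0.5)")
    marg = m.cis_marginals()
    nz = marg[marg > 0]
    thr = (np.quantile(nz, min_marginal_quantile, method="lower")
           if nz.size else np.inf)
    new_mask = m.mask & (marg > 0) & (marg >= thr)
    return replace(m, mask=new_mask, bias=None, balanced=None)


def ice_balance(m: ContactMatrix, tol: float = 1e-5,
                max_iter: int = 200) -> ContactMatrix:
    """Iterative correction: factor counts into b_i * b_j * balanced.

    Classic marginal equalization — each sweep divides the working matrix by
    the ratio of its genome-wide (cis+trans) unmasked row sums to their mean.
    Converged when the max relative deviation of unmasked row sums < ``tol``.
    The bias vector is normalized to mean 1 over unmasked bins; masked bins
    get bias NaN and zeroed balanced rows.  Raw counts are retained.
    """
    if int(m.mask.sum()) < 2:
        raise ValueError("need at least 2 unmasked bins to balance")
    n = m.n_bins
    keep = m.mask.astype(float)
    # zero out masked rows/cols of a working copy
    D = sp.diags(keep)
    work = (D @ m.counts @ D).tocsr()
    bias = np.ones(n)
    dev = np.inf
    for _ in range(max_iter):
        s = np.asarray(work.sum(axis=1)).ravel()
        s_un = s[m.mask]
        mean = s_un.mean()
        if mean == 0:
            raise ValueError("all unmasked bins have zero contacts")
        dev = np.abs(s_un / mean - 1).max()
        if dev < tol:
            break
        # symmetric update: each cell is divided by r_i * r_j, so the
        # square root of the marginal ratio is the stable step
        ratio = np.ones(n)
        ratio[m.mask] = np.sqrt(s[m.mask] / mean)
        # guard bins that hit zero mid-iteration
        ratio[ratio == 0] = 1.0
        bias *= ratio
        Dr = sp.diags(1.0 / ratio)
        work = (Dr @ work @ Dr).tocsr()
    else:
        raise RuntimeError(
            f"iterative correction did not converge in {max_iter} sweeps "
            f"(last max relative deviation {dev:.3g})")
    scale = bias[m.mask].mean()
    bias /= scale
    balanced = (work * scale * scale).tocsr()
    bias_out = np.where(m.mask, bias, np.nan)
    return replace(m, bias=bias_out, balanced=balanced)


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Aggregate raw counts to a ``factor``-times coarser bin size.

    Returns an unbalanced matrix; a new bin is usable if any constituent bin
    was usable.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    new_bins = make_bins(m.bins.chroms, m.bins.bin_size * factor)
    # map old global bin -> new global bin
    mapping = np.empty(m.n_bins, dtype=np.int64)
    for chrom in m.bins.chroms.names:
        lo, hi = m.bins.chrom_range(chrom)
        nlo, _ = new_bins.chrom_range(chrom)
        mapping[lo:hi] = nlo + np.arange(hi - lo) // factor
    S = sp.coo_matrix((np.ones(m.n_bins), (mapping, np.arange(m.n_bins))),
                      shape=(new_bins.n_bins, m.n_bins)).tocsr()
    counts = (S @ m.counts @ S.T).tocsr()
    new_mask = np.zeros(new_bins.n_bins, dtype=bool)
    np.logical_or.at(new_mask, mapping, m.mask)
    meta = dict(m.metadata)
    meta["bin_size"] = new_bins.bin_size
    return ContactMatrix(bins=new_bins, counts=counts, mask=new_mask,
                         metadata=meta)


def estimate_map_resolution(pairs: pd.DataFrame, chroms: ChromTable,
                            candidate_bin_sizes: list[int],
                            min_contacts: int = 1000,
                            min_fraction: float = 0.80) -> int | None:
    """Smallest bin size at which >= ``min_fraction`` of bins have
    >= ``min_contacts`` incident contacts.

    A bin's contact count is the number of pair endpoints falling in it.
    Returns None when no candidate qualifies.
    """
    if len(candidate_bin_sizes) == 0:
        raise ValueError("empty candidate list")
    sizes = sorted(int(s) for s in candidate_bin_sizes)
    for size in sizes:
        bins = make_bins(chroms, size)
        marg = np.zeros(bins.n_bins)
        for c, p in (("chrom1", "pos1"), ("chrom2", "pos2")):
            for chrom in chroms.names:
                selmask = (pairs[c] == chrom).to_numpy()
                if selmask.any():
                    ids = bins.bin_id(chrom, pairs[p].to_numpy()[selmask])
                    np.add.at(marg, ids, 1)
        frac = float((marg >= min_contacts).mean())
        if frac >= min_fraction:
            return size
    return None


def write_coo(m: ContactMatrix, matrix_path, bins_path=None,
              balanced: bool = False) -> None:
    """Write upper-triangle COO text ("bin_i bin_j count") + bins sidecar."""
    mat = m.balanced if balanced else m.counts
    if mat is None:
        raise ValueError("matrix has not been balanced")
    coo = sp.triu(mat).tocoo()
    order = np.lexsort((coo.col, coo.row))
    df = pd.DataFrame({"bin_i": coo.row[order], "bin_j": coo.col[order],
                       "count": coo.data[order]})
    df.to_csv(matrix_path, sep="\t", index=False)
    if bins_path is not None:
        m.bins.write(bins_path)


def read_coo(matrix_path, bins: BinTable,
             metadata: dict | None = None) -> ContactMatrix:
    """Read upper-triangle COO text back into a symmetric ContactMatrix."""
    df = pd.read_csv(matrix_path, sep="\t")
    n = bins.n_bins
    upper = sp.coo_matrix((df["count"], (df["bin_i"], df["bin_j"])),
                          shape=(n, n)).tocsr()
    counts = upper + upper.T - sp.diags(upper.diagonal())
    return ContactMatrix(bins=bins, counts=counts.tocsr(),
                         mask=np.ones(n, dtype=bool),
                         metadata=dict(metadata or {}))
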