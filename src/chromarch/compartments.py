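"""A/B compartment calling and between-condition switch classification.

Per chromosome the balanced cis matrix is turned into an observed/expected
matrix, then into a Pearson correlation matrix of bin profiles; the per-bin
score is the projection of the (column-centered) correlation matrix onto its
leading principal axis, so scores are exactly zero-mean per chromosome.  The
sign is oriented so that the positive (A) side is the gene-dense one — A is
the active, euchromatic compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import BinTable, assign_to_bins
from .matrix_ops import ContactMatrix
from .decay_norm import ExpectedProfile, expected_profile

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentTrack",
    "SwitchTrack",
    "call_compartments",
    "classify_switches",
    "compartment_summary",
    "gene_counts_per_bin",
]

SWITCH_CATEGORIES = ("A-A", "A-B", "B-A", "B-B", "NA")


@dataclass
class CompartmentTrack:
    bins: BinTable
    score: np.ndarray  # NaN where unassigned
    label: np.ndarray  # 'A' | 'B' | 'NA'
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.frame.copy()
        df["score"] = self.score
        df["label"] = self.label
        return df


@dataclass
class SwitchTrack:
    bins: BinTable
    category: np.ndarray  # per-bin, one of SWITCH_CATEGORIES
    regions: pd.DataFrame  # chrom,start,end,category runs (non-NA)
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.frame.copy()
        df["category"] = self.category
        return df


def gene_counts_per_bin(genes: pd.DataFrame, bins: BinTable,
                        rule: str = "majority") -> np.ndarray:
    counts = np.zeros(bins.n_bins)
    if len(genes):
        ids = assign_to_bins(genes, bins, rule=rule)
        np.add.at(counts, ids, 1)
    return counts


def call_compartments(m: ContactMatrix, e: ExpectedProfile | None = None,
                      genes: pd.DataFrame | None = None,
                      condition: str = "", min_valid_cells: int = 3,
                      min_bins: int = 10) -> CompartmentTrack:
    """Call per-bin A/B compartments from a balanced cis matrix.

    Chromosomes with fewer than ``min_bins`` usable bins, or a degenerate
    (zero-variance) correlation structure, are flagged NA with a warning.
    When ``genes`` is given, each chromosome's eigenvector sign is flipped if
    needed so that mean gene density on the positive side is >= that on the
    negative side; without genes the sign is fixed by a deterministic
    convention (positive score at the highest-coverage bin) and A/B labels
    should be treated as unoriented.
    """
    use_balanced = m.balanced is not None
    if e is None:
        e = expected_profile(m, use_balanced=use_balanced)
    gene_density = (gene_counts_per_bin(genes, m.bins)
                    if genes is not None else None)
    n = m.bins.n_bins
    score = np.full(n, np.nan)
    label = np.full(n, "NA", dtype=object)

    for chrom in m.bins.chroms.names:
        lo, hi = m.bins.chrom_range(chrom)
        mk = m.mask[lo:hi]
        nb = hi - lo
        if int(mk.sum()) < min_bins:
            logger.warning("compartments: %s has <%d usable bins, flagged NA",
                           chrom, min_bins)
            continue
        obs = m.dense_cis(chrom, balanced=use_balanced)
        d = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
        mu, _, ok = e.lookup(d.ravel())
        exp = mu.reshape(nb, nb)
        # the self-interaction diagonal is dominated by ligation artifacts
        # and carries no compartment signal
        okm = ok.reshape(nb, nb) & (exp > 0) & (d > 0)
        # invalid cells are filled with the neutral ratio 1 so they do not
        # distort the row correlations
        oe = np.ones((nb, nb))
        oe[okm] = obs[okm] / exp[okm]
        sub = np.ix_(mk, mk)
        oe_u = oe[sub]
        valid_u = okm[sub]
        rows_ok = valid_u.sum(axis=1) >= min_valid_cells
        if int(rows_ok.sum()) < min_bins:
            logger.warning("compartments: %s too sparse, flagged NA", chrom)
            continue
        X = oe_u[np.ix_(rows_ok, rows_ok)]
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X)
        # rows with (numerically) no contrast carry no signal
        flat = X.std(axis=1) <= 1e-9 * max(np.abs(X).max(), 1e-300)
        if not np.all(np.isfinite(C)) or flat.any():
            bad = ~np.all(np.isfinite(C), axis=1) | flat
            C[bad, :] = 0.0
            C[:, bad] = 0.0
        Xc = C - C.mean(axis=0, keepdims=True)
        G = Xc.T @ Xc
        if not np.any(G):
            logger.warning("compartments: %s degenerate correlation, NA", chrom)
            continue
        w, V = np.linalg.eigh(G)
        v = V[:, -1]
        s = Xc @ v  # zero-mean by construction (columns of Xc sum to 0)
        if np.allclose(s, 0):
            logger.warning("compartments: %s zero-variance scores, NA", chrom)
            continue
        local_ids = np.flatnonzero(mk)[rows_ok]
        # orient the sign
        if gene_density is not None:
            gd = gene_density[lo:hi][local_ids]
            pos, neg = s > 0, s < 0
            mean_pos = gd[pos].mean() if pos.any() else -np.inf
            mean_neg = gd[neg].mean() if neg.any() else -np.inf
            if mean_pos < mean_neg:
                s = -s
        else:
            cov = obs[local_ids].sum(axis=1)
            if s[np.argmax(cov)] < 0:
                s = -s
        score[lo + local_ids] = s
        lab = np.where(s > 0, "A", np.where(s < 0, "B", "NA"))
        label[lo + local_ids] = lab
    return CompartmentTrack(bins=m.bins, score=score, label=label,
                            condition=condition)


def _runs(values: np.ndarray):
    """Yield (start_idx, end_idx, value) maximal runs of equal values."""
    if len(values) == 0:
        return
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            yield start, i, values[start]
            start = i


def classify_switches(t1: CompartmentTrack, t2: CompartmentTrack) -> SwitchTrack:
    """Per-bin A/B switch categories between two conditions.

    Bins labeled in both conditions get one of A-A/A-B/B-A/B-B; anything else
    is NA.  The summary reports per-category bin and region counts plus the
    switching fraction (switched bins / bins labeled in both conditions).
    """
    if not t1.bins.frame.equals(t2.bins.frame):
        raise ValueError("bin tables differ")
    bins = t1.bins
    cat = np.full(bins.n_bins, "NA", dtype=object)
    both = (t1.label != "NA") & (t2.label != "NA")
    cat[both] = np.char.add(np.char.add(
        t1.label[both].astype(str), "-"), t2.label[both].astype(str))

    rows = []
    for chrom in bins.chroms.names:
        lo, hi = bins.chrom_range(chrom)
        bf = bins.frame
        for s, ee, val in _runs(cat[lo:hi]):
            if val == "NA":
                continue
            rows.append((chrom, int(bf["start"].iloc[lo + s]),
                         int(bf["end"].iloc[lo + ee - 1]), val))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])

    labeled = int(both.sum())
    switched = int(np.isin(cat, ["A-B", "B-A"]).sum())
    summary = {
        "bins_labeled": labeled,
        "switching_fraction": (switched / labeled) if labeled else np.nan,
    }
    for c in SWITCH_CATEGORIES[:4]:
        summary[f"bins_{c}"] = int((cat == c).sum())
        summary[f"regions_{c}"] = int((regions["category"] == c).sum()) if len(regions) else 0
    return SwitchTrack(bins=bins, category=cat, regions=regions, summary=summary)


def compartment_summary(t: CompartmentTrack, genes: pd.DataFrame | None = None,
                        gc: np.ndarray | None = None) -> pd.DataFrame:
    """Per-label region count, genome fraction, gene count and density.

    Regions are maximal same-label runs; genome fraction is labeled bp over
    total genome bp; gene density is genes per Mb of labeled sequence.
    """
    bins = t.bins
    bf = bins.frame
    widths = (bf["end"] - bf["start"]).to_numpy()
    genome_bp = widths.sum()
    gene_bin = None
    if genes is not None:
        gene_bin = assign_to_bins(genes, bins, rule="majority")
    rows = []
    for lab in ("A", "B"):
        sel = t.label == lab
        nregions = 0
        for chrom in bins.chroms.names:
            lo, hi = bins.chrom_range(chrom)
            nregions += sum(1 for _, _, v in _runs(t.label[lo:hi]) if v == lab)
        bp = int(widths[sel].sum())
        row = {"label": lab, "n_regions": nregions, "n_bins": int(sel.sum()),
               "genome_fraction": bp / genome_bp}
        if gene_bin is not None:
            ngenes = int(np.isin(gene_bin, np.flatnonzero(sel)).sum())
            row["n_genes"] = ngenes
            row["gene_density_per_mb"] = ngenes / (bp / 1e6) if bp else np.nan
        if gc is not None:
            row["mean_gc"] = float(np.nanmean(gc[sel])) if sel.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
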