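"""Joins between architecture calls and expression / histone-peak tracks.

Expression contrasts between genomic classes use the two-sided Wilcoxon
rank-sum test on log2(x+1) abundances; simple differential-expression calls
gate a count-based test with the |fold change| > 2, P < 0.01 rule;
region-level enrichment of DE genes uses Fisher's exact test; differential
peaks follow an any-overlap gain/loss rule binned by switch category; and
boundary metaprofiles average peak coverage around TAD boundary bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import BinTable, assign_to_bins
from .compartments import SwitchTrack
from .tads import TADSet

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "expression_compare",
    "deg_call_simple",
    "deg_region_enrichment",
    "peak_gain_loss",
    "boundary_peak_profile",
]


@dataclass
class PeakSet:
    mark: str
    condition: str
    intervals: pd.DataFrame  # chrom,start,end


def expression_compare(values_a: np.ndarray, values_b: np.ndarray,
                       log_transform: bool = True) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U, normal approximation
    with tie correction) between two gene classes.

    Abundances are compared on log2(x + 1) scale.  Returns the statistic,
    p-value, per-class medians and sizes.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty expression class")
    if log_transform:
        a = np.log2(a + 1)
        b = np.log2(b + 1)
    if np.ptp(np.concatenate([a, b])) == 0:
        # all values tied: no evidence either way
        stat, p = a.size * b.size / 2.0, 1.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    return {"statistic": stat, "p_value": p,
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "n_a": int(a.size), "n_b": int(b.size)}


def deg_call_simple(expr: pd.DataFrame, cond1_cols: list[str],
                    cond2_cols: list[str], fc_min: float = 2.0,
                    p_max: float = 0.01, pseudocount: float = 1.0,
                    ) -> pd.DataFrame:
    """Simple differential-expression calls between two conditions.

    log2 fold change is computed on pseudocounted, library-size-normalized
    mean counts (condition 2 over condition 1).  With >= 3 replicates per
    side the p-value comes from a Welch t-test on log2(cpm + 1); otherwise
    from the exact conditional binomial test on summed counts (the classic
    two-sample Poisson comparison), with the library-size ratio as the null
    proportion.  A gene is up/down only when |fold change| > ``fc_min`` AND
    p < ``p_max``; all-zero genes are 'ns' and flagged.
    """
    if not cond1_cols or not cond2_cols:
        raise ValueError("need at least one replicate per condition")
    x = expr[list(cond1_cols) + list(cond2_cols)].to_numpy(dtype=float)
    # median-of-ratios size factors: robust to asymmetric differential
    # expression, which inflates plain total-count library sizes
    with np.errstate(divide="ignore"):
        loggm = np.log(x).mean(axis=1)
    usable = np.isfinite(loggm)
    if usable.sum() >= 10:
        sf = np.exp(np.median(np.log(x[usable]) - loggm[usable, None], axis=0))
    else:
        tot = x.sum(axis=0)
        sf = tot / tot.mean() if tot.mean() > 0 else np.ones(x.shape[1])
    sf = sf / sf.mean()
    xn = x / sf
    n1, n2 = len(cond1_cols), len(cond2_cols)
    x1, x2 = xn[:, :n1], xn[:, n1:]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))

    p = np.ones(len(expr))
    if n1 >= 3 and n2 >= 3:
        with np.errstate(invalid="ignore"):
            res = stats.ttest_ind(np.log2(x2 + 1), np.log2(x1 + 1),
                                  axis=1, equal_var=False)
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    else:
        s1 = x[:, :n1].sum(axis=1)
        s2 = x[:, n1:].sum(axis=1)
        e1, e2 = sf[:n1].sum(), sf[n1:].sum()
        prop = e2 / (e1 + e2)
        for g in range(len(expr)):
            tot = int(s1[g] + s2[g])
            if tot > 0:
                p[g] = stats.binomtest(int(s2[g]), tot, prop,
                                       alternative="two-sided").pvalue
    x1 = expr[cond1_cols].to_numpy(dtype=float)
    x2 = expr[cond2_cols].to_numpy(dtype=float)

    all_zero = (x1.sum(axis=1) + x2.sum(axis=1)) == 0
    status = np.where(
        (np.abs(log2fc) > np.log2(fc_min)) & (p < p_max) & ~all_zero,
        np.where(log2fc > 0, "up", "down"), "ns")
    out = pd.DataFrame({
        "gene_id": expr["gene_id"] if "gene_id" in expr else expr.index,
        "log2_fold_change": log2fc,
        "p_value": p,
        "status": status,
        "all_zero": all_zero,
    })
    return out.reset_index(drop=True)


def _genes_in_regions(genes: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Boolean per gene: midpoint falls inside any region."""
    inside = np.zeros(len(genes), dtype=bool)
    mids = ((genes["start"].to_numpy() + genes["end"].to_numpy()) // 2)
    for chrom, grp in regions.groupby("chrom", sort=False):
        selmask = (genes["chrom"] == chrom).to_numpy()
        if not selmask.any():
            continue
        gm = mids[selmask]
        hit = np.zeros(len(gm), dtype=bool)
        for s, e in zip(grp["start"], grp["end"]):
            hit |= (gm >= s) & (gm < e)
        inside[np.flatnonzero(selmask)[hit]] = True
    return inside


def deg_region_enrichment(degs: pd.DataFrame, regions: pd.DataFrame,
                          genes: pd.DataFrame,
                          categories: list[str] | None = None) -> pd.DataFrame:
    """Enrichment of up/down DEGs inside region categories (Fisher exact).

    For each region category and direction, a 2x2 table of
    (DEG-of-direction vs not) x (gene inside vs outside) is tested
    two-sided.  Degenerate tables (no DEGs of the direction) yield an
    undefined odds ratio and are flagged.
    """
    if len(genes) == 0:
        raise ValueError("empty gene universe")
    deg_by_gene = degs.set_index("gene_id")["status"]
    status = genes["name"].map(deg_by_gene).fillna("ns").to_numpy()
    if categories is None:
        categories = sorted(regions["category"].unique()) \
            if "category" in regions else ["all"]
    rows = []
    for cat in categories:
        reg = regions[regions["category"] == cat] if "category" in regions else regions
        inside = _genes_in_regions(genes, reg)
        for direction in ("up", "down"):
            is_deg = status == direction
            t11 = int((is_deg & inside).sum())
            t12 = int((is_deg & ~inside).sum())
            t21 = int((~is_deg & inside).sum())
            t22 = int((~is_deg & ~inside).sum())
            degenerate = (t11 + t12 == 0) or (t21 + t22 == 0) \
                or (t11 + t21 == 0) or (t12 + t22 == 0)
            if degenerate:
                odds, pval = np.nan, 1.0
            else:
                odds, pval = stats.fisher_exact([[t11, t12], [t21, t22]],
                                                alternative="two-sided")
            rows.append({"category": cat, "direction": direction,
                         "n_deg_inside": t11, "n_deg_outside": t12,
                         "n_other_inside": t21, "n_other_outside": t22,
                         "odds_ratio": odds, "p_value": pval,
                         "degenerate": degenerate})
    return pd.DataFrame(rows)


def _any_overlap(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: overlaps (>=1 bp) any subject interval."""
    out = np.zeros(len(query), dtype=bool)
    for chrom, sub in subject.groupby("chrom", sort=False):
        selmask = (query["chrom"] == chrom).to_numpy()
        if not selmask.any():
            continue
        qs = query["start"].to_numpy()[selmask]
        qe = query["end"].to_numpy()[selmask]
        ss = np.sort(sub["start"].to_numpy())
        se_sorted = sub.sort_values("start")["end"].to_numpy()
        # subject intervals may abut; check all with start < query end and
        # end > query start via running max of ends
        run_max_end = np.maximum.accumulate(se_sorted)
        idx = np.searchsorted(ss, qe, side="left")  # subjects starting before qe
        hit = (idx > 0) & (run_max_end[np.maximum(idx - 1, 0)] > qs)
        out[np.flatnonzero(selmask)] = hit
    return out


def peak_gain_loss(p1: PeakSet, p2: PeakSet, switch: SwitchTrack,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak gains/losses between conditions, by compartment switch category.

    A gain is a condition-2 peak with zero bp overlap to every condition-1
    peak; a loss is the mirror.  Each event is assigned the switch category
    of its majority bin.  Returns (events, counts) where counts has one row
    per (change, category).
    """
    if p1.mark != p2.mark:
        raise ValueError(f"mark mismatch: {p1.mark} vs {p2.mark}")
    gains = p2.intervals[~_any_overlap(p2.intervals, p1.intervals)].copy()
    losses = p1.intervals[~_any_overlap(p1.intervals, p2.intervals)].copy()
    events = []
    for change, df in (("gain", gains), ("loss", losses)):
        if len(df) == 0:
            continue
        ids = assign_to_bins(df, switch.bins, rule="majority")
        cats = switch.category[ids]
        for (chrom, s, e), cat in zip(
                zip(df["chrom"], df["start"], df["end"]), cats):
            events.append({"mark": p1.mark, "change": change, "chrom": chrom,
                           "start": int(s), "end": int(e), "category": cat})
    events_df = pd.DataFrame(
        events, columns=["mark", "change", "chrom", "start", "end", "category"])
    counts = (events_df.groupby(["change", "category"]).size()
              .rename("n").reset_index()
              if len(events_df) else
              pd.DataFrame(columns=["change", "category", "n"]))
    return events_df, counts


def coverage_per_bin(peaks: pd.DataFrame, bins: BinTable) -> np.ndarray:
    """Fraction of each bin covered by (possibly overlapping) peaks."""
    cov = np.zeros(bins.n_bins)
    bs = bins.bin_size
    bf = bins.frame
    widths = (bf["end"] - bf["start"]).to_numpy()
    for chrom, grp in peaks.groupby("chrom", sort=False):
        if chrom not in bins.offsets:
            continue
        lo, hi = bins.chrom_range(chrom)
        length = bins.chroms.length(chrom)
        # merge overlapping peaks, then spread bp into bins
        ivs = grp.sort_values("start")[["start", "end"]].to_numpy()
        merged = []
        for s, e in ivs:
            s, e = max(0, int(s)), min(int(e), length)
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            elif e > s:
                merged.append([s, e])
        for s, e in merged:
            b0, b1 = s // bs, (e - 1) // bs
            for b in range(b0, b1 + 1):
                ov = min(e, (b + 1) * bs) - max(s, b * bs)
                cov[lo + b] += ov
    return cov / widths


def boundary_peak_profile(peaks: PeakSet, tads: TADSet,
                          window: int = 10) -> pd.DataFrame:
    """Mean peak coverage per bin offset around TAD boundary bins.

    Offsets run from -window to +window bins; coverage is bp covered over
    bin length, averaged over all boundaries whose offset bin stays on the
    same chromosome.
    """
    bins = tads.bins
    cov = coverage_per_bin(peaks.intervals, bins)
    offsets = np.arange(-window, window + 1)
    sums = np.zeros(len(offsets))
    ns = np.zeros(len(offsets))
    for b in tads.boundaries:
        lo, hi = bins.chrom_range(b.chrom)
        for k, off in enumerate(offsets):
            j = b.bin_id + off
            if lo <= j < hi:
                sums[k] += cov[j]
                ns[k] += 1
    mean = np.divide(sums, ns, out=np.zeros_like(sums), where=ns > 0)
    return pd.DataFrame({"offset_bins": offsets, "mean_coverage": mean,
                         "n_boundaries": ns.astype(int)})
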