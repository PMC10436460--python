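"""Distance-stratified significant cis-contact calling and background-based
trans-contact calling.

Cis bin pairs at or beyond a minimum genomic distance are pooled into
equal-occupancy distance strata; the expected count of a pair is the stratum
mean rate times the product of the two bin biases.  P-values are upper-tail
Poisson probabilities, q-values are Benjamini-Hochberg over the whole tested
family (all unmasked pairs in range, zero-count pairs included), and a call
is significant only when count > min_count AND p < p_max AND q < q_max.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix_ops import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "call_significant_cis",
    "call_significant_trans",
    "compare_interaction_sets",
]

_CALL_COLUMNS = ["bin_i", "bin_j", "kind", "distance", "count", "expected",
                 "p_value", "q_value", "significant"]


def _bias_or_ones(m: ContactMatrix) -> np.ndarray:
    if m.bias is None:
        return np.ones(m.n_bins)
    b = np.where(np.isfinite(m.bias), m.bias, 1.0)
    return b


def _finalize(df: pd.DataFrame, min_count: int, p_max: float,
              q_max: float) -> pd.DataFrame:
    if len(df) == 0:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    _, q, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
    df["q_value"] = q
    df["significant"] = ((df["count"] > min_count)
                         & (df["p_value"] < p_max)
                         & (df["q_value"] < q_max))
    return df


def call_significant_cis(m: ContactMatrix, n_strata: int = 100,
                         min_dist: int = 10_000, min_count: int = 2,
                         p_max: float = 0.01, q_max: float = 0.01) -> pd.DataFrame:
    """Call significant cis interactions with a stratified Poisson model.

    Every unmasked cis pair at genomic distance >= ``min_dist`` is tested;
    contiguous distance ranges are grouped into ``n_strata`` strata of
    approximately equal total contact count (equal occupancy), and the
    expected count of a pair is its stratum's mean count per pair times
    b_i * b_j.  Returns one row per tested pair with i <= j.
    """
    bs = m.bins.bin_size
    min_dist_bins = -(-min_dist // bs)

    bi_all, bj_all, cnt_all, dist_all = [], [], [], []
    for chrom in m.bins.chroms.names:
        lo, hi = m.bins.chrom_range(chrom)
        nb = hi - lo
        if nb <= min_dist_bins:
            continue
        block = m.dense_cis(chrom)
        iu, ju = np.triu_indices(nb, k=min_dist_bins)
        ok = m.mask[lo + iu] & m.mask[lo + ju]
        bi_all.append(lo + iu[ok])
        bj_all.append(lo + ju[ok])
        cnt_all.append(block[iu[ok], ju[ok]])
        dist_all.append(ju[ok] - iu[ok])
    if not bi_all:
        warnings.warn("no cis pairs at or beyond min_dist")
        return pd.DataFrame(columns=_CALL_COLUMNS)
    bi = np.concatenate(bi_all)
    bj = np.concatenate(bj_all)
    cnt = np.concatenate(cnt_all)
    dist = np.concatenate(dist_all)

    # per-distance totals, then contiguous equal-occupancy grouping
    max_d = int(dist.max()) + 1
    per_d_sum = np.zeros(max_d)
    per_d_n = np.zeros(max_d)
    np.add.at(per_d_sum, dist, cnt)
    np.add.at(per_d_n, dist, 1)
    present = np.flatnonzero(per_d_n > 0)
    total = per_d_sum.sum()
    n_strata_eff = int(min(n_strata, len(present)))
    if n_strata_eff < n_strata:
        warnings.warn(f"fewer distance strata than requested: {n_strata_eff}")
    # assign each distance to a stratum by cumulative occupancy
    cum = np.cumsum(per_d_sum[present])
    if total > 0:
        strat_of_present = np.minimum(
            (cum / total * n_strata_eff - 1e-12).astype(int), n_strata_eff - 1)
    else:
        strat_of_present = np.zeros(len(present), dtype=int)
    strat_of_d = np.zeros(max_d, dtype=int)
    strat_of_d[present] = strat_of_present
    strat = strat_of_d[dist]

    # decay-matched bias: alternate (a) stratum rates on bias-corrected
    # counts with (b) per-bin marginal matching against the expected
    # marginal.  Unlike the raw ICE bias this does not absorb chromosome-
    # edge coverage structure, so the Poisson factorization stays calibrated.
    n = m.n_bins
    bias = np.ones(n)
    lam_strat = np.zeros(n_strata_eff)
    for _ in range(6):
        bb = bias[bi] * bias[bj]
        s_cnt = np.zeros(n_strata_eff)
        s_bb = np.zeros(n_strata_eff)
        np.add.at(s_cnt, strat, cnt)
        np.add.at(s_bb, strat, bb)
        lam_strat = np.divide(s_cnt, s_bb, out=np.zeros(n_strata_eff),
                              where=s_bb > 0)
        pred = lam_strat[strat] * bb
        obs_marg = np.zeros(n)
        exp_marg = np.zeros(n)
        for arr in (bi, bj):
            np.add.at(obs_marg, arr, cnt)
            np.add.at(exp_marg, arr, pred)
        upd = np.sqrt(np.divide(obs_marg, exp_marg,
                                out=np.ones(n), where=exp_marg > 0))
        bias *= upd
        tested = np.zeros(n, dtype=bool)
        tested[bi] = True
        tested[bj] = True
        bias[tested] /= bias[tested].mean()

    expected = lam_strat[strat] * bias[bi] * bias[bj]
    p = stats.poisson.sf(cnt - 1, expected)
    p = np.where(expected > 0, p, 1.0)
    df = pd.DataFrame({"bin_i": bi, "bin_j": bj, "kind": "cis",
                       "distance": dist * bs, "count": cnt,
                       "expected": expected, "p_value": p})
    return _finalize(df, min_count, p_max, q_max)


def call_significant_trans(m: ContactMatrix, min_count: int = 2,
                           p_max: float = 0.01, q_max: float = 0.01,
                           ) -> pd.DataFrame:
    """Call significant trans interactions against a uniform background.

    The expected count of every unmasked trans pair is the global trans mean
    count per pair times b_i * b_j; only nonzero pairs can exceed the count
    gate but the whole family enters the BH correction.
    """
    bias = _bias_or_ones(m)
    chroms = m.bins.chroms.names
    # global trans totals
    n_pairs = 0
    total = 0.0
    blocks = []
    for x in range(len(chroms)):
        lo1, hi1 = m.bins.chrom_range(chroms[x])
        for y in range(x + 1, len(chroms)):
            lo2, hi2 = m.bins.chrom_range(chroms[y])
            blk = m.counts[lo1:hi1, lo2:hi2].tocoo()
            ok = m.mask[lo1 + blk.row] & m.mask[lo2 + blk.col]
            blocks.append((lo1 + blk.row[ok], lo2 + blk.col[ok], blk.data[ok]))
            n_pairs += int(m.mask[lo1:hi1].sum()) * int(m.mask[lo2:hi2].sum())
            total += blk.data[ok].sum()
    if n_pairs == 0 or total == 0:
        warnings.warn("no trans contacts; empty call set")
        return pd.DataFrame(columns=_CALL_COLUMNS)
    lam = total / n_pairs
    bi = np.concatenate([b[0] for b in blocks])
    bj = np.concatenate([b[1] for b in blocks])
    cnt = np.concatenate([b[2] for b in blocks])
    expected = lam * bias[bi] * bias[bj]
    p_nz = stats.poisson.sf(cnt - 1, expected)
    df = pd.DataFrame({"bin_i": bi, "bin_j": bj, "kind": "trans",
                       "distance": -1, "count": cnt,
                       "expected": expected, "p_value": p_nz})
    # zero-count trans pairs belong to the tested family with p = 1; they can
    # never be significant, so they enter BH as an implicit count.  BH with
    # m0 extra p=1 tests rescales q by (n + m0) / rank; do it explicitly.
    n_zero = n_pairs - len(df)
    if len(df):
        p_sorted_idx = np.argsort(df["p_value"].to_numpy(), kind="stable")
        p_sorted = df["p_value"].to_numpy()[p_sorted_idx]
        ranks = np.arange(1, len(df) + 1)
        q_raw = p_sorted * (len(df) + n_zero) / ranks
        q_mono = np.minimum.accumulate(q_raw[::-1])[::-1]
        q = np.empty(len(df))
        q[p_sorted_idx] = np.minimum(q_mono, 1.0)
        df["q_value"] = q
        df["significant"] = ((df["count"] > min_count)
                             & (df["p_value"] < p_max)
                             & (df["q_value"] < q_max))
    return df


def compare_interaction_sets(calls: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Venn-style overlap table of significant calls across conditions.

    Calls are keyed by (bin_i, bin_j, kind); the output has one row per
    non-empty membership pattern with the member conditions and the count.
    """
    names = list(calls)
    sets = {}
    for name, df in calls.items():
        sig = df[df["significant"]] if "significant" in df else df
        sets[name] = set(zip(sig["bin_i"], sig["bin_j"], sig["kind"]))
    universe = set().union(*sets.values()) if sets else set()
    patterns: dict[tuple[str, ...], int] = {}
    for key in universe:
        members = tuple(n for n in names if key in sets[n])
        patterns[members] = patterns.get(members, 0) + 1
    rows = [{"conditions": "&".join(k), "n": v}
            for k, v in sorted(patterns.items())]
    return pd.DataFrame(rows, columns=["conditions", "n"])
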