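"""Insulation-score TAD calling and the four-class transition classifier.

The insulation score of bin i is the mean contact intensity in the square of
cells spanning the ``square_span`` upstream bins by the ``square_span``
downstream bins (the bin's own row/column excluded), normalized as log2 of
the ratio to the chromosome mean.  Boundaries sit at local minima where the
delta track (right-window mean minus left-window mean of the normalized
score) crosses zero upward with sufficient amplitude; TADs are the
inter-boundary intervals.  Between-condition transitions are classified on a
bipartite overlap graph as Stable / Split / Merge / Rearrangement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import BinTable
from .matrix_ops import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InsulationTrack",
    "Boundary",
    "TADSet",
    "TransitionEvent",
    "insulation_score",
    "call_boundaries",
    "derive_tads",
    "partition_boundary_interior",
    "classify_transitions",
]


@dataclass
class InsulationTrack:
    bins: BinTable
    raw: np.ndarray  # mean contact in the sliding square; NaN where invalid
    norm: np.ndarray  # log2(raw / chromosome mean of raw)
    valid: np.ndarray
    square_span: int

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.frame.copy()
        df["raw_insulation"] = self.raw
        df["norm_insulation"] = self.norm
        df["valid"] = self.valid
        return df


@dataclass(frozen=True)
class Boundary:
    bin_id: int
    chrom: str
    position: int  # bp, bin midpoint
    strength: float


@dataclass
class TADSet:
    tads: pd.DataFrame  # chrom,start,end[,score], ordered, non-overlapping
    boundaries: list[Boundary]
    bins: BinTable
    condition: str = ""
    flags: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tads)


@dataclass
class TransitionEvent:
    type: str  # Stable | Split | Merge | Rearrangement
    source: list[int]  # row indices into condition-1 TAD table
    target: list[int]
    overlap_bp: int


def _square_means(block: np.ndarray, mask: np.ndarray, w: int):
    """Mean and unmasked-cell fraction of the w x w square upstream-by-
    downstream of every bin, via summed-area tables."""
    n = block.shape[0]
    vals = np.where(np.outer(mask, mask), block, 0.0)
    cnts = np.outer(mask, mask).astype(float)
    # padded 2D prefix sums
    V = np.zeros((n + 1, n + 1))
    C = np.zeros((n + 1, n + 1))
    V[1:, 1:] = vals.cumsum(0).cumsum(1)
    C[1:, 1:] = cnts.cumsum(0).cumsum(1)

    def rect_sum(P, r0, r1, c0, c1):  # rows [r0,r1), cols [c0,c1)
        return P[r1, c1] - P[r0, c1] - P[r1, c0] + P[r0, c0]

    mean = np.full(n, np.nan)
    frac = np.zeros(n)
    for i in range(w, n - w):
        c = rect_sum(C, i - w, i, i + 1, i + w + 1)
        frac[i] = c / (w * w)
        if c > 0:
            mean[i] = rect_sum(V, i - w, i, i + 1, i + w + 1) / c
    return mean, frac


def insulation_score(m: ContactMatrix, square_span: int = 100_000,
                     delta_span: int = 40_000,
                     use_balanced: bool | None = None) -> InsulationTrack:
    """Sliding-square insulation score, per chromosome.

    ``square_span`` and ``delta_span`` are in bp and must be multiples of the
    bin size.  A bin is valid only when the full square fits inside the
    chromosome and at least 50% of the square's cells involve unmasked bins.
    Balanced counts are used when available.
    """
    bs = m.bins.bin_size
    if square_span % bs or delta_span % bs:
        raise ValueError("square_span and delta_span must be multiples of the bin size")
    w = square_span // bs
    if use_balanced is None:
        use_balanced = m.balanced is not None
    n = m.bins.n_bins
    raw = np.full(n, np.nan)
    norm = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for chrom in m.bins.chroms.names:
        lo, hi = m.bins.chrom_range(chrom)
        block = m.dense_cis(chrom, balanced=use_balanced)
        mean, frac = _square_means(block, m.mask[lo:hi], w)
        ok = np.isfinite(mean) & (frac >= 0.5) & m.mask[lo:hi]
        if ok.any():
            chrom_mean = np.nanmean(mean[ok])
            with np.errstate(divide="ignore"):
                nm = np.where(ok & (mean > 0) & (chrom_mean > 0),
                              np.log2(np.where(mean > 0, mean, 1.0) / chrom_mean),
                              np.nan)
            ok = ok & np.isfinite(nm)
            raw[lo:hi] = mean
            norm[lo:hi] = nm
            valid[lo:hi] = ok
    return InsulationTrack(bins=m.bins, raw=raw, norm=norm, valid=valid,
                           square_span=square_span)


def call_boundaries(ins: InsulationTrack, delta_span: int = 40_000,
                    min_strength: float = 0.1) -> list[Boundary]:
    """TAD boundaries from the insulation delta track.

    delta(i) = mean(norm over (i, i+d]) - mean(norm over [i-d, i)) with
    d = delta_span / bin_size.  A boundary is placed where delta crosses zero
    upward (the insulation valley floor); its strength is the delta amplitude
    (max delta over the right window minus min delta over the left window),
    reported only when >= ``min_strength``.
    """
    bins = ins.bins
    bs = bins.bin_size
    if delta_span % bs:
        raise ValueError("delta_span must be a multiple of the bin size")
    d = delta_span // bs
    out: list[Boundary] = []
    bf = bins.frame
    min_side = max(1, d // 2)  # tolerate masked-bin holes in the windows
    for chrom in bins.chroms.names:
        lo, hi = bins.chrom_range(chrom)
        nm = ins.norm[lo:hi]
        ok = ins.valid[lo:hi]
        nb = hi - lo
        delta = np.full(nb, np.nan)
        for i in range(d, nb - d):
            left = nm[i - d:i][ok[i - d:i]]
            right = nm[i + 1:i + d + 1][ok[i + 1:i + d + 1]]
            if ok[i] and len(left) >= min_side and len(right) >= min_side:
                delta[i] = right.mean() - left.mean()
        finite = np.flatnonzero(np.isfinite(delta))
        for p, q in zip(finite[:-1], finite[1:]):
            if q - p > d:  # too large a hole to localize a crossing
                continue
            if delta[p] <= 0 < delta[q]:
                # the upcrossing bin is the valley floor: at a domain
                # junction between bins k-1 and k the delta track is
                # antisymmetric around it, so the first positive-delta bin
                # is the junction bin itself
                i = int(q)
                right_max = np.nanmax(delta[q:min(nb, q + d + 1)])
                left_min = np.nanmin(delta[max(0, p - d):p + 1])
                strength = right_max - left_min
                if strength >= min_strength:
                    gid = lo + i
                    pos = int((bf["start"].iloc[gid] + bf["end"].iloc[gid]) // 2)
                    out.append(Boundary(bin_id=int(gid), chrom=chrom,
                                        position=pos, strength=float(strength)))
    # adjacent crossings may snap to the same valley floor: keep the strongest
    best: dict[int, Boundary] = {}
    for b in out:
        if b.bin_id not in best or b.strength > best[b.bin_id].strength:
            best[b.bin_id] = b
    return [best[k] for k in sorted(best)]


def derive_tads(boundaries: list[Boundary], bins: BinTable,
                min_tad_size: int = 3, condition: str = "") -> TADSet:
    """TADs as the inter-boundary intervals (including chromosome ends).

    Intervals shorter than ``min_tad_size`` bins are dropped with a log note;
    a chromosome with no boundary yields one whole-chromosome TAD, flagged.
    """
    rows = []
    flags: list[str] = []
    for chrom in bins.chroms.names:
        lo, hi = bins.chrom_range(chrom)
        length = bins.chroms.length(chrom)
        bnds = sorted(b.bin_id - lo for b in boundaries if b.chrom == chrom)
        if not bnds:
            flags.append(f"{chrom}: no boundaries, whole chromosome kept as one TAD")
            rows.append((chrom, 0, length))
            continue
        edges_bins = [0] + bnds + [hi - lo]
        bf = bins.frame
        for a, b in zip(edges_bins[:-1], edges_bins[1:]):
            if b - a < min_tad_size:
                logger.info("derive_tads: dropping %d-bin gap on %s", b - a, chrom)
                continue
            start = int(bf["start"].iloc[lo + a])
            end = int(bf["end"].iloc[lo + b - 1])
            rows.append((chrom, start, end))
    tads = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return TADSet(tads=tads, boundaries=list(boundaries), bins=bins,
                  condition=condition, flags=flags)


def partition_boundary_interior(t: TADSet, flank_bins: int = 1) -> np.ndarray:
    """Per-bin class: 'border' (boundary bin +/- flank), 'inter' (TAD bins
    not border), 'outside' (rest).  Border wins overlaps."""
    bins = t.bins
    cls = np.full(bins.n_bins, "outside", dtype=object)
    bf = bins.frame
    starts = bf["start"].to_numpy()
    ends = bf["end"].to_numpy()
    chrom_arr = bf["chrom"].to_numpy()
    for _, row in t.tads.iterrows():
        lo, hi = bins.chrom_range(row["chrom"])
        sel = slice(lo, hi)
        inside = (starts[sel] < row["end"]) & (ends[sel] > row["start"])
        cls[np.flatnonzero(inside) + lo] = "inter"
    for b in t.boundaries:
        lo, hi = bins.chrom_range(b.chrom)
        a = max(lo, b.bin_id - flank_bins)
        z = min(hi, b.bin_id + flank_bins + 1)
        cls[a:z] = "border"
    # keep chrom association implicit via bins
    del chrom_arr
    return cls


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify_transitions(t1: TADSet, t2: TADSet, stable_frac: float = 0.75,
                         member_frac: float = 0.75) -> tuple[list[TransitionEvent], dict]:
    """Classify TAD changes between two conditions into four classes.

    Connected components of the any-bp-overlap bipartite graph are
    classified: 1-vs-1 with reciprocal overlap strictly above ``stable_frac``
    for BOTH TADs -> Stable; 1-vs-k (k >= 2) where every target lies at least
    ``member_frac`` of its length inside the source -> Split; the mirror case
    -> Merge; everything else (including unmatched TADs) -> Rearrangement.
    Every TAD of both conditions appears in exactly one event.
    """
    for name, ts in (("condition 1", t1), ("condition 2", t2)):
        df = ts.tads.sort_values(["chrom", "start"])
        for chrom, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping TADs within {name} on {chrom}")

    a = t1.tads.reset_index(drop=True)
    b = t2.tads.reset_index(drop=True)
    # adjacency via per-chromosome sweep
    edges: dict[int, list[int]] = {i: [] for i in range(len(a))}
    redges: dict[int, list[int]] = {j: [] for j in range(len(b))}
    for chrom in set(a["chrom"]) | set(b["chrom"]):
        ai = a.index[a["chrom"] == chrom]
        bi = b.index[b["chrom"] == chrom]
        for i in ai:
            for j in bi:
                if _overlap(a.at[i, "start"], a.at[i, "end"],
                            b.at[j, "start"], b.at[j, "end"]) > 0:
                    edges[i].append(j)
                    redges[j].append(i)

    seen_a, seen_b = set(), set()
    events: list[TransitionEvent] = []

    def component(i0: int):
        qa, qb = {i0}, set()
        stack = [("a", i0)]
        while stack:
            side, k = stack.pop()
            if side == "a":
                for j in edges[k]:
                    if j not in qb:
                        qb.add(j)
                        stack.append(("b", j))
            else:
                for i in redges[k]:
                    if i not in qa:
                        qa.add(i)
                        stack.append(("a", i))
        return sorted(qa), sorted(qb)

    def classify(src: list[int], tgt: list[int]) -> str:
        if len(src) == 1 and len(tgt) == 1:
            i, j = src[0], tgt[0]
            ov = _overlap(a.at[i, "start"], a.at[i, "end"],
                          b.at[j, "start"], b.at[j, "end"])
            la = a.at[i, "end"] - a.at[i, "start"]
            lb = b.at[j, "end"] - b.at[j, "start"]
            if ov / la > stable_frac and ov / lb > stable_frac:
                return "Stable"
            return "Rearrangement"
        if len(src) == 1 and len(tgt) >= 2:
            i = src[0]
            if all(_overlap(a.at[i, "start"], a.at[i, "end"],
                            b.at[j, "start"], b.at[j, "end"])
                   >= member_frac * (b.at[j, "end"] - b.at[j, "start"])
                   for j in tgt):
                return "Split"
            return "Rearrangement"
        if len(tgt) == 1 and len(src) >= 2:
            j = tgt[0]
            if all(_overlap(a.at[i, "start"], a.at[i, "end"],
                            b.at[j, "start"], b.at[j, "end"])
                   >= member_frac * (a.at[i, "end"] - a.at[i, "start"])
                   for i in src):
                return "Merge"
            return "Rearrangement"
        return "Rearrangement"

    for i in range(len(a)):
        if i in seen_a:
            continue
        src, tgt = component(i)
        seen_a.update(src)
        seen_b.update(tgt)
        ov = sum(_overlap(a.at[x, "start"], a.at[x, "end"],
                          b.at[y, "start"], b.at[y, "end"])
                 for x in src for y in tgt)
        events.append(TransitionEvent(type=classify(src, tgt),
                                      source=src, target=tgt, overlap_bp=ov))
    for j in range(len(b)):
        if j not in seen_b:
            events.append(TransitionEvent(type="Rearrangement",
                                          source=[], target=[j], overlap_bp=0))
            seen_b.add(j)

    counts = {k: 0 for k in ("Stable", "Split", "Merge", "Rearrangement")}
    for ev in events:
        counts[ev.type] += 1
    return events, counts
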