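"""Synthetic Hi-C maps and matched tracks with known planted architecture.

The generator draws Poisson counts around a multiplicative rate model

    lambda(i, j) = B * (|i-j|*bin + d0)^(-alpha) * kappa^[same compartment]
                   * tau^[same TAD] * rho^[loop anchor pair] * b_i * b_j

so each architectural layer (checkerboard compartments, nested
self-interacting domains, point loops, per-bin biases, power-law decay) is
independently switchable.  Trans cells are Poisson at a uniform background
rate, modulated by kappa for same-compartment pairs.  The overall scale B is
calibrated so the expected total contact count equals the requested depth.
Every draw is seeded; identical seeds give bit-identical maps.

A perturbation step flips compartment blocks, splits/merges domains and
adds/removes loops, recording the planted truth so downstream recovery can
be scored exactly.  Matched gene/expression/peak tracks follow the effect
directions seen in nutrient-stress chromatin studies: the A compartment is
gene-dense and more expressed than B, TAD boundaries are expression- and
mark-enriched, and differentially expressed genes sit inside switched
regions.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome_io import ChromTable, BinTable, make_bins
from .matrix_ops import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ArchitectureSpec",
    "ArchitectureTruth",
    "PerturbationSpec",
    "default_architecture",
    "simulate_contact_map",
    "perturb_architecture",
    "simulate_tracks",
    "nd_reorg_pair",
]


@dataclass
class ArchitectureSpec:
    """Planted-architecture parameters for one condition's contact map."""

    chroms: ChromTable
    bin_size: int = 10_000
    # labeled compartment blocks tiling each chromosome: (chrom,start,end,label)
    compartment_blocks: list[tuple[str, int, int, str]] = field(default_factory=list)
    # self-interacting domains tiling each chromosome: (chrom,start,end)
    tads: list[tuple[str, int, int]] = field(default_factory=list)
    # loop anchors: (chrom, pos_i, pos_j, enrichment rho)
    loops: list[tuple[str, int, int, float]] = field(default_factory=list)
    alpha: float = 1.0  # decay exponent
    d0: float = 10_000.0  # decay offset, bp
    kappa: float = 1.5  # same-compartment contrast
    tau: float = 2.0  # within-TAD boost
    bias_sigma: float = 0.1  # lognormal spread of per-bin biases
    depth: float = 5e6  # expected total contact count
    trans_background: float = 0.05  # expected counts per trans cell
    seed: int = 0
    # biases model sequence-driven effects (mappability, GC), so they are
    # shared across conditions: drawn from their own seed, which a
    # perturbation never changes
    bias_seed: int | None = None

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.alpha <= 0:
            raise ValueError("decay exponent must be positive")
        for val, nm in ((self.kappa, "kappa"), (self.tau, "tau")):
            if val < 1:
                raise ValueError(f"{nm} must be >= 1")
        if any(r < 1 for *_, r in self.loops):
            raise ValueError("loop enrichment must be >= 1")
        for chrom, length in self.chroms.items():
            for name, items in (("compartment blocks",
                                 [(c, s, e) for c, s, e, _ in self.compartment_blocks]),
                                ("tads", self.tads)):
                ivs = sorted((s, e) for c, s, e in items if c == chrom)
                if not ivs:
                    continue
                if ivs[0][0] != 0 or ivs[-1][1] != length or any(
                        a[1] != b[0] for a, b in zip(ivs, ivs[1:])):
                    raise ValueError(f"{name} do not tile {chrom}")


@dataclass
class ArchitectureTruth:
    """The realized planted architecture, for recovery scoring."""

    spec: ArchitectureSpec
    bins: BinTable
    compartment_label: np.ndarray  # per generation-size bin, 'A'/'B'
    tad_intervals: pd.DataFrame  # chrom,start,end
    boundary_positions: pd.DataFrame  # chrom,pos (bp, internal TAD junctions)
    loops: list[tuple[str, int, int, float]]
    switches: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "kind"]))
    splits: list[tuple[str, int, int]] = field(default_factory=list)
    merges: list[tuple[str, int, int]] = field(default_factory=list)

    def labels_at(self, bin_size: int) -> np.ndarray:
        """Planted compartment label per bin at an analysis bin size
        (label of the block containing the bin midpoint)."""
        bins = make_bins(self.spec.chroms, bin_size)
        labels = np.full(bins.n_bins, "NA", dtype=object)
        mids = ((bins.frame["start"] + bins.frame["end"]) // 2).to_numpy()
        chroms = bins.frame["chrom"].to_numpy()
        for chrom, s, e, lab in self.spec.compartment_blocks:
            hit = (chroms == chrom) & (mids >= s) & (mids < e)
            labels[hit] = lab
        return labels


@dataclass
class PerturbationSpec:
    """Requested architectural changes between two conditions."""

    blocks_to_flip: list[int] = field(default_factory=list)  # block indices
    tads_to_split: list[int] = field(default_factory=list)  # tad indices
    tad_pairs_to_merge: list[tuple[int, int]] = field(default_factory=list)
    loops_to_add: list[tuple[str, int, int, float]] = field(default_factory=list)
    loops_to_remove: list[int] = field(default_factory=list)
    seed: int = 1


def default_architecture(n_chroms: int = 4, chrom_length: int = 2_000_000,
                         bin_size: int = 10_000, depth: float = 5e6,
                         kappa: float = 1.5, tau: float = 2.0,
                         seed: int = 0, **kw) -> ArchitectureSpec:
    """Desk-scale default genome: alternating 400-kb compartment blocks,
    domains subdividing every block, and a few point loops.

    The genome is deliberately small but each chromosome is >= 20x the
    100-kb insulation window, so boundary validity margins are exercised.
    """
    chroms = ChromTable.from_dict(
        {f"chr{i + 1}": chrom_length for i in range(n_chroms)})
    block_len = 400_000
    blocks, tads, loops = [], [], []
    # domain patterns per block, chosen so block edges are always domain edges
    patterns = [(200_000, 200_000), (160_000, 240_000), (400_000,)]
    for ci, (chrom, length) in enumerate(chroms.items()):
        lab = "A" if ci % 2 == 0 else "B"  # stagger start label per chromosome
        for k, s in enumerate(range(0, length, block_len)):
            e = min(s + block_len, length)
            blocks.append((chrom, s, e, lab))
            pos = s
            for span in patterns[k % len(patterns)]:
                tads.append((chrom, pos, min(pos + span, e)))
                pos += span
            lab = "B" if lab == "A" else "A"
        # two loops per chromosome between mid-block anchors
        loops.append((chrom, 250_000, 850_000, 8.0))
        loops.append((chrom, 1_050_000, 1_650_000, 8.0))
    spec = ArchitectureSpec(chroms=chroms, bin_size=bin_size,
                            compartment_blocks=blocks, tads=tads, loops=loops,
                            kappa=kappa, tau=tau, depth=depth, seed=seed,
                            bias_seed=kw.pop("bias_seed", 100_003 + seed), **kw)
    spec.validate()
    return spec


def _per_bin_annotation(spec: ArchitectureSpec, bins: BinTable):
    n = bins.n_bins
    label = np.full(n, "B", dtype=object)
    tad_id = np.full(n, -1, dtype=np.int64)
    mids = ((bins.frame["start"] + bins.frame["end"]) // 2).to_numpy()
    chroms = bins.frame["chrom"].to_numpy()
    for chrom, s, e, lab in spec.compartment_blocks:
        label[(chroms == chrom) & (mids >= s) & (mids < e)] = lab
    for t, (chrom, s, e) in enumerate(spec.tads):
        tad_id[(chroms == chrom) & (mids >= s) & (mids < e)] = t
    return label, tad_id


def simulate_contact_map(spec: ArchitectureSpec,
                         ) -> tuple[ContactMatrix, ArchitectureTruth]:
    """Draw one Poisson contact map from the planted-architecture model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bins = make_bins(spec.chroms, spec.bin_size)
    n = bins.n_bins
    label, tad_id = _per_bin_annotation(spec, bins)

    bias_rng = (np.random.default_rng(spec.bias_seed)
                if spec.bias_seed is not None else rng)
    bias = np.exp(bias_rng.normal(0.0, spec.bias_sigma, size=n)) \
        if spec.bias_sigma > 0 else np.ones(n)
    bias /= bias.mean()

    # unit-rate cis layers per chromosome (B factored out for calibration)
    unit_blocks = {}
    cis_unit_total = 0.0
    for chrom in spec.chroms.names:
        lo, hi = bins.chrom_range(chrom)
        nb = hi - lo
        d = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
        rate = (d * spec.bin_size + spec.d0) ** (-spec.alpha)
        np.fill_diagonal(rate, 0.0)  # self-bin ligation filtered upstream
        lab = label[lo:hi]
        rate *= np.where(lab[:, None] == lab[None, :], spec.kappa, 1.0)
        tid = tad_id[lo:hi]
        same_tad = (tid[:, None] == tid[None, :]) & (tid[:, None] >= 0)
        rate *= np.where(same_tad, spec.tau, 1.0)
        for lchrom, pi, pj, rho in spec.loops:
            if lchrom != chrom:
                continue
            bi = int(bins.bin_id(chrom, pi) - lo)
            bj = int(bins.bin_id(chrom, pj) - lo)
            rate[bi, bj] *= rho
            rate[bj, bi] *= rho
        rate *= np.outer(bias[lo:hi], bias[lo:hi])
        unit_blocks[chrom] = rate
        cis_unit_total += np.triu(rate, 1).sum()

    # expected trans total (not scaled by B)
    trans_expected = 0.0
    names = spec.chroms.names
    trans_rates = {}
    for x in range(len(names)):
        lo1, hi1 = bins.chrom_range(names[x])
        for y in range(x + 1, len(names)):
            lo2, hi2 = bins.chrom_range(names[y])
            same = label[lo1:hi1, None] == label[None, lo2:hi2]
            r = spec.trans_background * np.where(same, spec.kappa, 1.0)
            r = r * np.outer(bias[lo1:hi1], bias[lo2:hi2])
            trans_rates[(names[x], names[y])] = r
            trans_expected += r.sum()

    B = (spec.depth - trans_expected) / cis_unit_total
    if B <= 0:
        raise ValueError("infeasible depth: trans background alone exceeds it")

    mat = sp.lil_matrix((n, n))
    for chrom in names:
        lo, hi = bins.chrom_range(chrom)
        nb = hi - lo
        lam = B * unit_blocks[chrom]
        iu, ju = np.triu_indices(nb, k=1)
        draws = rng.poisson(lam[iu, ju])
        dense = np.zeros((nb, nb))
        dense[iu, ju] = draws
        dense += dense.T
        mat[lo:hi, lo:hi] = dense
    for (c1, c2), r in trans_rates.items():
        lo1, hi1 = bins.chrom_range(c1)
        lo2, hi2 = bins.chrom_range(c2)
        draws = rng.poisson(r)
        mat[lo1:hi1, lo2:hi2] = draws
        mat[lo2:hi2, lo1:hi1] = draws.T
    counts = mat.tocsr()

    tad_df = pd.DataFrame(spec.tads, columns=["chrom", "start", "end"])
    bnd_rows = []
    for chrom in names:
        edges = sorted({s for c, s, e in spec.tads if c == chrom} |
                       {e for c, s, e in spec.tads if c == chrom})
        for pos in edges[1:-1]:  # internal junctions only
            bnd_rows.append((chrom, int(pos)))
    truth = ArchitectureTruth(
        spec=spec, bins=bins, compartment_label=label,
        tad_intervals=tad_df,
        boundary_positions=pd.DataFrame(bnd_rows, columns=["chrom", "pos"]),
        loops=list(spec.loops))
    m = ContactMatrix(bins=bins, counts=counts, mask=np.ones(n, dtype=bool),
                      metadata={"bin_size": spec.bin_size,
                                "depth": spec.depth, "seed": spec.seed,
                                "true_bias": bias})
    return m, truth


def perturb_architecture(truth: ArchitectureTruth, pert: PerturbationSpec,
                         ) -> tuple[ArchitectureSpec, ArchitectureTruth]:
    """Apply exactly the requested flips/splits/merges to a base truth.

    Returns the perturbed condition's spec plus its truth, whose switch
    list records the flipped blocks and whose split/merge lists record the
    planted TAD events.  Unperturbed elements are untouched.
    """
    base = truth.spec
    spec = copy.deepcopy(base)
    spec.seed = pert.seed

    switch_rows = []
    for bi in pert.blocks_to_flip:
        if not (0 <= bi < len(spec.compartment_blocks)):
            raise ValueError(f"block index {bi} out of range")
        chrom, s, e, lab = spec.compartment_blocks[bi]
        new = "B" if lab == "A" else "A"
        spec.compartment_blocks[bi] = (chrom, s, e, new)
        switch_rows.append((chrom, s, e, f"{lab}-{new}"))

    splits, merges = [], []
    tads = list(spec.tads)
    for ti in pert.tads_to_split:
        if not (0 <= ti < len(base.tads)):
            raise ValueError(f"tad index {ti} out of range")
        chrom, s, e = base.tads[ti]
        mid = s + ((e - s) // 2 // spec.bin_size) * spec.bin_size
        if not (s < mid < e):
            raise ValueError(f"tad {ti} too short to split")
        tads[tads.index((chrom, s, e))] = (chrom, s, mid)
        tads.append((chrom, mid, e))
        splits.append((chrom, s, e))
    for ti, tj in pert.tad_pairs_to_merge:
        for k in (ti, tj):
            if not (0 <= k < len(base.tads)):
                raise ValueError(f"tad index {k} out of range")
        (c1, s1, e1), (c2, s2, e2) = base.tads[ti], base.tads[tj]
        if c1 != c2 or (e1 != s2 and e2 != s1):
            raise ValueError(f"tads {ti},{tj} are not adjacent")
        s, e = min(s1, s2), max(e1, e2)
        tads.remove((c1, s1, e1))
        tads.remove((c2, s2, e2))
        tads.append((c1, s, e))
        merges.append((c1, s, e))
    spec.tads = sorted(tads)

    loops = list(spec.loops)
    for li in sorted(pert.loops_to_remove, reverse=True):
        if not (0 <= li < len(base.loops)):
            raise ValueError(f"loop index {li} out of range")
        loops.pop(li)
    loops.extend(pert.loops_to_add)
    spec.loops = loops
    spec.validate()

    bins = truth.bins
    label, _ = _per_bin_annotation(spec, bins)
    tad_df = pd.DataFrame(spec.tads, columns=["chrom", "start", "end"])
    bnd_rows = []
    for chrom in spec.chroms.names:
        edges = sorted({s for c, s, e in spec.tads if c == chrom} |
                       {e for c, s, e in spec.tads if c == chrom})
        for pos in edges[1:-1]:
            bnd_rows.append((chrom, int(pos)))
    new_truth = ArchitectureTruth(
        spec=spec, bins=bins, compartment_label=label,
        tad_intervals=tad_df,
        boundary_positions=pd.DataFrame(bnd_rows, columns=["chrom", "pos"]),
        loops=list(spec.loops),
        switches=pd.DataFrame(switch_rows,
                              columns=["chrom", "start", "end", "kind"]),
        splits=splits, merges=merges)
    return spec, new_truth


def simulate_tracks(truth: ArchitectureTruth, n_genes: int = 1000,
                    gene_density_ratio_A_over_B: float = 2.0,
                    expr_log2_shift_A: float = 1.0,
                    expr_log2_shift_boundary: float = 0.5,
                    boundary_peak_boost: float = 3.0,
                    de_effect_log2: float = 2.0,
                    replicates: int = 2, mean_depth_per_gene: float = 50.0,
                    nb_dispersion: float = 0.1,
                    marks: tuple[str, ...] = ("H3K27ac", "H3K36me2", "Kcr"),
                    peak_rate: float = 0.1, seed: int = 0):
    """Matched gene / expression / peak tracks for a (base, perturbed) pair.

    Genes are placed with inhomogeneous density (A-compartment bins richer
    by the stated ratio); log2 abundances are normal with the A shift and a
    boundary-proximity shift; counts are negative-binomial per replicate for
    two conditions; genes inside switched regions get the stated DE effect
    in condition 2.  Peaks are Bernoulli per bin with boundary and
    A-compartment boosts, one set per mark per condition.

    Returns a dict with genes, expression (cond1/cond2 replicate columns),
    peaks (list of PeakSet) and the DE-truth gene table.
    """
    from .integration import PeakSet  # local import avoids a cycle

    for val, nm in ((gene_density_ratio_A_over_B, "gene density ratio"),
                    (boundary_peak_boost, "peak boost")):
        if val < 0:
            raise ValueError(f"{nm} must be >= 0")
    rng = np.random.default_rng(seed)
    bins = truth.bins
    n = bins.n_bins
    bf = bins.frame

    boundary_bins = np.zeros(n, dtype=bool)
    for chrom, pos in zip(truth.boundary_positions["chrom"],
                          truth.boundary_positions["pos"]):
        lo, hi = bins.chrom_range(chrom)
        b = int(bins.bin_id(chrom, min(pos, bins.chroms.length(chrom) - 1)))
        boundary_bins[max(lo, b - 1):min(hi, b + 2)] = True

    is_a = truth.compartment_label == "A"
    w = np.where(is_a, gene_density_ratio_A_over_B, 1.0)
    w = w / w.sum()
    gene_bins = rng.choice(n, size=n_genes, replace=True, p=w)
    gene_bins.sort()
    starts = (bf["start"].to_numpy()[gene_bins]
              + rng.integers(0, np.maximum(
                  (bf["end"] - bf["start"]).to_numpy()[gene_bins] - 1000, 1)))
    genes = pd.DataFrame({
        "chrom": bf["chrom"].to_numpy()[gene_bins],
        "start": starts,
        "end": starts + 1000,
        "name": [f"g{i:05d}" for i in range(n_genes)],
        "strand": rng.choice(["+", "-"], size=n_genes),
    })

    log2_mu = rng.normal(5.0, 1.0, size=n_genes)
    log2_mu += np.where(is_a[gene_bins], expr_log2_shift_A, 0.0)
    log2_mu += np.where(boundary_bins[gene_bins], expr_log2_shift_boundary, 0.0)

    # DE truth: genes whose bin midpoint lies in a switched region
    de_sign = np.zeros(n_genes)
    mids = ((genes["start"] + genes["end"]) // 2).to_numpy()
    for chrom, s, e, kind in zip(truth.switches.get("chrom", []),
                                 truth.switches.get("start", []),
                                 truth.switches.get("end", []),
                                 truth.switches.get("kind", [])):
        hit = (genes["chrom"].to_numpy() == chrom) & (mids >= s) & (mids < e)
        de_sign[hit] = de_effect_log2 if kind == "B-A" else -de_effect_log2

    mu1 = 2.0 ** log2_mu
    mu2 = 2.0 ** (log2_mu + de_sign)
    scale1 = mean_depth_per_gene / mu1.mean()
    # same per-read scale both conditions: depth differences are normalized out
    expr = {"gene_id": genes["name"]}
    r = 1.0 / nb_dispersion
    for cond, mu in (("cond1", mu1 * scale1), ("cond2", mu2 * scale1)):
        for rep in range(replicates):
            p = r / (r + mu)
            expr[f"{cond}_rep{rep + 1}"] = rng.negative_binomial(r, p)
    expression = pd.DataFrame(expr)

    peaks = []
    base_p = np.clip(peak_rate * np.where(is_a, 2.0, 1.0)
                     * np.where(boundary_bins, boundary_peak_boost, 1.0), 0, 0.95)
    for cond in ("cond1", "cond2"):
        for mark in marks:
            hit = rng.random(n) < base_p
            iv = bf.loc[hit, ["chrom", "start", "end"]].reset_index(drop=True)
            peaks.append(PeakSet(mark=mark, condition=cond, intervals=iv))

    de_truth = pd.DataFrame({
        "gene_id": genes["name"],
        "planted_log2fc": de_sign,
        "planted_status": np.where(de_sign > 0, "up",
                                   np.where(de_sign < 0, "down", "ns")),
    })
    return {"genes": genes, "expression": expression, "peaks": peaks,
            "de_truth": de_truth}


def nd_reorg_pair(seed: int = 0, depth: float = 5e6, n_chroms: int = 4,
                  chrom_length: int = 2_000_000, bin_size: int = 10_000,
                  **kw):
    """The default two-condition study: a base map plus a perturbed map with
    flipped compartment blocks, split and merged domains, and loop changes —
    a desk-scale stand-in for a nutrient-stress reorganization experiment.

    Returns (map1, truth1, map2, truth2, perturbation).
    """
    spec = default_architecture(n_chroms=n_chroms, chrom_length=chrom_length,
                                bin_size=bin_size, depth=depth,
                                seed=seed, **kw)
    m1, t1 = simulate_contact_map(spec)
    n_blocks_per_chrom = chrom_length // 400_000
    # flip one interior block per chromosome; split/merge domains picked from
    # the two-domain blocks so tiling and block edges are preserved
    flips = [c * n_blocks_per_chrom + 2 for c in range(n_chroms)]
    tad_index = {t: i for i, t in enumerate(spec.tads)}
    splits, merges = [], []
    for chrom, length in spec.chroms.items():
        # block 0 pattern (200k, 200k): merge those two domains
        merges.append((tad_index[(chrom, 0, 200_000)],
                       tad_index[(chrom, 200_000, 400_000)]))
        # block 2 pattern (400k,): split the single 400-kb domain
        splits.append(tad_index[(chrom, 800_000, 1_200_000)])
    pert = PerturbationSpec(blocks_to_flip=flips, tads_to_split=splits,
                            tad_pairs_to_merge=merges,
                            loops_to_remove=[0],
                            loops_to_add=[(spec.chroms.names[0],
                                           450_000, 1_250_000, 8.0)],
                            seed=seed + 1)
    spec2, t2 = perturb_architecture(t1, pert)  # t2 carries switch/split/merge truth
    m2, _ = simulate_contact_map(spec2)
    return m1, t1, m2, t2, pert
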