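"""Shared fixtures: small genomes and the analyzed default synthetic pair."""

import numpy as np
import pytest

from chromarch.genome_io import ChromTable, make_bins
from chromarch import matrix_ops as mo, tads as td
from chromarch.synthetic import nd_reorg_pair


@pytest.fixture(scope="session")
def small_chroms():
    return ChromTable.from_dict({"chr1": 1_000_000, "chr2": 600_000})


@pytest.fixture(scope="session")
def small_bins(small_chroms):
    return make_bins(small_chroms, 100_000)


@pytest.fixture(scope="session")
def nd_pair():
    """Default two-condition synthetic study (base + perturbed), raw maps."""
    return nd_reorg_pair(seed=0)


@pytest.fixture(scope="session")
def nd_pair_analyzed(nd_pair):
    """Balanced matrices, insulation tracks, boundaries and TAD sets for the
    default pair."""
    m1, t1, m2, t2, pert = nd_pair
    out = {}
    for name, m, tr in (("c1", m1, t1), ("c2", m2, t2)):
        mb = mo.ice_balance(mo.mask_low_coverage(m))
        ins = td.insulation_score(mb, 100_000, 40_000)
        bnds = td.call_boundaries(ins, 40_000, 0.1)
        tset = td.derive_tads(bnds, mb.bins)
        out[name] = {"matrix": mb, "truth": tr, "insulation": ins,
                     "boundaries": bnds, "tads": tset}
    return out


def boundary_recall(boundaries, truth, bins, tol_bins=1):
    """Fraction of planted boundaries with a called boundary within tol."""
    called = {(b.chrom, b.bin_id - bins.offsets[b.chrom]) for b in boundaries}
    hits = 0
    for chrom, pos in zip(truth.boundary_positions["chrom"],
                          truth.boundary_positions["pos"]):
        k = pos // bins.bin_size
        hits += any((chrom, k + o) in called
                    for o in range(-tol_bins, tol_bins + 1))
    return hits / len(truth.boundary_positions)
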