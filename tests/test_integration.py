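import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromarch.genome_io import ChromTable, make_bins
from chromarch import integration as ig
from chromarch import compartments as cp
from chromarch import tads as td
from chromarch.synthetic import nd_reorg_pair, simulate_tracks


class TestExpressionCompare:
    def test_identical_classes_p_one(self):
        v = np.full(20, 3.0)
        res = ig.expression_compare(v, v)
        assert res["p_value"] == 1.0

    def test_same_sample_both_sides_p_one(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(3, 1, 40)
        res = ig.expression_compare(v, v)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["median_a"] == res["median_b"]

    def test_planted_shift_detected_with_direction(self):
        rng = np.random.default_rng(1)
        a = 2.0 ** rng.normal(6, 1, 500)
        b = 2.0 ** rng.normal(5, 1, 500)
        res = ig.expression_compare(a, b)
        assert res["p_value"] < 0.001
        assert res["median_a"] > res["median_b"]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ig.expression_compare(np.array([]), np.ones(3))

    def test_null_pvalues_uniform_under_permutation(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(3, 1, 60)
        ps = []
        for _ in range(1000):
            perm = rng.permutation(vals)
            ps.append(ig.expression_compare(perm[:30], perm[30:])["p_value"])
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.05


class TestDegCallSimple:
    def mk_expr(self, c1, c2):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(c1))],
            "a_rep1": [x[0] for x in c1], "a_rep2": [x[1] for x in c1],
            "b_rep1": [x[0] for x in c2], "b_rep2": [x[1] for x in c2],
        })

    def test_threshold_gates(self):
        # a strong 4x gene passes; a 1.5x gene never does regardless of p
        base = [(1000, 1000)] * 40
        c2 = [(1000, 1000)] * 40
        base += [(500, 500), (1000, 1000)]
        c2 += [(2000, 2000), (1500, 1500)]
        degs = ig.deg_call_simple(self.mk_expr(base, c2),
                                  ["a_rep1", "a_rep2"], ["b_rep1", "b_rep2"])
        assert degs.iloc[-2]["status"] == "up"
        assert degs.iloc[-1]["status"] == "ns"

    def test_all_zero_gene_flagged_ns(self):
        degs = ig.deg_call_simple(self.mk_expr([(0, 0), (50, 60)],
                                               [(0, 0), (55, 45)]),
                                  ["a_rep1", "a_rep2"], ["b_rep1", "b_rep2"])
        assert degs.iloc[0]["status"] == "ns" and degs.iloc[0]["all_zero"]

    def test_planted_up_genes_recalled(self):
        *_, t2, _ = nd_reorg_pair(seed=0)
        tracks = simulate_tracks(t2, seed=100)
        degs = ig.deg_call_simple(tracks["expression"],
                                  ["cond1_rep1", "cond1_rep2"],
                                  ["cond2_rep1", "cond2_rep2"])
        up = (tracks["de_truth"]["planted_status"] == "up").to_numpy()
        assert up.sum() >= 50
        assert (degs.loc[up, "status"] == "up").mean() >= 0.9


def hypergeom_fisher_oracle(t11, t12, t21, t22):
    """Two-sided Fisher p by direct enumeration of the hypergeometric."""
    n = t11 + t12 + t21 + t22
    row1 = t11 + t12
    col1 = t11 + t21
    rv = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    cutoff = rv.pmf(t11) * (1 + 1e-7)
    return probs[probs <= cutoff].sum()


class TestDegRegionEnrichment:
    def setup_universe(self, rng, n=400, frac_inside=0.25, up_inside_only=False):
        genes = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
            "name": [f"g{i}" for i in range(n)],
        })
        cut = int(n * frac_inside)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                "end": [cut * 1000], "category": ["B-A"]})
        if up_inside_only:
            status = np.where(np.arange(n) < cut, "up", "ns")
        else:
            status = rng.choice(["up", "ns"], size=n, p=[0.2, 0.8])
        degs = pd.DataFrame({"gene_id": genes["name"], "status": status,
                             "log2_fold_change": 0.0, "p_value": 1.0})
        return degs, regions, genes

    def test_uniform_degs_odds_ratio_near_one(self):
        rng = np.random.default_rng(3)
        ors = []
        for _ in range(20):
            degs, regions, genes = self.setup_universe(rng)
            out = ig.deg_region_enrichment(degs, regions, genes)
            row = out[(out["category"] == "B-A") & (out["direction"] == "up")]
            ors.append(row["odds_ratio"].iloc[0])
        assert 0.7 < np.median(ors) < 1.4

    def test_concentrated_degs_enriched(self):
        rng = np.random.default_rng(4)
        degs, regions, genes = self.setup_universe(rng, up_inside_only=True)
        out = ig.deg_region_enrichment(degs, regions, genes)
        row = out[(out["category"] == "B-A") & (out["direction"] == "up")].iloc[0]
        assert row["p_value"] < 0.01 and row["odds_ratio"] > 1

    def test_zero_degs_degenerate_flagged(self):
        rng = np.random.default_rng(5)
        degs, regions, genes = self.setup_universe(rng)
        degs["status"] = "ns"
        out = ig.deg_region_enrichment(degs, regions, genes)
        assert out["degenerate"].all()
        assert out["odds_ratio"].isna().all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ig.deg_region_enrichment(pd.DataFrame({"gene_id": [], "status": []}),
                                     pd.DataFrame({"chrom": [], "start": [],
                                                   "end": [], "category": []}),
                                     pd.DataFrame(columns=["chrom", "start",
                                                           "end", "name"]))

    @pytest.mark.parametrize("table", [
        (12, 30, 50, 300), (1, 9, 11, 3), (0, 5, 8, 9), (40, 2, 3, 50)])
    def test_fisher_matches_hypergeometric_oracle(self, table):
        t11, t12, t21, t22 = table
        _, p = stats.fisher_exact([[t11, t12], [t21, t22]],
                                  alternative="two-sided")
        assert abs(p - hypergeom_fisher_oracle(*table)) < 1e-10


def peakset(mark, cond, rows):
    return ig.PeakSet(mark=mark, condition=cond,
                      intervals=pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestPeakGainLoss:
    @pytest.fixture()
    def switch(self):
        bins = make_bins(ChromTable.from_dict({"chr1": 400_000}), 100_000)
        cat = np.array(["A-A", "A-B", "B-A", "B-B"], dtype=object)
        return cp.SwitchTrack(bins=bins, category=cat,
                              regions=pd.DataFrame(), summary={})

    def test_gain_only_in_condition_two(self, switch):
        p1 = peakset("H3K27ac", "c1", [])
        p2 = peakset("H3K27ac", "c2", [("chr1", 120_000, 130_000)])
        events, counts = ig.peak_gain_loss(p1, p2, switch)
        assert len(events) == 1
        assert events.iloc[0]["change"] == "gain"
        assert events.iloc[0]["category"] == "A-B"

    def test_one_bp_overlap_is_neither(self, switch):
        p1 = peakset("Kcr", "c1", [("chr1", 100, 200)])
        p2 = peakset("Kcr", "c2", [("chr1", 199, 300)])
        events, _ = ig.peak_gain_loss(p1, p2, switch)
        assert len(events) == 0

    def test_mark_mismatch_rejected(self, switch):
        with pytest.raises(ValueError):
            ig.peak_gain_loss(peakset("Kcr", "c1", []),
                              peakset("H3K27ac", "c2", []), switch)

    def test_gains_equal_mirrored_losses(self, switch):
        rng = np.random.default_rng(6)
        def rand_peaks(mark, cond, n):
            starts = rng.integers(0, 390_000, n)
            return peakset(mark, cond,
                           [("chr1", int(s), int(s + 5000)) for s in starts])
        p1 = rand_peaks("Kcr", "c1", 20)
        p2 = rand_peaks("Kcr", "c2", 25)
        ev12, _ = ig.peak_gain_loss(p1, p2, switch)
        ev21, _ = ig.peak_gain_loss(p2, p1, switch)
        gains12 = ev12[ev12["change"] == "gain"][["chrom", "start", "end"]]
        losses21 = ev21[ev21["change"] == "loss"][["chrom", "start", "end"]]
        pd.testing.assert_frame_equal(gains12.reset_index(drop=True),
                                      losses21.reset_index(drop=True))


class TestBoundaryPeakProfile:
    def make_tads(self, boundary_bins):
        bins = make_bins(ChromTable.from_dict({"chr1": 1_000_000}), 10_000)
        bnds = [td.Boundary(b, "chr1", b * 10_000 + 5000, 1.0)
                for b in boundary_bins]
        return td.derive_tads(bnds, bins)

    def test_peaks_at_boundaries_peak_at_offset_zero(self):
        tads = self.make_tads([30, 60])
        peaks = peakset("Kcr", "c1", [("chr1", 300_000, 310_000),
                                      ("chr1", 600_000, 610_000)])
        prof = ig.boundary_peak_profile(peaks, tads, window=5)
        prof = prof.set_index("offset_bins")
        assert prof.loc[0, "mean_coverage"] == pytest.approx(1.0)
        assert prof.drop(index=0)["mean_coverage"].max() == 0

    def test_no_peaks_all_zero(self):
        tads = self.make_tads([50])
        prof = ig.boundary_peak_profile(peakset("Kcr", "c1", []), tads)
        assert (prof["mean_coverage"] == 0).all()

    def test_uniform_peaks_flat_profile(self):
        rng = np.random.default_rng(7)
        tads = self.make_tads([25, 50, 75])
        starts = rng.integers(0, 995_000, 300)
        peaks = peakset("Kcr", "c1",
                        [("chr1", int(s), int(s + 2000)) for s in starts])
        prof = ig.boundary_peak_profile(peaks, tads, window=8)
        cov = prof["mean_coverage"]
        assert cov.std() < 0.25 * cov.mean() + 0.05
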