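import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.io_formats import MISSING, ValidationError
from sweepscan.scan import (
    ScanThresholds,
    Window,
    candidate_windows,
    fst_site,
    log2_pi_ratio,
    make_windows,
    merge_regions,
    percentile_cutoffs,
    pi_pairwise_site,
    scan_windows,
    window_fst,
    window_pi,
)

from conftest import make_gm, split_popmap
from oracles import pi_site_oracle, window_fst_oracle, window_pi_oracle


class TestFstSite:
    @pytest.mark.parametrize(
        "pa,pb,expected",
        [
            (0.5, 0.5, 0.0),
            (0.5, 0.0, 1.0),  # 0.25 / 0.25
            (1.0, 0.0, 1.0),  # fixed difference convention
            (0.3, 0.3, 0.0),
            (0.9, 0.1, 1.0),  # raw value 3.56, clipped
        ],
    )
    def test_values(self, pa, pb, expected):
        assert fst_site(pa, pb) == pytest.approx(expected)

    def test_both_fixed_same_allele_undefined(self):
        assert np.isnan(fst_site(1.0, 1.0))
        assert np.isnan(fst_site(0.0, 0.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fst_site(1.2, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_symmetric(self, pa, pb):
        a, b = fst_site(pa, pb), fst_site(pb, pa)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestPiSite:
    def test_monomorphic_zero(self):
        assert pi_pairwise_site([1, 1, 1]) == 0.0
        assert pi_pairwise_site([2, 2]) == 0.0

    def test_opposite_homozygotes(self):
        # n=2: d12 = 1, pi = 1/(2*1) * 1
        assert pi_pairwise_site([0, 2]) == pytest.approx(0.5)

    def test_fewer_than_two_calls_undefined(self):
        assert np.isnan(pi_pairwise_site([1, MISSING]))

    def test_matches_pair_sum_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(2, 9)
            d = rng.choice([0, 1, 2, MISSING], size=n, p=[0.3, 0.3, 0.3, 0.1])
            if (d != MISSING).sum() < 2:
                continue
            assert pi_pairwise_site(d) == pytest.approx(pi_site_oracle(d), abs=1e-12)


class TestLog2Ratio:
    def test_equal_diversity_zero(self):
        assert log2_pi_ratio(3e-4, 3e-4) == 0.0

    def test_doubling_gives_one(self):
        assert log2_pi_ratio(2e-4, 1e-4) == pytest.approx(1.0)

    def test_zero_diversity_tails(self):
        assert log2_pi_ratio(1e-4, 0.0) == np.inf
        assert log2_pi_ratio(0.0, 1e-4) == -np.inf
        assert np.isnan(log2_pi_ratio(0.0, 0.0))

    @given(st.floats(1e-8, 1.0), st.floats(1e-8, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric(self, a, b):
        assert log2_pi_ratio(a, b) == pytest.approx(-log2_pi_ratio(b, a))


class TestMakeWindows:
    def test_100kb_chromosome(self):
        ws = make_windows({"c": 100_000}, 50_000, 25_000)
        assert [(w.start, w.end) for w in ws] == [
            (0, 50_000), (25_000, 75_000), (50_000, 100_000), (75_000, 100_000)
        ]

    def test_truncation(self):
        ws = make_windows({"c": 40_000}, 50_000, 25_000)
        assert [(w.start, w.end) for w in ws] == [(0, 40_000), (25_000, 40_000)]

    def test_chromosome_shorter_than_step(self):
        ws = make_windows({"c": 9_000}, 50_000, 25_000)
        assert [(w.start, w.end) for w in ws] == [(0, 9_000)]

    def test_empty_input(self):
        assert make_windows({}) == []

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValidationError):
            make_windows({"c": 100_000}, 10_000, 20_000)


class TestWindowStats:
    def _random_case(self, seed):
        rng = np.random.default_rng(seed)
        m = 100
        pos = np.sort(rng.choice(np.arange(1, 50_001), size=m, replace=False))
        dosage = rng.choice([0, 1, 2, MISSING], size=(20, m), p=[0.35, 0.3, 0.3, 0.05])
        gm = make_gm(dosage.astype(np.int8), positions=pos)
        pm = split_popmap(gm, 10)
        return gm, pm

    def test_window_fst_matches_oracle(self):
        for seed in range(5):
            gm, pm = self._random_case(seed)
            windows = make_windows({"chr1": 50_000}, 20_000, 10_000)
            vals, _ = window_fst(gm, pm, windows)
            ia, ib = pm.indices(gm.samples, "A"), pm.indices(gm.samples, "B")
            pos = gm.sites["pos"].to_numpy()
            for w, v in zip(windows, vals):
                expected = window_fst_oracle(
                    gm.dosage[ia], gm.dosage[ib], pos, w.start, w.end
                )
                if np.isnan(expected):
                    assert np.isnan(v)
                else:
                    assert v == pytest.approx(expected, abs=1e-12)

    def test_window_pi_matches_oracle(self):
        for seed in range(5):
            gm, pm = self._random_case(seed + 10)
            windows = make_windows({"chr1": 50_000}, 20_000, 10_000)
            ia = pm.indices(gm.samples, "A")
            vals = window_pi(gm, ia, windows)
            pos = gm.sites["pos"].to_numpy()
            for w, v in zip(windows, vals):
                assert v == pytest.approx(
                    window_pi_oracle(gm.dosage[ia], pos, w.start, w.end), abs=1e-12
                )

    def test_min_snps_rule(self):
        gm = make_gm(np.array([[0, 2], [1, 1], [2, 0], [0, 0]], dtype=np.int8),
                     positions=[100, 200])
        pm = split_popmap(gm, 2)
        vals, _ = window_fst(gm, pm, [Window("chr1", 0, 1000)], min_snps=3)
        assert np.isnan(vals[0])
        vals, _ = window_fst(gm, pm, [Window("chr1", 0, 1000)], min_snps=2)
        assert np.isfinite(vals[0])

    def test_single_site_pi_per_bp(self):
        """pi = 0.5 at one site in a 50-kb window → 1e-5 per bp."""
        col = np.array([[0], [2]], dtype=np.int8)
        gm = make_gm(col, positions=[25_000], samples=["x", "y"])
        vals = window_pi(gm, np.array([0, 1]), [Window("chr1", 0, 50_000)])
        assert vals[0] == pytest.approx(1.0e-5)

    def test_scan_invariant_to_sample_order(self, two_pop_sim):
        gm, pm, _ = two_pop_sim
        res1 = scan_windows(gm, pm, chrom_lengths={"chr1": 50_000_000})
        order = list(reversed(gm.samples))
        gm2 = gm.take_samples(order)
        res2 = scan_windows(gm2, pm, chrom_lengths={"chr1": 50_000_000})
        pd.testing.assert_frame_equal(res1.table, res2.table)


class TestPercentiles:
    def test_top_five_percent_of_1_to_100(self):
        values = np.arange(1, 101, dtype=float)
        thr = percentile_cutoffs(values, 0.05, "top")
        assert thr == pytest.approx(95.05)
        assert (values > thr).sum() == 5

    def test_bottom_tail_of_1_to_200(self):
        values = np.arange(1, 201, dtype=float)
        thr = percentile_cutoffs(values, 0.025, "bottom")
        assert thr == pytest.approx(5.975)
        assert set(values[values < thr]) == {1, 2, 3, 4, 5}

    def test_all_equal_selects_nothing(self):
        values = np.full(50, 7.0)
        thr = percentile_cutoffs(values, 0.05, "top")
        assert (values > thr).sum() == 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            percentile_cutoffs(np.arange(10, dtype=float), 0.05, "top")


def _stats_result(fst, ratio):
    n = len(fst)
    from sweepscan.scan import ScanResult

    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 25_000,
            "end": np.arange(n) * 25_000 + 50_000,
            "n_snps": 10,
            "fst": fst,
            "pi_A": 1e-4,
            "pi_B": 1e-4,
            "log2_ratio": ratio,
        }
    )
    return ScanResult(table=table, pop_a="A", pop_b="B")


class TestCandidates:
    def test_intersection_logic(self):
        rng = np.random.default_rng(0)
        n = 1000
        fst = rng.random(n)
        ratio = rng.normal(size=n)
        # plant one window in both upper tails and one in fst-top only
        fst[0], ratio[0] = 2.0, 100.0
        fst[1], ratio[1] = 2.0, 0.0
        res = _stats_result(fst, ratio)
        sel_b, sel_a, info = candidate_windows(res)
        assert 0 in sel_b.index or res.table.loc[0, "start"] in set(sel_b["start"])
        assert res.table.loc[1, "start"] not in set(sel_b["start"]) | set(sel_a["start"])

    def test_infinite_ratio_always_in_tail(self):
        rng = np.random.default_rng(1)
        n = 500
        fst = rng.random(n)
        ratio = rng.normal(size=n)
        fst[3], ratio[3] = 2.0, np.inf
        fst[4], ratio[4] = 2.0, -np.inf
        sel_b, sel_a, _ = candidate_windows(_stats_result(fst, ratio))
        assert _stats_result(fst, ratio).table.loc[3, "start"] in set(sel_b["start"])
        assert _stats_result(fst, ratio).table.loc[4, "start"] in set(sel_a["start"])

    def test_null_candidate_fraction_bounded(self, two_pop_sim):
        """Without sweeps the intersection can only shrink the F_ST top
        set: each candidate set holds at most the top fraction of
        defined windows."""
        gm, pm, _ = two_pop_sim
        res = scan_windows(gm, pm, chrom_lengths={"chr1": 50_000_000})
        sel_b, sel_a, _ = candidate_windows(res)
        n_defined = int(np.isfinite(res.table["fst"].to_numpy(float)).sum())
        assert len(sel_b) <= 0.05 * n_defined
        assert len(sel_a) <= 0.05 * n_defined


class TestMergeRegions:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"]).assign(
            n_snps=5, fst=0.5, pi_A=1e-4, pi_B=1e-4, log2_ratio=0.0
        )

    def test_overlapping_merge(self):
        regions = merge_regions(self._df([("chr1", 0, 50_000), ("chr1", 25_000, 75_000)]), "SELECTED_IN_B")
        assert [(r.start, r.end, r.n_windows) for r in regions] == [(0, 75_000, 2)]

    def test_bookended_merge(self):
        regions = merge_regions(self._df([("chr1", 0, 50_000), ("chr1", 50_000, 100_000)]), "SELECTED_IN_A")
        assert [(r.start, r.end) for r in regions] == [(0, 100_000)]

    def test_different_chromosomes_never_merge(self):
        regions = merge_regions(self._df([("chr1", 0, 50_000), ("chr2", 0, 50_000)]), "SELECTED_IN_B")
        assert len(regions) == 2

    def test_disjoint_stay_separate(self):
        regions = merge_regions(self._df([("chr1", 0, 50_000), ("chr1", 100_000, 150_000)]), "SELECTED_IN_B")
        assert [(r.start, r.end) for r in regions] == [(0, 50_000), (100_000, 150_000)]
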