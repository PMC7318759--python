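"""Window tiling, H_P, Karlsson F_ST and the percentile outlier rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan.variants import PoolPanel, PoolSample
from poolscan.windows import (ContrastSpec, WindowTrack, call_outliers,
                              fst_snp_karlsson, fst_track, fst_window,
                              group_fst, hp_track, hp_transform, hp_window,
                              make_windows, single_breed_fst,
                              window_size_diagnostic)

from conftest import make_table


class TestMakeWindows:
    def test_tiling_with_truncated_last_window(self):
        gw = make_windows({"1": 250_000})
        assert len(gw) == 3
        assert gw.label(2) == "1:200001:250000"

    def test_exact_single_window(self):
        assert len(make_windows({"1": 100_000})) == 1

    def test_genome_scale_window_count(self):
        """Chromosome lengths summing to 2,366.6 Mb in 100-kb multiples
        tile into exactly 23,666 windows."""
        lengths = {f"c{i}": 130_000_000 for i in range(18)}  # 23,400
        lengths["c18"] = 26_600_000                          # + 266
        gw = make_windows(lengths)
        assert sum(v for v in lengths.values()) == 2_366_600_000
        assert len(gw) == 23_666

    def test_boundary_snp_assignment(self):
        gw = make_windows({"1": 300_000})
        w = gw.assign(np.array(["1", "1"]), np.array([100_000, 100_001]))
        assert w.tolist() == [0, 1]

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"1": 0})


class TestWindowSizeDiagnostic:
    def test_uniform_density_exact_counts(self, two_pool_panel):
        # 1 SNP per 10 kb on a 1-Mb chromosome
        recs = [("1", p, "A", "G", 30, True, set(), [(20, 20), (20, 20)])
                for p in range(5_000, 1_000_000, 10_000)]
        t = make_table(two_pool_panel, recs)
        diag = window_size_diagnostic(t, {"1": 1_000_000},
                                      sizes=(50_000, 100_000))
        assert diag[50_000] == 20   # 5 SNPs each: all sparse
        assert diag[100_000] == 0   # 10 SNPs each: none sparse

    def test_monotone_non_increasing(self, two_pool_panel):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), 300, replace=False))
        recs = [("1", int(p), "A", "G", 30, True, set(), [(20, 20), (20, 20)])
                for p in pos]
        t = make_table(two_pool_panel, recs)
        diag = window_size_diagnostic(t, {"1": 2_000_000})
        vals = list(diag.values())
        assert all(b <= a for a, b in zip(vals, vals[1:]))


class TestHp:
    def test_maximal_heterozygosity(self):
        assert hp_window([30], [30]) == 0.5

    def test_swept_window_is_zero(self):
        assert hp_window([30, 42, 17], [0, 0, 0]) == 0.0

    def test_hand_value(self):
        # counts (30,10) and (20,20): SumMaj=50, SumMin=30 -> 0.46875
        assert hp_window([30, 20], [10, 20]) == pytest.approx(0.46875)

    def test_zero_depth_undefined(self):
        assert math.isnan(hp_window([0], [0]))

    @pytest.mark.parametrize("hp,expected", [(0.5, -1.0), (0.25, -2.0)])
    def test_log2_transform(self, hp, expected):
        assert hp_transform(hp) == expected

    def test_log2_of_zero_is_undefined(self):
        assert math.isnan(hp_transform(0.0))
        with pytest.raises(ValueError):
            hp_transform(-0.1)

    @given(st.lists(st.tuples(st.integers(0, 60), st.integers(0, 60)),
                    min_size=1, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_order_and_allele_label_invariance(self, counts):
        ref = np.array([c[0] for c in counts], float)
        alt = np.array([c[1] for c in counts], float)
        base = hp_window(ref, alt)
        perm = np.random.default_rng(0).permutation(len(ref))
        if math.isnan(base):
            assert math.isnan(hp_window(alt, ref))
            return
        assert hp_window(ref[perm], alt[perm]) == pytest.approx(base)
        assert hp_window(alt, ref) == pytest.approx(base)  # ref/alt relabel


class TestKarlssonFst:
    def test_opposite_fixation(self):
        n, d, f = fst_snp_karlsson(0, 20, 20, 20)
        assert (n, d, f) == (1.0, 1.0, 1.0)

    def test_hand_value(self):
        n, d, f = fst_snp_karlsson(10, 20, 0, 20)
        assert n == pytest.approx(0.25 - (10 / 19) / 20)
        assert d == pytest.approx(0.75)
        assert f == pytest.approx(0.2982456140, abs=1e-9)

    def test_exact_fraction_cross_check(self):
        """Re-derivation with exact rational arithmetic."""
        from fractions import Fraction as Fr

        def oracle(a1, n1, a2, n2):
            p1, p2 = Fr(a1, n1), Fr(a2, n2)
            h1 = Fr(2 * a1 * (n1 - a1), n1 * (n1 - 1))
            h2 = Fr(2 * a2 * (n2 - a2), n2 * (n2 - 1))
            N = (p1 - p2) ** 2 - h1 / n1 - h2 / n2
            D = N + h1 + h2
            return N / D if D != 0 else None

        rng = np.random.default_rng(11)
        for _ in range(200):
            n1, n2 = rng.integers(2, 80, size=2)
            a1, a2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            expected = oracle(int(a1), int(n1), int(a2), int(n2))
            _, _, f = fst_snp_karlsson(a1, n1, a2, n2)
            if expected is None:
                assert math.isnan(f)
            else:
                assert f == pytest.approx(float(expected), abs=1e-12)

    def test_identical_pools_slightly_negative(self):
        _, d, f = fst_snp_karlsson(10, 40, 10, 40)
        h = 2 * 10 * 30 / (40 * 39)
        assert f == pytest.approx(-(2 * h / 40) / d)
        # approaches 0 from below as n grows
        _, _, f_big = fst_snp_karlsson(1000, 4000, 1000, 4000)
        assert f < f_big < 0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        n1, n2 = rng.integers(2, 60, size=2)
        a1, a2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
        f_ab = fst_snp_karlsson(a1, n1, a2, n2)[2]
        f_ba = fst_snp_karlsson(a2, n2, a1, n1)[2]
        assert f_ab == pytest.approx(f_ba, abs=1e-14)

    def test_same_fixation_undefined(self):
        assert math.isnan(fst_snp_karlsson(0, 20, 0, 20)[2])

    def test_window_mean(self):
        assert fst_window(np.array([1.0, 0.5])) == 0.75
        assert math.isnan(fst_window(np.array([np.nan, np.nan])))


class TestTracks:
    @pytest.fixture
    def panel4(self):
        return PoolPanel([PoolSample(n, 35) for n in "abcd"])

    def test_single_breed_average_across_comparisons(self, panel4):
        """One window where b-vs-c and b-vs-d window F_ST are knowable by
        hand: the single-breed value is their mean."""
        # 20 identical SNPs so the window passes the 20-SNP floor
        recs = []
        for i in range(20):
            # a slightly polymorphic; b fixed ref; c opposite-fixed; d half
            recs.append(("1", 1000 + i, "A", "G", 30, True, set(),
                         [(15, 5), (20, 0), (0, 20), (10, 10)]))
        t = make_table(panel4, recs)
        gw = make_windows({"1": 100_000})
        fab = fst_track(t, gw, "b", "a").values[0]
        fbc = fst_track(t, gw, "b", "c").values[0]
        fbd = fst_track(t, gw, "b", "d").values[0]
        track, scalar = single_breed_fst(t, gw, "b")
        assert track.values[0] == pytest.approx((fab + fbc + fbd) / 3)
        assert scalar == pytest.approx(track.values[0])

    def test_contrast_of_singletons_reduces_to_pairwise(self, panel4):
        rng = np.random.default_rng(9)
        recs = []
        for i in range(40):
            counts = [(int(rng.integers(5, 40)), int(rng.integers(5, 40)))
                      for _ in range(4)]
            recs.append(("1", 500 + i * 17, "A", "G", 30, True, set(), counts))
        t = make_table(panel4, recs)
        gw = make_windows({"1": 100_000})
        pair = fst_track(t, gw, "a", "c")
        grp = group_fst(t, gw, ContrastSpec(("a",), ("c",), "x"))
        np.testing.assert_allclose(grp.values, pair.values, equal_nan=True)

    def test_identical_groups_near_zero(self, panel4):
        recs = [("1", 100 + i, "A", "G", 30, True, set(),
                 [(15, 25)] * 4) for i in range(25)]
        t = make_table(panel4, recs)
        gw = make_windows({"1": 100_000})
        grp = group_fst(t, gw, ContrastSpec(("a", "b"), ("c", "d"), "x"))
        assert abs(grp.values[0]) < 0.02

    def test_contrast_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            ContrastSpec(("a",), ("a", "b"), "bad")
        with pytest.raises(ValueError, match="non-empty"):
            ContrastSpec((), ("b",), "bad")


class TestCallOutliers:
    @staticmethod
    def _track(values, retained=None, statistic="FST"):
        n = len(values)
        gw = make_windows({"1": n * 100_000})
        values = np.asarray(values, float)
        if retained is None:
            retained = ~np.isnan(values)
        return WindowTrack("t", statistic, gw, values,
                           np.full(n, 100), np.asarray(retained, bool))

    def test_counts_at_study_scale(self):
        rng = np.random.default_rng(0)
        n_total, n_discard = 23_666, 399
        vals = rng.normal(size=n_total)
        retained = np.ones(n_total, bool)
        retained[rng.choice(n_total, n_discard, replace=False)] = False
        track = self._track(vals, retained)
        oset = call_outliers(track, percentile=99.95)
        assert track.n_retained == 23_267
        assert len(oset) == 12

    def test_round_rule(self):
        vals = np.arange(10_000, dtype=float)
        assert len(call_outliers(self._track(vals), 99.95)) == 5

    def test_k1_selects_extreme(self):
        vals = np.arange(1, 2001, dtype=float)
        oset = call_outliers(self._track(vals), 99.95, tail="upper")
        assert len(oset) == 1
        assert vals[oset.windows[0]] == 2000

    def test_hp_defaults_to_lower_tail(self):
        vals = np.linspace(0.01, 0.5, 2000)
        oset = call_outliers(self._track(vals, statistic="HP"), 99.95)
        assert oset.tail == "lower"
        assert vals[oset.windows[0]] == pytest.approx(0.01)

    def test_tie_break_by_genomic_order(self):
        vals = np.full(4000, 1.0)
        vals[[100, 200, 300]] = 9.0  # 3-way tie beyond k=2
        oset = call_outliers(self._track(vals), 99.95, tail="upper")
        assert oset.windows.tolist() == [100, 200]

    def test_monotone_invariance_of_selection(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.01, 0.5, 4000)
        raw = self._track(vals, statistic="HP")
        log = raw.log2()
        assert (call_outliers(raw, 99.95).windows.tolist()
                == call_outliers(log, 99.95).windows.tolist())

    def test_zero_k_warns(self):
        with pytest.warns(UserWarning, match="0 windows"):
            oset = call_outliers(self._track(np.arange(10.0)), 99.95)
        assert len(oset) == 0
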