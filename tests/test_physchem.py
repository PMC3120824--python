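import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomscan.physchem import (
    charge_scale,
    distance_to_binding,
    g_test,
    group_delta_profile,
    hydropathy_scale,
    permutation_slope_test,
    property_values,
    rank_sum_test,
    sliding_window,
)
from venomscan.seqio import (
    AminoAlignment,
    BindingSiteSet,
    CoordinateMap,
    TaxonGroups,
)

from _oracles import enumerate_rank_sum


class TestPropertyValues:
    def test_charge_assignments(self):
        aln = AminoAlignment(("t",), ("KRDEAH",))
        vals = property_values(aln, charge_scale())[0]
        np.testing.assert_array_equal(vals, [1, 1, -1, -1, 0, 0])

    def test_histidine_positive_option(self):
        aln = AminoAlignment(("t",), ("H",))
        assert property_values(aln, charge_scale(histidine_positive=True))[0, 0] == 1

    def test_hydropathy_values(self):
        aln = AminoAlignment(("t",), ("IR",))
        vals = property_values(aln, hydropathy_scale())[0]
        np.testing.assert_allclose(vals, [4.5, -4.5])

    def test_gap_and_x_are_nan(self):
        aln = AminoAlignment(("t",), ("K-X",))
        vals = property_values(aln, charge_scale())[0]
        assert vals[0] == 1 and np.isnan(vals[1]) and np.isnan(vals[2])

    def test_full_scale_coverage(self):
        # all 20 residues must be scored by both scales
        residues = "ACDEFGHIKLMNPQRSTVWY"
        aln = AminoAlignment(("t",), (residues,))
        assert not np.isnan(property_values(aln, hydropathy_scale())).any()
        assert not np.isnan(property_values(aln, charge_scale())).any()


def _profile_fixture(seq_res, seq_non, start=600):
    taxa = tuple(f"r{i}" for i in range(len(seq_res))) + tuple(
        f"n{i}" for i in range(len(seq_non))
    )
    aln = AminoAlignment(taxa, tuple(seq_res) + tuple(seq_non))
    groups = TaxonGroups(
        frozenset(t for t in taxa if t.startswith("r")),
        frozenset(t for t in taxa if t.startswith("n")),
    )
    coord = CoordinateMap(
        reference_taxon=taxa[0],
        positions=tuple(range(start, start + aln.n_sites)),
    )
    return aln, groups, coord


class TestGroupDeltaProfile:
    def test_identical_groups_zero_delta(self):
        aln, groups, coord = _profile_fixture(["KDE", "KDE"], ["KDE", "KDE"])
        vals = property_values(aln, charge_scale())
        prof = group_delta_profile(vals, aln.taxa, groups, coord, BindingSiteSet())
        np.testing.assert_allclose(prof["delta"], 0.0)

    def test_hand_computed_charge_delta(self):
        # resistant {K, K}, non-resistant {E, D}: delta = (+1) - (-1) = 2
        aln, groups, coord = _profile_fixture(["K", "K"], ["E", "D"])
        vals = property_values(aln, charge_scale())
        prof = group_delta_profile(vals, aln.taxa, groups, coord, BindingSiteSet())
        assert prof["delta"].iloc[0] == pytest.approx(2.0)
        assert prof["abs_delta"].iloc[0] == pytest.approx(2.0)

    def test_group_swap_flips_sign(self):
        aln, groups, coord = _profile_fixture(["KA", "RA"], ["EA", "DG"])
        swapped = TaxonGroups(groups.non_resistant, groups.resistant)
        vals = property_values(aln, charge_scale())
        p1 = group_delta_profile(vals, aln.taxa, groups, coord, BindingSiteSet())
        p2 = group_delta_profile(vals, aln.taxa, swapped, coord, BindingSiteSet())
        np.testing.assert_allclose(p1["delta"], -p2["delta"])
        np.testing.assert_allclose(p1["abs_delta"], p2["abs_delta"])

    def test_uninformative_site_is_nan(self):
        aln, groups, coord = _profile_fixture(["-", "-"], ["K", "K"])
        vals = property_values(aln, charge_scale())
        prof = group_delta_profile(vals, aln.taxa, groups, coord, BindingSiteSet())
        assert np.isnan(prof["delta"].iloc[0])
        assert prof["n_resistant"].iloc[0] == 0

    def test_binding_flag_from_coordinates(self):
        aln, groups, coord = _profile_fixture(["KKK", "KKK"], ["KKK", "KKK"], start=627)
        vals = property_values(aln, charge_scale())
        prof = group_delta_profile(vals, aln.taxa, groups, coord, BindingSiteSet())
        # positions 627, 628, 629: only the last two are binding sites
        assert list(prof["binding"]) == [False, True, True]


class TestRankSum:
    def test_complete_separation(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0

    def test_identical_multisets_half(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n1*n2/2

    @pytest.mark.parametrize("n1,n2,seed", [(2, 3, 1), (3, 3, 2), (4, 5, 3), (6, 6, 4)])
    def test_matches_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n1)
        b = rng.normal(size=n2) + 0.5
        res = rank_sum_test(a, b)
        u_oracle, p_oracle = enumerate_rank_sum(a, b)
        assert res.statistic == pytest.approx(u_oracle)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_midrank_ties_give_fractional_statistic(self):
        # U1 = #{a > b} + 0.5 #{a = b} = 0 + 0.5
        res = rank_sum_test([1.0, 2.0], [2.0, 3.0])
        assert res.statistic == pytest.approx(0.5)
        assert res.ties_present

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])
        with pytest.raises(ValueError):
            rank_sum_test([np.nan], [1.0])


class TestGTest:
    def test_reported_enrichment_counts(self):
        res = g_test(((3, 9), (4, 189)))
        assert round(res.statistic, 2) == 8.61
        assert res.df == 1
        assert res.p_value == pytest.approx(0.0033, abs=5e-4)

    def test_proportional_rows_give_zero(self):
        assert g_test(((10, 10), (5, 5))).statistic == pytest.approx(0.0, abs=1e-12)
        assert g_test(((2, 6), (5, 15))).statistic == pytest.approx(0.0, abs=1e-12)

    @given(
        a=st.integers(1, 60),
        b=st.integers(1, 60),
        c=st.integers(1, 60),
        d=st.integers(1, 60),
    )
    @settings(max_examples=50, deadline=None)
    def test_transpose_invariance_and_nonnegativity(self, a, b, c, d):
        g1 = g_test(((a, b), (c, d)))
        g2 = g_test(((a, c), (b, d)))
        assert g1.statistic == pytest.approx(g2.statistic, abs=1e-9)
        assert g1.statistic >= 0

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            g_test(((0, 0), (4, 189)))

    def test_zero_cell_allowed(self):
        res = g_test(((0, 12), (4, 189)))
        assert np.isfinite(res.statistic)


class TestSlidingWindow:
    def test_window_one_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(sliding_window(x, 1), x)

    def test_constant_profile(self):
        x = np.full(10, 2.5)
        np.testing.assert_allclose(sliding_window(x, 5), x)

    def test_truncated_edges_hand_computed(self):
        np.testing.assert_allclose(
            sliding_window([0.0, 3.0, 0.0], 3), [1.5, 1.0, 1.5]
        )

    def test_nan_ignored(self):
        out = sliding_window([1.0, np.nan, 3.0], 3)
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            sliding_window([1.0, 2.0], 2)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_window([1.0, 2.0], 5)


class TestDistanceToBinding:
    def test_member_is_zero(self):
        d = distance_to_binding([628], BindingSiteSet())
        assert d[0] == 0

    def test_site_648_nearest_643(self):
        d = distance_to_binding([648], BindingSiteSet())
        assert d[0] == 5

    def test_full_vector_matches_brute_force(self):
        sites = BindingSiteSet()
        positions = np.arange(478, 729)
        d = distance_to_binding(positions, sites)
        brute = [min(abs(p - b) for b in sites.positions) for p in positions]
        np.testing.assert_array_equal(d, brute)


class TestPermutationSlope:
    def test_constant_delta_all_zero(self):
        x = np.arange(20.0)
        res = permutation_slope_test(np.full(20, 1.3), x, n_perm=50, seed=1)
        assert res.observed_slope == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.null_slopes, 0.0, atol=1e-12)

    def test_strong_trend_outside_interval(self, rng):
        x = np.arange(60.0)
        y = 5.0 - 0.08 * x + rng.normal(0, 0.05, size=60)
        res = permutation_slope_test(y, x, n_perm=500, seed=4)
        lo, hi = res.interval95
        assert res.observed_slope < lo
        assert res.significant

    def test_same_seed_identical_null(self):
        rng = np.random.default_rng(0)
        y, x = rng.normal(size=30), np.arange(30.0)
        r1 = permutation_slope_test(y, x, n_perm=100, seed=7)
        r2 = permutation_slope_test(y, x, n_perm=100, seed=7)
        np.testing.assert_array_equal(r1.null_slopes, r2.null_slopes)

    def test_binding_exclusion_drops_rows(self):
        x = np.array([0.0, 0.0, 3.0, 5.0, 8.0, 10.0])
        y = np.array([4.0, 5.0, 1.0, 1.2, 0.8, 1.0])
        mask = x == 0
        with_b = permutation_slope_test(y, x, n_perm=50, seed=2, is_binding=mask)
        without = permutation_slope_test(
            y, x, n_perm=50, seed=2, include_binding=False, is_binding=mask
        )
        assert abs(without.observed_slope) < abs(with_b.observed_slope)

    def test_equal_distances_error(self):
        with pytest.raises(ValueError, match="slope undefined"):
            permutation_slope_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], n_perm=10)

    def test_nan_removed_pairwise(self):
        y = np.array([1.0, np.nan, 2.0, 3.0])
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = permutation_slope_test(y, x, n_perm=10, seed=0)
        assert np.isfinite(res.observed_slope)
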