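"""Sequence-slotting psi: DP least-cost path vs exhaustive enumeration, binning, drops."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from palynores.records import PercentageRecord
from palynores.slotting import (
    MultivariateSeries,
    align_variables,
    bin_time_intervals,
    distance_matrix,
    drop_analysis,
    least_cost_path,
    psi,
)


def series(values, name="s", variables=None, index=None):
    arr = np.atleast_2d(np.asarray(values, float))
    cols = variables or [f"v{i}" for i in range(arr.shape[1])]
    return MultivariateSeries(name, pd.DataFrame(arr, columns=cols, index=index))


# --- independent oracle: enumerate every monotone path -------------------

def enumerate_paths(m, n, diagonals):
    def walk(i, j, acc):
        if (i, j) == (m - 1, n - 1):
            yield acc + [(i, j)]
            return
        if i + 1 < m:
            yield from walk(i + 1, j, acc + [(i, j)])
        if j + 1 < n:
            yield from walk(i, j + 1, acc + [(i, j)])
        if diagonals and i + 1 < m and j + 1 < n:
            yield from walk(i + 1, j + 1, acc + [(i, j)])

    yield from walk(0, 0, [])


def brute_least_cost(d, diagonals):
    return min(
        sum(d[i, j] for i, j in path)
        for path in enumerate_paths(d.shape[0], d.shape[1], diagonals)
    )


class TestDistanceMatrix:
    def test_three_four_five_triangle(self):
        a = series([[0.0, 0.0], [1.0, 1.0]])
        b = series([[3.0, 4.0], [0.0, 0.0]])
        d = distance_matrix(a, b)
        assert d[0, 0] == pytest.approx(5.0)
        assert d[1, 1] == pytest.approx(np.sqrt(2.0))

    def test_identical_rows_zero_distance(self):
        a = series([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(np.diag(distance_matrix(a, a)), 0.0)

    def test_one_dim_worked_matrix(self):
        a = series([[0.0], [2.0]])
        b = series([[1.0], [3.0]])
        np.testing.assert_allclose(distance_matrix(a, b), [[1.0, 3.0], [1.0, 1.0]])

    def test_alignment_is_by_label_not_position(self):
        a = series([[1.0, 9.0], [2.0, 8.0]], variables=["x", "y"])
        b = MultivariateSeries("b", pd.DataFrame([[9.0, 1.0], [8.0, 2.0]],
                                                 columns=["y", "x"]))
        np.testing.assert_allclose(np.diag(distance_matrix(a, b)), 0.0)

    def test_mismatched_variables_error_lists_labels(self):
        a = series([[1.0], [2.0]], variables=["x"])
        b = series([[1.0], [2.0]], variables=["z"])
        with pytest.raises(ValueError, match=r"x.*z|z.*x"):
            distance_matrix(a, b)


class TestLeastCostPath:
    def test_single_cell(self):
        cost, path = least_cost_path(np.array([[2.5]]))
        assert cost == pytest.approx(2.5) and path == [(0, 0)]

    def test_worked_two_by_two_prefers_diagonal(self):
        cost, path = least_cost_path(np.array([[1.0, 3.0], [1.0, 1.0]]), diagonals=True)
        assert cost == pytest.approx(2.0)
        assert path == [(0, 0), (1, 1)]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            least_cost_path(np.empty((0, 0)))

    @pytest.mark.parametrize("diagonals", [True, False])
    def test_dp_equals_exhaustive_enumeration(self, diagonals):
        """200 random matrices up to 4x4: DP cost == brute-force minimum."""
        rng = np.random.default_rng(1234)
        for _ in range(200):
            m, n = rng.integers(1, 5, size=2)
            d = rng.uniform(0.0, 10.0, size=(m, n))
            cost, path = least_cost_path(d, diagonals=diagonals)
            assert cost == pytest.approx(brute_least_cost(d, diagonals))
            assert cost == pytest.approx(sum(d[i, j] for i, j in path))
            assert path[0] == (0, 0) and path[-1] == (m - 1, n - 1)
            steps = {(i2 - i1, j2 - j1) for (i1, j1), (i2, j2) in zip(path, path[1:])}
            allowed = {(1, 0), (0, 1)} | ({(1, 1)} if diagonals else set())
            assert steps <= allowed

    def test_diagonals_never_cost_more(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            d = rng.uniform(0, 1, size=rng.integers(1, 5, size=2))
            assert least_cost_path(d, True)[0] <= least_cost_path(d, False)[0] + 1e-12


class TestPsi:
    def test_identical_series_have_zero_psi(self):
        a = series([[0.0, 1.0], [2.0, 3.0], [1.0, 0.0]])
        res = psi(a, a)
        assert res.psi == pytest.approx(0.0, abs=1e-12)

    def test_one_dim_worked_example(self):
        a = series([[0.0], [2.0]])
        b = series([[1.0], [3.0]])
        res = psi(a, b)
        assert res.ab_between == pytest.approx(2.0)
        assert res.ab_within == pytest.approx(4.0)
        assert res.psi == pytest.approx(0.5)

    def test_formula_identity_and_symmetry(self):
        rng = np.random.default_rng(99)
        a = series(rng.uniform(0, 10, (5, 3)))
        b = series(rng.uniform(0, 10, (7, 3)))
        ra, rb = psi(a, b), psi(b, a)
        assert ra.psi == pytest.approx((ra.ab_between - ra.ab_within) / ra.ab_within + 1)
        assert ra.psi == pytest.approx(rb.psi)

    def test_constant_sequences_degenerate(self):
        a = series([[1.0], [1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            psi(a, a)

    @given(
        arrays(float, (4, 2), elements=st.floats(0, 50)),
        arrays(float, (5, 2), elements=st.floats(0, 50)),
        st.floats(0.1, 20.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, va, vb, k):
        a, b = series(va), series(vb)
        try:
            base = psi(a, b)
        except ValueError:
            return  # degenerate draw
        scaled = psi(series(va * k), series(vb * k))
        assert scaled.psi == pytest.approx(base.psi, rel=1e-9, abs=1e-9)

    def test_invariant_under_joint_variable_permutation(self):
        rng = np.random.default_rng(3)
        va, vb = rng.uniform(0, 5, (4, 3)), rng.uniform(0, 5, (6, 3))
        a, b = series(va, variables=list("xyz")), series(vb, variables=list("xyz"))
        ap = series(va[:, [2, 0, 1]], variables=list("zxy"))
        bp = series(vb[:, [2, 0, 1]], variables=list("zxy"))
        assert psi(ap, bp).psi == pytest.approx(psi(a, b).psi)


class TestAlignVariables:
    def test_union_with_zero_fill(self):
        a = series([[1.0], [2.0]], variables=["x"])
        b = series([[3.0], [4.0]], variables=["y"])
        aa, bb = align_variables(a, b)
        assert aa.variables == bb.variables == ["x", "y"]
        assert aa.values["y"].tolist() == [0.0, 0.0]
        assert bb.values["x"].tolist() == [0.0, 0.0]


def pct_record(values: dict, ages, site="t") -> PercentageRecord:
    df = pd.DataFrame(values, index=pd.Index(np.asarray(ages, float), name="age_calBP"))
    return PercentageRecord(site_name=site, values=df,
                            reference_sum=pd.Series(100, index=df.index))


class TestBinning:
    def test_nonzero_mean_within_bin(self):
        pct = pct_record({"A": [0.0, 2.0, 4.0], "B": [1.0, 1.0, 1.0]},
                         ages=[50.0, 150.0, 450.0])
        out = bin_time_intervals(pct, width=500.0)
        assert out.values.loc["A", 500] == pytest.approx(3.0)  # zeros excluded
        assert out.values.loc["B", 500] == pytest.approx(1.0)

    def test_all_zero_bin_is_zero(self):
        pct = pct_record({"A": [0.0, 0.0], "B": [1.0, 2.0]}, ages=[100.0, 700.0])
        out = bin_time_intervals(pct, width=500.0)
        assert out.values.loc["A", 500] == 0.0
        assert out.values.loc["A", 1000] == 0.0

    def test_one_sample_per_bin_passthrough(self):
        pct = pct_record({"A": [2.5, 7.5], "B": [1.0, 1.0]}, ages=[100.0, 700.0])
        out = bin_time_intervals(pct, width=500.0)
        assert out.values.loc["A", 500] == pytest.approx(2.5)
        assert out.values.loc["A", 1000] == pytest.approx(7.5)

    def test_negative_ages_fall_in_youngest_bin(self):
        pct = pct_record({"A": [4.0, 6.0], "B": [1.0, 1.0]}, ages=[-50.0, 300.0])
        out = bin_time_intervals(pct, width=500.0)
        assert out.values.loc["A", 0] == pytest.approx(4.0)
        assert out.values.loc["A", 500] == pytest.approx(6.0)

    def test_row_order_follows_order_key(self):
        pct = pct_record({"b": [1.0, 1.0], "a": [2.0, 2.0], "c": [3.0, 1.0]},
                         ages=[0.0, 100.0])
        out = bin_time_intervals(pct, order_key={"b": "0group", "a": "zz", "c": "mid"})
        assert list(out.values.index) == ["b", "c", "a"]


class TestDropAnalysis:
    def test_identical_series_have_nothing_to_attribute(self):
        a = series([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], variables=[500, 1000, 1500])
        with pytest.raises(ValueError, match="psi_full"):
            drop_analysis(a, a)

    def test_single_differing_bin_gets_maximal_positive_drop(self):
        bins = [500, 1000, 1500]
        a = series([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [0.0, 1.0, 2.0]], variables=bins)
        vb = a.values.copy()
        vb[1000] = vb[1000] + 5.0  # only the middle bin differs
        b = MultivariateSeries("b", vb)
        res = drop_analysis(a, b)
        assert res.drop_percent.idxmax() == 1000
        assert res.drop_percent.loc[1000] > 0

    def test_drop_formula_matches_from_scratch_recomputation(self):
        rng = np.random.default_rng(11)
        bins = [500, 1000, 1500, 2000]
        a = series(rng.uniform(0, 5, (4, 4)), variables=bins)
        b = series(rng.uniform(0, 5, (5, 4)), variables=bins)
        res = drop_analysis(a, b)
        full = psi(a, b).psi
        for bin_label in bins:
            removed = psi(a.drop_variable(bin_label), b.drop_variable(bin_label)).psi
            expected = 100.0 * (full - removed) / full
            assert res.drop_percent.loc[bin_label] == pytest.approx(expected)

    def test_mismatched_bins_rejected(self):
        a = series([[1.0, 2.0], [3.0, 4.0]], variables=[500, 1000])
        b = series([[1.0, 2.0], [3.0, 5.0]], variables=[500, 1500])
        with pytest.raises(ValueError, match="bin labels differ"):
            drop_analysis(a, b)
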