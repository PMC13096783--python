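from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edalayout import ConfigError, ContractError, InputFormatError
from edalayout.pcp_engine import (
    CrossingMatrix,
    PcpOptions,
    build_pcp_layout,
    count_crossings,
    crossing_matrix,
    mutual_information,
    normalise_axis,
    order_axes_by_mi,
    order_axes_min_crossings,
)
from edalayout.synthdata import gen_class_mixture

from conftest import make_table


# ---------------------------------------------------------------------------
# oracles


def brute_force_crossings(a, b):
    """Quadratic pairwise definition: sign-reversed pairs, ties contribute 0."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = len(a)
    return sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if (a[i] - a[j]) * (b[i] - b[j]) < 0
    )


def brute_force_best_order(counts):
    k = counts.shape[0]
    best, best_cost = None, math.inf
    for perm in itertools.permutations(range(k)):
        cost = sum(counts[perm[t], perm[t + 1]] for t in range(k - 1))
        if cost < best_cost:
            best, best_cost = perm, cost
    return best, best_cost


def path_cost(counts, order):
    return sum(counts[order[t], order[t + 1]] for t in range(len(order) - 1))


# ---------------------------------------------------------------------------
# normalisation


class TestNormaliseAxis:
    def test_minmax_linear(self):
        np.testing.assert_allclose(normalise_axis([0, 5, 10], "minmax"), [0, 0.5, 1])

    @pytest.mark.parametrize("method", ["minmax", "rank", "zscore"])
    def test_constant_maps_to_half(self, method):
        np.testing.assert_allclose(normalise_axis([7, 7, 7], method), [0.5, 0.5, 0.5])

    def test_rank_equally_spaced(self):
        np.testing.assert_allclose(normalise_axis([10, 20, 30], "rank"), [0, 0.5, 1])

    def test_rank_average_ties(self):
        # ranks of (1,1,2) are (1.5,1.5,3) -> (0.25,0.25,1)
        np.testing.assert_allclose(normalise_axis([1, 1, 2], "rank"), [0.25, 0.25, 1.0])

    def test_missing_stays_missing(self):
        out = normalise_axis([1.0, np.nan, 3.0], "minmax")
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0, 1])

    def test_zscore_clips_at_three_sigma(self):
        x = np.array([0.0] * 100 + [1000.0])
        out = normalise_axis(x, "zscore")
        assert np.all(out >= 0) and np.all(out <= 1)
        assert out[-1] == 1.0

    def test_non_numeric_rejected(self):
        with pytest.raises(ContractError):
            normalise_axis(["a", "b"], "minmax")

    def test_unknown_method_rejected(self):
        with pytest.raises(ContractError):
            normalise_axis([1, 2], "bogus")

    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=50),
        st.sampled_from(["minmax", "rank", "zscore"]),
    )
    def test_outputs_in_unit_interval(self, vals, method):
        out = normalise_axis(vals, method)
        assert np.all(out >= -1e-12) and np.all(out <= 1 + 1e-12)

    @given(st.lists(st.integers(-100, 100), min_size=2, max_size=40, unique=True))
    def test_rank_invariant_under_monotone_transform(self, vals):
        x = np.array(vals, dtype=float)
        np.testing.assert_allclose(
            normalise_axis(x, "rank"), normalise_axis(np.exp(x / 50.0), "rank")
        )


# ---------------------------------------------------------------------------
# crossings


class TestCountCrossings:
    def test_parallel_lines(self):
        assert count_crossings([0.1, 0.9], [0.1, 0.9]) == 0

    def test_one_swap(self):
        assert count_crossings([0.1, 0.9], [0.9, 0.1]) == 1

    def test_matches_oracle_seeded_n8(self):
        rng = np.random.default_rng(42)
        a, b = rng.random(8), rng.random(8)
        assert count_crossings(a, b) == brute_force_crossings(a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.random(20), rng.random(20)
        assert count_crossings(a, b) == count_crossings(b, a)

    def test_missing_pairs_excluded(self):
        a = [0.1, np.nan, 0.9]
        b = [0.9, 0.5, 0.1]
        assert count_crossings(a, b) == 1

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            count_crossings([0.1], [0.1, 0.2])

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.integers(min_value=2, max_value=64),
        st.sampled_from([False, True]),
    )
    @settings(max_examples=120, deadline=None)
    def test_property_equals_quadratic_oracle(self, seed, n, with_ties):
        rng = np.random.default_rng(seed)
        if with_ties:
            a = rng.integers(0, 5, n).astype(float)
            b = rng.integers(0, 5, n).astype(float)
        else:
            a, b = rng.random(n), rng.random(n)
        assert count_crossings(a, b) == brute_force_crossings(a, b)


class TestCrossingMatrix:
    def _table(self, cols):
        return make_table({k: ("numeric", v) for k, v in cols.items()})

    def test_identical_columns_zero(self):
        t = self._table({"a": [1, 2, 3], "b": [1, 2, 3]})
        m = crossing_matrix(t, ["a", "b"])
        assert m.counts[0, 1] == 0

    def test_negated_column_all_pairs(self):
        t = self._table({"a": [1, 2, 3], "b": [-1, -2, -3]})
        m = crossing_matrix(t, ["a", "b"])
        assert m.counts[0, 1] == 3  # C(3,2)

    def test_seeded_matrix_matches_oracle(self):
        rng = np.random.default_rng(11)
        cols = {f"c{j}": list(rng.random(12)) for j in range(4)}
        t = self._table(cols)
        m = crossing_matrix(t, list(cols))
        for i, j in itertools.combinations(range(4), 2):
            expect = brute_force_crossings(cols[f"c{i}"], cols[f"c{j}"])
            assert m.counts[i, j] == expect
        assert np.array_equal(m.counts, m.counts.T)
        assert np.all(np.diag(m.counts) == 0)

    def test_non_numeric_axis_named(self):
        t = make_table({"a": ("numeric", [1, 2]), "g": ("categorical", ["x", "y"])})
        with pytest.raises(ContractError, match="'g'"):
            crossing_matrix(t, ["a", "g"])


class TestOrderAxesMinCrossings:
    def test_single_axis(self):
        m = CrossingMatrix(axes=("only",), counts=np.zeros((1, 1), dtype=int))
        assert order_axes_min_crossings(m) == ["only"]

    def test_all_equal_ties_give_identity(self):
        c = np.full((4, 4), 5)
        np.fill_diagonal(c, 0)
        m = CrossingMatrix(axes=("a", "b", "c", "d"), counts=c)
        assert order_axes_min_crossings(m) == ["a", "b", "c", "d"]

    @pytest.mark.parametrize("seed", range(5))
    def test_seeded_k5_matches_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 50, (5, 5))
        c = np.triu(c, 1)
        c = c + c.T
        m = CrossingMatrix(axes=tuple("abcde"), counts=c)
        got = order_axes_min_crossings(m)
        idx = [m.axes.index(x) for x in got]
        _, best_cost = brute_force_best_order(c)
        assert path_cost(c, idx) == best_cost

    def test_reversal_canonicalisation(self):
        rng = np.random.default_rng(3)
        c = rng.integers(0, 20, (5, 5))
        c = np.triu(c, 1)
        c = c + c.T
        m = CrossingMatrix(axes=tuple("abcde"), counts=c)
        got = order_axes_min_crossings(m)
        idx = [m.axes.index(x) for x in got]
        assert idx[0] < idx[-1]

    @pytest.mark.parametrize("seed", range(5))
    def test_heuristic_never_worse_than_input(self, seed):
        rng = np.random.default_rng(seed)
        k = 12
        c = rng.integers(0, 100, (k, k))
        c = np.triu(c, 1)
        c = c + c.T
        m = CrossingMatrix(axes=tuple(f"a{i}" for i in range(k)), counts=c)
        got = order_axes_min_crossings(m)
        idx = [m.axes.index(x) for x in got]
        assert path_cost(c, idx) <= path_cost(c, list(range(k)))

    def test_asymmetric_matrix_rejected(self):
        c = np.array([[0, 1], [2, 0]])
        with pytest.raises(ContractError):
            CrossingMatrix(axes=("a", "b"), counts=c)


# ---------------------------------------------------------------------------
# mutual information


class TestMutualInformation:
    def test_constant_feature_zero(self):
        assert mutual_information([1.0] * 10, ["a"] * 5 + ["b"] * 5, 4) == 0.0

    def test_perfect_separation_one_bit(self):
        x = np.concatenate([np.arange(50), np.arange(100, 150)]).astype(float)
        y = ["lo"] * 50 + ["hi"] * 50
        assert mutual_information(x, y, 2) == pytest.approx(1.0, abs=1e-12)

    def test_fixed_2x2_contingency_matches_hand_sum(self):
        # joint counts 30,20 / 20,30 over n=100
        x = np.arange(100, dtype=float)  # 2 equal-frequency bins: [0,50), [50,100)
        y = ["A"] * 30 + ["B"] * 20 + ["A"] * 20 + ["B"] * 30
        got = mutual_information(x, y, 2)
        # independent four-term evaluation of sum p log2(p/(px py))
        expect = 0.0
        for p, px, py in [(0.3, 0.5, 0.5), (0.2, 0.5, 0.5), (0.2, 0.5, 0.5), (0.3, 0.5, 0.5)]:
            expect += p * math.log2(p / (px * py))
        assert expect == pytest.approx(0.029049405545331, abs=1e-12)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_non_negative_and_bounded(self):
        rng = np.random.default_rng(0)
        x = rng.random(200)
        y = rng.choice(["a", "b", "c"], 200)
        mi = mutual_information(x, y, 4)
        assert 0.0 <= mi <= min(math.log2(4), math.log2(3)) + 1e-12

    def test_independent_bias_small(self):
        # estimator bias on independent data: median over seeds < 0.05 bits
        vals = []
        for seed in range(21):
            rng = np.random.default_rng(seed)
            x = rng.random(1000)
            y = rng.choice(["a", "b"], 1000)
            vals.append(mutual_information(x, y, 4))
        assert np.median(vals) < 0.05

    def test_degenerate_single_label(self):
        assert mutual_information([1.0, 2.0, 3.0], ["a", "a", "a"], 2) == 0.0

    def test_degenerate_single_row(self):
        assert mutual_information([1.0], ["a"], 2) == 0.0

    def test_missing_excluded_pairwise(self):
        x = [np.nan, 1.0, 2.0, 3.0, 4.0]
        y = ["z", "a", "a", "b", None]
        # effective data: (1,a),(2,a),(3,b) — just checks it runs and is finite
        mi = mutual_information(x, y, 2)
        assert mi >= 0.0


class TestOrderAxesByMi:
    def test_informative_before_constant(self):
        t = make_table(
            {
                "sig": ("numeric", [0, 0, 0, 10, 10, 10]),
                "flat": ("numeric", [5, 5, 5, 5, 5, 5]),
                "cls": ("categorical", ["a", "a", "a", "b", "b", "b"]),
            }
        )
        got = order_axes_by_mi(t, ["flat", "sig"], "cls", 2)
        assert [name for name, _ in got] == ["sig", "flat"]
        assert got[1][1] == 0.0

    def test_ties_preserve_original_order(self):
        t = make_table(
            {
                "a": ("numeric", [1, 2, 3, 4]),
                "b": ("numeric", [1, 2, 3, 4]),
                "cls": ("categorical", ["x", "x", "y", "y"]),
            }
        )
        got = order_axes_by_mi(t, ["a", "b"], "cls", 2)
        assert [name for name, _ in got] == ["a", "b"]

    def test_numeric_class_rejected(self):
        t = make_table({"a": ("numeric", [1, 2]), "c": ("numeric", [1, 2])})
        with pytest.raises(ContractError):
            order_axes_by_mi(t, ["a"], "c", 2)

    def test_recovers_informative_axes(self):
        hits = 0
        for seed in range(10):
            t = gen_class_mixture(500, seed, 3, 3, 5, 3.0)
            axes = [c.name for c in t.columns if c.name != "class"]
            got = order_axes_by_mi(t, axes, "class")
            top3 = {name for name, _ in got[:3]}
            if top3 == {"signal_1", "signal_2", "signal_3"}:
                hits += 1
        assert hits >= 9


# ---------------------------------------------------------------------------
# layout assembly


class TestBuildPcpLayout:
    def test_basic_given_order(self):
        t = make_table(
            {"a": ("numeric", [1, 2, 3]), "b": ("numeric", [4, 5, 6])}
        )
        lay = build_pcp_layout(t, PcpOptions(ordering="given"))
        assert len(lay.polylines) == 3
        assert all(len(p.heights) == 2 for p in lay.polylines)
        assert lay.dropped_rows == []
        assert [a.position for a in lay.axes] == [0, 1]

    def test_missing_row_dropped_and_reported(self):
        t = make_table(
            {"a": ("numeric", [1, None, 3]), "b": ("numeric", [4, 5, 6])}
        )
        lay = build_pcp_layout(t)
        assert lay.dropped_rows == [1]
        assert len(lay.polylines) == 2
        assert {p.row for p in lay.polylines} == {0, 2}

    def test_highlight_flags(self):
        t = make_table(
            {
                "a": ("numeric", [1, 2, 3]),
                "b": ("numeric", [4, 5, 6]),
                "kind": ("categorical", ["Dermason", "Seker", "Dermason"]),
            }
        )
        lay = build_pcp_layout(
            t, PcpOptions(colour_feature="kind", highlight_level="Dermason")
        )
        flags = {p.row: p.foreground for p in lay.polylines}
        assert flags == {0: True, 1: False, 2: True}

    def test_vertex_conservation(self):
        rng = np.random.default_rng(5)
        from conftest import random_mixed_table

        for _ in range(10):
            t = random_mixed_table(rng)
            lay = build_pcp_layout(t)
            k = len(lay.axes)
            assert sum(len(p.heights) for p in lay.polylines) == (
                t.n_rows - len(lay.dropped_rows)
            ) * k
            for p in lay.polylines:
                assert all(0 <= h <= 1 for h in p.heights)

    def test_crossings_ordering_used(self):
        rng = np.random.default_rng(9)
        cols = {f"c{j}": ("numeric", list(rng.random(15))) for j in range(4)}
        t = make_table(cols)
        lay = build_pcp_layout(t, PcpOptions(ordering="crossings"))
        got = [a.column for a in lay.axes]
        expected = order_axes_min_crossings(crossing_matrix(t, list(cols), "minmax"))
        assert got == expected

    def test_too_few_axes(self):
        t = make_table({"a": ("numeric", [1, 2]), "g": ("categorical", ["x", "y"])})
        with pytest.raises(InputFormatError):
            build_pcp_layout(t)

    def test_mi_without_colour_is_config_error(self):
        t = make_table({"a": ("numeric", [1, 2]), "b": ("numeric", [3, 4])})
        with pytest.raises(ConfigError, match="colour"):
            build_pcp_layout(t, PcpOptions(ordering="mi"))

    def test_unknown_highlight_level_lists_levels(self):
        t = make_table(
            {
                "a": ("numeric", [1, 2]),
                "b": ("numeric", [3, 4]),
                "g": ("categorical", ["x", "y"]),
            }
        )
        with pytest.raises(ConfigError, match="x, y"):
            build_pcp_layout(
                t, PcpOptions(colour_feature="g", highlight_level="zzz")
            )
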