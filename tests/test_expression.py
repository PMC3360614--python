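"""Relative expression, fold classes, clamping and row clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirest.expression import (
    classify_fold,
    cluster_rows,
    count_classes,
    relative_expression,
)
from mirest.seq import FormatError


def _table(values: dict, samples=("s1",), control=1000.0):
    rows = {k: np.atleast_1d(np.asarray(v, dtype=float))
            for k, v in values.items()}
    rows["U6snRNA"] = np.full(len(samples), control)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(samples))


class TestRelativeExpression:
    def test_ratio_log_and_clamp(self):
        df = _table({
            "m1": 1000.0,        # ratio 1 -> log 0
            "m2": 1_000_000.0,   # ratio 1000 -> clamped 3
            "m3": 0.1,           # ratio 1e-4 -> clamped -3
            "m4": 0.0,           # ratio 0 -> -inf -> clamped -3
        })
        mat = relative_expression(df)
        assert mat.logs.loc["m1", "s1"] == 0.0
        assert mat.clamped.loc["m2", "s1"] == 3.0
        assert mat.clamped.loc["m3", "s1"] == -3.0
        assert mat.clamped.loc["m4", "s1"] == -3.0
        assert ((mat.clamped >= -3) & (mat.clamped <= 3)).all().all()

    def test_clamp_idempotent(self):
        df = _table({"m1": 5e6, "m2": 1e-3})
        mat = relative_expression(df)
        assert mat.clamped.clip(-3, 3).equals(mat.clamped)

    def test_zero_control_names_column(self):
        df = _table({"m1": [1.0, 2.0]}, samples=("sA", "sB"))
        df.loc["U6snRNA", "sB"] = 0.0
        with pytest.raises(ValueError, match="sB"):
            relative_expression(df)

    def test_missing_control_row_rejected(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["m1"])
        with pytest.raises(FormatError):
            relative_expression(df)

    def test_reference_column_selection(self):
        df = _table({"m1": [5000.0, 1500.0]}, samples=("early", "late"))
        assert relative_expression(df, reference="late").classes["m1"] \
            == "intermediate"
        assert relative_expression(df, reference="max").classes["m1"] \
            == "high"


class TestClassifyFold:
    @pytest.mark.parametrize(
        "ratio, label",
        [
            (2.5, "high"),
            (2.0, "intermediate"),   # the published bins leave (1, 2]
            (1.0, "moderate"),
            (0.5, "moderate"),
            (0.1, "moderate"),
            (0.05, "intermediate"),  # and (0.01, 0.1)
            (0.01, "intermediate"),
            (0.005, "very_low"),
            (0.0, "very_low"),
            (1e9, "high"),
        ],
    )
    def test_bins(self, ratio, label):
        assert classify_fold(ratio) == label

    def test_total_on_nonnegative_reals(self, rng):
        for r in 10.0 ** rng.uniform(-8, 8, size=200):
            assert classify_fold(float(r)) in (
                "high", "moderate", "very_low", "intermediate"
            )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_fold(-0.1)

    @given(st.floats(min_value=0.0, max_value=1e18, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_totality_property(self, ratio):
        assert classify_fold(ratio) in (
            "high", "moderate", "very_low", "intermediate"
        )


class TestCountClasses:
    def test_narrative_composition(self):
        values = {f"hi{i}": 5000.0 for i in range(11)}
        values.update({f"mid{i}": 500.0 for i in range(45)})
        values.update({f"lo{i}": 5.0 for i in range(2)})
        mat = relative_expression(_table(values))
        assert count_classes(mat, "high") == 11
        assert count_classes(mat, "moderate") == 45
        assert count_classes(mat, "very_low") == 2

    def test_all_equal_to_control_gives_zero_high(self):
        mat = relative_expression(_table({f"m{i}": 1000.0 for i in range(5)}))
        assert count_classes(mat, "high") == 0

    def test_unknown_class_rejected(self):
        mat = relative_expression(_table({"m1": 1.0}))
        with pytest.raises(ValueError):
            count_classes(mat, "stellar")


def naive_average_linkage_heights(dist):
    """Independent O(n^3) average-linkage reference (merge heights only)."""
    n = dist.shape[0]
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    nxt = n
    while len(active) > 1:
        (i, j), h = min(
            ((k, v) for k, v in d.items()
             if k[0] in active and k[1] in active),
            key=lambda kv: (kv[1], kv[0]),
        )
        heights.append(h)
        for k in active - {i, j}:
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            d[(k, nxt)] = (sizes[i] * dik + sizes[j] * djk) \
                / (sizes[i] + sizes[j])
        sizes[nxt] = sizes[i] + sizes[j]
        active -= {i, j}
        active.add(nxt)
        nxt += 1
    return sorted(heights)


class TestClusterRows:
    def _matrix(self, rng, n_rows=11, n_cols=9):
        data = rng.normal(size=(n_rows, n_cols))
        return pd.DataFrame(
            data, index=[f"m{i:02d}" for i in range(n_rows)],
            columns=[f"s{j}" for j in range(n_cols)],
        )

    def test_identical_rows_merge_first_at_zero(self, rng):
        df = self._matrix(rng, 5)
        df.loc["m01"] = df.loc["m00"]
        res = cluster_rows(df)
        assert res.merge_heights[0] == pytest.approx(0.0, abs=1e-12)
        a, b = int(res.linkage[0, 0]), int(res.linkage[0, 1])
        assert {res.names[a], res.names[b]} == {"m00", "m01"}

    def test_anticorrelated_rows_merge_last_at_two(self):
        df = pd.DataFrame(
            {"s1": [1.0, -1.0], "s2": [2.0, -2.0], "s3": [3.0, -3.0]},
            index=["up", "down"],
        )
        res = cluster_rows(df)
        assert res.merge_heights[-1] == pytest.approx(2.0)

    def test_permutation_invariance(self, rng):
        df = self._matrix(rng)
        base = cluster_rows(df)
        for seed in (1, 2, 3):
            shuffled = df.sample(frac=1, random_state=seed)
            res = cluster_rows(shuffled)
            assert res.order == base.order
            assert np.allclose(res.merge_heights, base.merge_heights)

    def test_constant_row_warns_and_sits_at_distance_one(self, rng):
        df = self._matrix(rng, 4)
        df.loc["m03"] = 7.0
        with pytest.warns(UserWarning, match="m03"):
            res = cluster_rows(df)
        assert "m03" in res.order

    def test_single_row_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_rows(self._matrix(rng, 1))

    def test_merge_heights_match_naive_reference(self, rng):
        df = self._matrix(rng, 8)
        res = cluster_rows(df)
        x = df.sort_index().to_numpy()
        c = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((c ** 2).sum(axis=1))
        dist = 1.0 - (c @ c.T) / np.outer(norm, norm)
        np.fill_diagonal(dist, 0.0)
        expected = naive_average_linkage_heights(dist)
        assert np.allclose(sorted(res.merge_heights), expected, atol=1e-9)
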