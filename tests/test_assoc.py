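"""Stage trends, correlations, marker filters and decile tables."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chromstrat.assoc import (
    basal_filter,
    decile_tables,
    divergent_genes,
    one_tailed_t,
    pearson,
    stage_trend,
    stars,
)
from chromstrat.types import ExpressionMatrix


def welch_oracle(x, y, direction):
    """Textbook Welch t-test, computed from first principles."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p_greater = tdist.sf(t, df)
    return p_greater if direction == "greater" else 1 - p_greater


class TestOneTailedT:
    def test_identical_samples_give_half(self):
        assert one_tailed_t([1, 2, 3], [1, 2, 3], "greater") == 0.5

    def test_matches_direct_welch_computation(self):
        x, y = [1, 2, 3], [4, 5, 6]
        got = one_tailed_t(x, y, "less")
        assert got == pytest.approx(welch_oracle(x, y, "less"), abs=1e-9)

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=15),
        st.lists(st.floats(-50, 50), min_size=3, max_size=15),
    )
    def test_direction_complementarity(self, x, y):
        if np.var(x) == 0 and np.var(y) == 0:
            return
        p_g = one_tailed_t(x, y, "greater")
        p_l = one_tailed_t(x, y, "less")
        assert p_g + p_l == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_conventions(self):
        assert one_tailed_t([2, 2], [2, 2], "greater") == 0.5
        assert one_tailed_t([3, 3], [2, 2], "greater") == 0.0
        assert one_tailed_t([3, 3], [2, 2], "less") == 1.0

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            one_tailed_t([1], [2, 3], "greater")


def pearson_oracle(x, y):
    """Direct covariance-formula Pearson r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))


class TestPearson:
    def test_perfect_positive(self):
        r, _ = pearson([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative_affine(self):
        x = np.array([1.0, 2, 3, 4])
        r, _ = pearson(x, -2 * x + 5)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_covariance_example(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        r, p = pearson(x, y)
        assert r == pytest.approx(0.8, abs=1e-12)
        # p from t with n-2=2 df
        from scipy.stats import t as tdist

        t = 0.8 * math.sqrt(2 / (1 - 0.64))
        assert p == pytest.approx(2 * tdist.sf(t, 2), abs=1e-12)

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=40),
        st.integers(0, 10_000),
    )
    def test_matches_direct_formula_to_1e12(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=len(x))
        if np.var(x) == 0 or np.var(y) == 0:
            return
        r, _ = pearson(x, y)
        assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


def _expr(rows: dict, samples) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(rows, index=samples).T)


class TestBasalFilter:
    def test_disjoint_bottom_quartiles_remove_nothing(self):
        samples = [f"S{i}" for i in range(8)]
        expr = _expr({"FOXA1": range(1, 9), "GATA3": range(8, 0, -1)}, samples)
        kept, removed = basal_filter(expr)
        assert removed == [] and len(kept) == 8

    def test_aligned_markers_remove_bottom_quarter(self):
        samples = [f"S{i}" for i in range(8)]
        expr = _expr({"FOXA1": range(1, 9), "GATA3": range(1, 9)}, samples)
        kept, removed = basal_filter(expr)
        # type-7 quantile of 1..8 at 0.25 is 2.75; values 1,2 are <= cut
        assert removed == ["S0", "S1"]

    def test_all_identical_all_removed_with_warning(self, caplog):
        samples = [f"S{i}" for i in range(4)]
        expr = _expr({"FOXA1": [5] * 4, "GATA3": [5] * 4}, samples)
        with caplog.at_level("WARNING"):
            kept, removed = basal_filter(expr)
        assert kept == [] and len(removed) == 4
        assert any("degenerate" in r.message for r in caplog.records)

    def test_strict_boundary_excludes_samples_at_the_cut(self):
        samples = [f"S{i}" for i in range(4)]
        # quantile of [1,2,3,4] at 0.25 is 1.75; only value 1 is <= or < cut
        expr = _expr({"FOXA1": [1, 2, 3, 4], "GATA3": [1, 2, 3, 4]}, samples)
        _, removed_le = basal_filter(expr, boundary="le")
        _, removed_lt = basal_filter(expr, boundary="lt")
        assert removed_le == removed_lt == ["S0"]
        # with a sample exactly at the cut the conventions diverge
        expr2 = _expr({"FOXA1": [1, 1, 1, 5], "GATA3": [1, 1, 1, 5]}, samples)
        _, removed_le = basal_filter(expr2, boundary="le")
        _, removed_lt = basal_filter(expr2, boundary="lt")
        assert removed_le == ["S0", "S1", "S2"] and removed_lt == []

    def test_missing_marker_rejected(self):
        expr = _expr({"FOXA1": [1, 2, 3, 4]}, ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="GATA3"):
            basal_filter(expr)

    def test_invariant_to_sample_order_and_monotone_transform(self, rng):
        samples = [f"S{i}" for i in range(20)]
        f = rng.uniform(1, 10, 20)
        g = rng.uniform(1, 10, 20)
        expr = _expr({"FOXA1": f, "GATA3": g}, samples)
        _, removed = basal_filter(expr)
        perm = list(rng.permutation(samples))
        _, removed_perm = basal_filter(ExpressionMatrix(expr.data[perm]))
        assert set(removed) == set(removed_perm)
        _, removed_tr = basal_filter(_expr({"FOXA1": np.exp(f / 3), "GATA3": g**2}, samples))
        assert set(removed) == set(removed_tr)


class TestDivergentGenes:
    def test_arithmetic_oracle(self):
        expr = _expr({"g1": [15, 15, 3, 3], "g2": [5, 5, 5, 5]}, ["a", "b", "c", "d"])
        higher, lower = divergent_genes(expr, ["a", "b"], ["c", "d"], lfc_threshold=1.0)
        assert higher["g1"] == pytest.approx(2.0)  # log2(16/4)
        assert "g2" not in higher.index and "g2" not in lower.index

    def test_equal_means_in_neither_list(self):
        expr = _expr({"g1": [4, 4, 4, 4]}, ["a", "b", "c", "d"])
        higher, lower = divergent_genes(expr, ["a", "b"], ["c", "d"], lfc_threshold=0.0)
        assert len(higher) == 0 and len(lower) == 0

    def test_threshold_zero_classifies_all_unequal(self):
        expr = _expr({"up": [2, 2, 1, 1], "down": [1, 1, 2, 2], "flat": [1, 1, 1, 1]},
                     ["a", "b", "c", "d"])
        higher, lower = divergent_genes(expr, ["a", "b"], ["c", "d"], lfc_threshold=0.0)
        assert list(higher.index) == ["up"] and list(lower.index) == ["down"]

    def test_overlapping_sets_rejected(self):
        expr = _expr({"g": [1, 2, 3]}, ["a", "b", "c"])
        with pytest.raises(ValueError, match="disjoint"):
            divergent_genes(expr, ["a", "b"], ["b", "c"])


class TestDecileTables:
    def _expr20(self):
        samples = [f"S{i:02d}" for i in range(20)]
        rows = {
            "ANP32E": np.arange(20, dtype=float),
            "g2": np.arange(20, dtype=float) ** 2,
            "g3": np.full(20, 7.0),
        }
        return _expr(rows, samples), samples

    def test_counts(self):
        expr, _ = self._expr20()
        tables = decile_tables(expr, "ANP32E", decile=0.1)
        assert len(tables.top_samples) == len(tables.bottom_samples) == 2

    def test_monotone_gene_bottom_is_first_samples(self):
        expr, samples = self._expr20()
        tables = decile_tables(expr, "ANP32E", decile=0.1)
        assert tables.bottom_samples == samples[:2]
        assert tables.top_samples == samples[-2:]

    def test_means_match_hand_computation(self):
        expr, samples = self._expr20()
        tables = decile_tables(expr, "ANP32E", decile=0.1)
        assert tables.bottom_means["g2"] == pytest.approx((0 + 1) / 2)
        assert tables.top_means["g2"] == pytest.approx((18**2 + 19**2) / 2)
        assert tables.top_means["g3"] == 7.0

    def test_too_small_cohort_rejected(self):
        expr = _expr({"g": [1, 2, 3]}, ["a", "b", "c"])
        with pytest.raises(ValueError):
            decile_tables(expr, "g", decile=0.1)


class TestStageTrend:
    def test_planted_increase_detected(self, rng):
        by_stage = {s: rng.normal(loc=i, scale=0.1, size=10) for i, s in
                    enumerate(["I", "II", "III", "IV"])}
        trend = stage_trend(by_stage, direction="greater")
        assert all(c.p_value < 0.01 for c in trend.comparisons)
        pairs = [(c.stage_a, c.stage_b) for c in trend.comparisons]
        assert pairs == [("I", "II"), ("II", "III"), ("III", "IV"), ("I", "IV")]

    def test_shuffled_labels_rarely_significant(self, rng):
        values = rng.normal(size=40)
        hits = total = 0
        for _ in range(100):
            perm = rng.permutation(values)
            by_stage = {s: perm[i * 10 : (i + 1) * 10] for i, s in
                        enumerate(["I", "II", "III", "IV"])}
            for c in stage_trend(by_stage, "greater").comparisons:
                total += 1
                hits += c.p_value < 0.01
        assert hits / total <= 0.10

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError):
            stage_trend({"I": [1, 2, 3]}, "greater")

    def test_star_bands(self):
        assert stars(0.5) == ""
        assert stars(0.005) == "*"
        assert stars(0.0005) == "**"
        assert stars(0.00005) == "***"
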