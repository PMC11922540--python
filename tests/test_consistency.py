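import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.stats import spearmanr

from phytoquant.consistency import (
    coinertia,
    count_correlations,
    critical_r,
    heatmap_order,
    rv_coefficient,
    spearman_grid,
    spearman_pair,
)


class TestSpearman:
    def test_matches_scipy_on_complete_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            r, p, n = spearman_pair(x, y)
            ref_r, ref_p = spearmanr(x, y)
            assert r == pytest.approx(ref_r, abs=1e-12)
            assert p == pytest.approx(ref_p, rel=1e-9)
            assert n == 15

    def test_pairwise_complete_equals_scipy_on_subset(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 20))
        x[[3, 7]] = np.nan
        y[5] = np.nan
        ok = ~(np.isnan(x) | np.isnan(y))
        r, p, n = spearman_pair(x, y)
        ref_r, ref_p = spearmanr(x[ok], y[ok])
        assert n == ok.sum()
        assert r == pytest.approx(ref_r, abs=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-9)

    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_pair(x, x**3)[0] == 1.0
        assert spearman_pair(x, -x)[0] == -1.0

    def test_too_few_pairs_undefined(self):
        x = np.array([1.0, 2, np.nan, np.nan, np.nan])
        y = np.array([1.0, 2, 3, 4, 5])
        r, p, n = spearman_pair(x, y)
        assert np.isnan(r) and np.isnan(p) and n == 2

    def test_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 12))
        r0 = spearman_pair(x, y)[0]
        assert spearman_pair(100 * np.exp(x), y)[0] == pytest.approx(r0)

    def test_exact_small_sample_p(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 2, 3, 5, 4])
        r, p, _ = spearman_pair(x, y, exact=True)
        # enumeration over 5! permutations is the gold standard here
        assert 0 < p < 1
        ref = spearmanr(x, y)
        assert r == pytest.approx(ref.statistic)


class TestGrid:
    def test_bh_is_stepup_over_all_cells(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        Y = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("wxyz"))
        Y["w"] = X["a"] + rng.normal(scale=0.1, size=12)  # one real signal
        grid = spearman_grid(X, Y, alpha=0.05)
        # manual Benjamini-Hochberg on the grid's own p-values
        p = grid.p.values.ravel()
        order = np.argsort(p)
        m = len(p)
        q_manual = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, p[i] * m / (rank_idx + 1))
            q_manual[i] = prev
        np.testing.assert_allclose(grid.q.values.ravel(), q_manual, atol=1e-12)

    def test_undefined_cells_excluded_from_family(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6],
                          "b": [np.nan] * 4 + [1.0, 2]})
        Y = pd.DataFrame({"y": [1.0, 2, 3, 4, 5, 6]})
        grid = spearman_grid(X, Y)
        assert np.isnan(grid.r.loc["b", "y"])
        assert not grid.significant.loc["b", "y"]
        assert grid.n.loc["b", "y"] == 2

    def test_count_correlations_signs(self):
        X = pd.DataFrame({"up": np.arange(10.0), "down": -np.arange(10.0)})
        Y = pd.DataFrame({"y": np.arange(10.0)})
        grid = spearman_grid(X, Y, alpha=0.05)
        assert count_correlations(grid) == (1, 1)

    def test_null_noise_yields_no_discoveries(self):
        rng = np.random.default_rng(123)
        X = pd.DataFrame(rng.normal(size=(27, 10)))
        Y = pd.DataFrame(rng.normal(size=(27, 10)), columns=range(10, 20))
        grid = spearman_grid(X, Y, alpha=0.05)
        # raw p: about alpha of cells small; BH over the null family
        # controls FDR so discoveries should collapse to (almost) none
        raw = (grid.p.values < 0.05).mean()
        assert raw < 0.15
        assert sum(count_correlations(grid)) <= 2


class TestCriticalR:
    def test_study_design_threshold(self):
        assert round(critical_r(27, 0.05), 2) == 0.38

    def test_small_n_value(self):
        assert critical_r(12, 0.05) == pytest.approx(0.576, abs=5e-4)

    def test_monotone_decreasing_in_n(self):
        values = [critical_r(n) for n in range(5, 60)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            critical_r(3)


class TestHeatmapOrder:
    def test_identical_rows_adjacent(self):
        r = pd.DataFrame(
            [[1.0, 0.0, 0.2], [0.0, 1.0, 0.9], [1.0, 0.0, 0.2]],
            index=["a", "mid", "a_twin"], columns=["x", "y", "z"])
        rows, _ = heatmap_order(r)
        ia, ib = rows.index("a"), rows.index("a_twin")
        assert abs(ia - ib) == 1

    def test_matches_bruteforce_linkage_on_fixture(self):
        rng = np.random.default_rng(6)
        block1 = rng.normal(0, 0.05, size=(3, 6)) + 1.0
        block2 = rng.normal(0, 0.05, size=(3, 6)) - 1.0
        r = pd.DataFrame(np.vstack([block1, block2]),
                         index=list("abcdef"))
        rows, _ = heatmap_order(r)
        # blocks must be contiguous in leaf order
        pos = {lab: i for i, lab in enumerate(rows)}
        first = sorted(pos[l] for l in "abc")
        second = sorted(pos[l] for l in "def")
        assert first == list(range(first[0], first[0] + 3))
        assert second == list(range(second[0], second[0] + 3))
        # and agree with directly calling scipy on the sorted matrix
        Z = linkage(r.sort_index().values, method="complete",
                    metric="euclidean")
        assert rows == [r.sort_index().index[i] for i in leaves_list(Z)]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        r = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"))
        shuffled = r.sample(frac=1, random_state=1)
        assert heatmap_order(r)[0] == heatmap_order(shuffled)[0]

    def test_single_row_identity(self):
        r = pd.DataFrame([[0.1, 0.2]], index=["only"])
        assert heatmap_order(r)[0] == ["only"]


def bruteforce_rv(X, Y):
    """RV from the covariance double-sum definition (independent oracle)."""
    X = np.asarray(X, float) - np.mean(X, axis=0)
    Y = np.asarray(Y, float) - np.mean(Y, axis=0)
    n = X.shape[0]
    cov_xy = sum(
        (X[:, i] @ Y[:, j] / n) ** 2
        for i in range(X.shape[1]) for j in range(Y.shape[1]))
    cov_xx = sum(
        (X[:, i] @ X[:, j] / n) ** 2
        for i in range(X.shape[1]) for j in range(X.shape[1]))
    cov_yy = sum(
        (Y[:, i] @ Y[:, j] / n) ** 2
        for i in range(Y.shape[1]) for j in range(Y.shape[1]))
    return cov_xy / np.sqrt(cov_xx * cov_yy)


class TestRV:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(9, 4))
        assert rv_coefficient(X, X) == pytest.approx(1.0, abs=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 5))
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        assert rv_coefficient(X, X @ Q) == pytest.approx(1.0, abs=1e-10)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            X = rng.normal(size=(8, 3))
            Y = rng.normal(size=(8, 5))
            rv = rv_coefficient(X, Y)
            assert 0.0 <= rv <= 1.0
            assert rv == pytest.approx(rv_coefficient(Y, X), abs=1e-14)

    def test_matches_bruteforce_double_sum(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            X = rng.normal(size=(5, 3))
            Y = rng.normal(size=(5, 3))
            assert rv_coefficient(X, Y) == pytest.approx(
                bruteforce_rv(X, Y), abs=1e-10)

    def test_zero_variance_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError):
            rv_coefficient(X, np.random.default_rng(0).normal(size=(5, 2)))


class TestCoinertia:
    def test_rank_one_coupling_on_first_axis(self):
        rng = np.random.default_rng(14)
        u = rng.normal(size=10)
        X = np.outer(u, rng.normal(size=4))
        Y = np.outer(u, rng.normal(size=3))
        res = coinertia(X, Y, n_axes=1)
        assert res.axis_inertia[0] / res.axis_inertia.sum() == pytest.approx(
            1.0, abs=1e-12)

    def test_axis_contributions_sum_to_total(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(12, 4))
        Y = rng.normal(size=(12, 5))
        res = coinertia(X, Y, n_axes=4)
        A = X - X.mean(axis=0)
        B = Y - Y.mean(axis=0)
        total = np.sum((A.T @ B / 12) ** 2)
        assert res.axis_inertia.sum() == pytest.approx(total, rel=1e-10)

    def test_rv_agrees_with_direct_computation(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(9, 4))
        Y = rng.normal(size=(9, 3))
        assert coinertia(X, Y).rv == pytest.approx(
            rv_coefficient(X, Y), abs=1e-10)

    def test_truncation_warns(self):
        rng = np.random.default_rng(17)
        u = rng.normal(size=8)
        X = np.outer(u, rng.normal(size=3))
        Y = np.outer(u, rng.normal(size=3))
        with pytest.warns(UserWarning, match="rank"):
            coinertia(X, Y, n_axes=3)
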