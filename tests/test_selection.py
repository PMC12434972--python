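"""ANOVA filter, successive projections and sequential forward selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import pestspec as ps
from pestspec.selection import ChainResult, spa_chain

from conftest import make_table


def anova_oracle(values, labels):
    """Literal between/within sum-of-squares computation."""
    values = np.asarray(values, float)
    grand = values.mean()
    classes = np.unique(labels)
    ssb = sum(
        (labels == c).sum() * (values[labels == c].mean() - grand) ** 2
        for c in classes
    )
    ssw = sum(
        ((values[labels == c] - values[labels == c].mean()) ** 2).sum()
        for c in classes
    )
    k, n = len(classes), len(values)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestAnovaF:
    def test_matches_sum_of_squares_oracle_and_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = rng.integers(1, 5, 40)
            while len(np.unique(labels)) < 4 or min(
                (labels == c).sum() for c in range(1, 5)
            ) < 2:
                labels = rng.integers(1, 5, 40)
            values = rng.normal(labels * rng.uniform(0, 1), 1.0)
            f = ps.anova_f(values, labels)
            assert f == pytest.approx(anova_oracle(values, labels), abs=1e-12, rel=1e-12)
            groups = [values[labels == c] for c in np.unique(labels)]
            assert f == pytest.approx(stats.f_oneway(*groups).statistic, rel=1e-10)

    def test_equal_class_means_give_zero(self):
        values = np.array([1.0, -1.0, 2.0, -2.0])
        labels = np.array([1, 1, 2, 2])
        assert ps.anova_f(values, labels) == pytest.approx(0.0)

    def test_zero_within_variance_flags_infinity(self):
        assert np.isinf(ps.anova_f([1, 1, 2, 2], [1, 1, 2, 2]))

    def test_all_identical_flags_nan(self):
        assert np.isnan(ps.anova_f([3, 3, 3, 3], [1, 1, 2, 2]))

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            ps.anova_f([1, 2, 3], [1, 1, 1])


class TestCriticalF:
    def test_matches_quadrature_oracle(self):
        # tail probability from numeric integration of the F density
        q = ps.critical_f(2, 10, 0.05)
        tail, _ = integrate.quad(lambda x: stats.f.pdf(x, 2, 10), q, np.inf)
        assert tail == pytest.approx(0.05, rel=1e-8)

    def test_median_near_one_for_large_dof(self):
        assert ps.critical_f(500, 500, 0.5) == pytest.approx(1.0, abs=0.01)

    def test_strictly_decreasing_in_p(self):
        for d1, d2 in [(1, 5), (3, 836), (10, 50)]:
            assert ps.critical_f(d1, d2, 1e-10) > ps.critical_f(d1, d2, 1e-5)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            ps.critical_f(0, 10, 0.05)
        with pytest.raises(ValueError):
            ps.critical_f(2, 10, 1.5)


class TestAnovaFilter:
    def test_boundary_f_equal_threshold_is_excluded(self):
        sel, exc = ps.filter_by_f({"a": 13.57, "b": 20.0}, 13.57)
        assert sel == ["b"] and exc == ["a"]

    def test_filter_on_table_keeps_strictly_greater(self):
        rng = np.random.default_rng(1)
        y = np.repeat([1, 2, 3, 4], 30)
        strong = y + rng.normal(0, 0.3, len(y))
        weak = rng.normal(0, 1, len(y))
        table = make_table(np.column_stack([strong, weak]), y, ["strong", "weak"])
        res = ps.anova_filter(table)
        assert res.selected == ["strong"]
        assert res.diagnostics["excluded"] == ["weak"]
        assert set(res.diagnostics["f_values"]) == {"strong", "weak"}

    def test_override_replaces_computed_threshold(self):
        rng = np.random.default_rng(2)
        y = np.repeat([1, 2, 3, 4], 10)
        table = make_table(rng.normal(size=(40, 3)), y)
        res = ps.anova_filter(table, f_override=0.0)
        assert res.diagnostics["threshold_used"] == 0.0
        assert len(res.selected) == 3  # everything beats an F threshold of 0


def gram_schmidt_chain_oracle(X, start, m):
    """Recompute the projection from scratch at every step (QR-based)."""
    X = np.asarray(X, float)
    chain = [start]
    p = X.shape[1]
    for _ in range(m - 1):
        Q, _ = np.linalg.qr(X[:, chain])
        norms = np.full(p, -np.inf)
        for j in range(p):
            if j in chain:
                continue
            resid = X[:, j] - Q @ (Q.T @ X[:, j])
            norms[j] = np.linalg.norm(resid)
        chain.append(int(np.argmax(norms)))
    return chain


class TestSpaChain:
    def test_orthogonal_columns_selected_by_residual_norm(self):
        X = np.diag([3.0, 1.0, 2.0])
        chain, truncated = spa_chain(X, start=1, m=3)
        assert chain == [1, 0, 2]  # largest remaining norm each step
        assert not truncated

    def test_duplicate_column_never_chosen_while_alternatives_remain(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        X[:, 4] = X[:, 0]  # exact duplicate
        chain, _ = spa_chain(X, start=0, m=4)
        assert 4 not in chain

    def test_rank_exhaustion_truncates_with_flag(self):
        X = np.ones((10, 3))
        res = spa_chain(X, start=0, m=3)
        assert isinstance(res, ChainResult)
        assert res.truncated and len(res.indices) < 3

    def test_matches_bruteforce_gram_schmidt(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            X = rng.normal(size=(10, 8))
            X = (X - X.mean(0)) / X.std(0)
            start = int(rng.integers(8))
            chain, _ = spa_chain(X, start, 8)
            assert chain == gram_schmidt_chain_oracle(X, start, 8)

    def test_selected_projection_dominates_each_step(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        chain, _ = spa_chain(X, 2, 6)
        for t in range(1, len(chain)):
            Q, _ = np.linalg.qr(X[:, chain[:t]])
            def rnorm(j):
                return np.linalg.norm(X[:, j] - Q @ (Q.T @ X[:, j]))
            chosen = rnorm(chain[t])
            for j in range(6):
                if j not in chain[: t + 1]:
                    assert chosen >= rnorm(j) - 1e-9


def make_planted_pair_table(seed, n=160, p=10):
    """Damage level exactly linear in two features; the other eight are
    noisy copies of one latent factor (mutually collinear, like a bank of
    vegetation indices)."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 2, 3, 4], n // 4)
    rng.shuffle(y)
    u = rng.normal(0, 1, n)
    f = rng.normal(0, 1, n)
    cols = {}
    for j in range(p):
        if j == 2:
            cols[f"f{j}"] = 0.5 * y + u
        elif j == 7:
            cols[f"f{j}"] = 0.5 * y - u + rng.normal(0, 0.01, n)
        else:
            cols[f"f{j}"] = f + rng.normal(0, 0.1, n)
    df = pd.DataFrame(cols, index=[f"t{i}" for i in range(n)])
    return ps.FeatureTable(df, pd.Series(y, index=df.index), {})


class TestSpaSelect:
    def test_recovers_exact_linear_pair_with_tiny_rmse(self):
        table = make_planted_pair_table(0)
        res = ps.spa_select(table, size_range=(1, 10), seed=0)
        assert {"f2", "f7"} <= set(res.selected)
        assert res.diagnostics["rmse_at_chosen"] < 0.05

    def test_single_feature_table(self):
        rng = np.random.default_rng(6)
        y = np.repeat([1, 2, 3, 4], 10)
        table = make_table((y + rng.normal(0, 0.1, 40))[:, None], y, ["only"])
        res = ps.spa_select(table, size_range=(1, 1), seed=0)
        assert res.selected == ["only"]
        assert res.diagnostics["chosen_size"] == 1

    def test_duplicated_noise_columns_leave_choice_unchanged(self):
        hits = 0
        for seed in range(20):
            table = make_planted_pair_table(seed)
            res = ps.spa_select(table, size_range=(1, 10), seed=seed)
            dup = table.values.copy()
            for j in (0, 1, 3):  # exact duplicates of noise columns
                dup[f"dup{j}"] = dup[f"f{j}"]
            table2 = ps.FeatureTable(dup, table.labels, {})
            res2 = ps.spa_select(table2, size_range=(1, 10), seed=seed)
            hits += res2.selected == res.selected
        assert hits >= 18

    def test_single_class_rejected(self):
        table = make_table(np.random.default_rng(0).normal(size=(20, 3)), [2] * 20)
        with pytest.raises(ValueError, match="degenerate"):
            ps.spa_select(table, seed=0)

    def test_deterministic_given_seed(self):
        table = make_planted_pair_table(3)
        a = ps.spa_select(table, seed=5)
        b = ps.spa_select(table, seed=5)
        assert a.selected == b.selected
        np.testing.assert_array_equal(
            a.diagnostics["rmse_curve"], b.diagnostics["rmse_curve"]
        )


def make_planted_signal_table(seed, n=100, p_noise=10):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 2, 3, 4], n // 4)
    rng.shuffle(y)
    cols = {f"n{j}": rng.normal(0, 1, n) for j in range(p_noise)}
    cols["sig"] = y + rng.normal(0, 0.5, n)
    df = pd.DataFrame(cols, index=[f"t{i}" for i in range(n)])
    return ps.FeatureTable(df, pd.Series(y, index=df.index), {})


class TestSfsSelect:
    def test_identical_copies_tie_toward_single_feature(self):
        rng = np.random.default_rng(7)
        y = np.repeat([1, 2, 3, 4], 25)
        base = y + rng.normal(0, 0.4, 100)
        table = make_table(np.tile(base[:, None], (1, 5)), y)
        res = ps.sfs_select(table, cv_folds=3, n_estimators=20, seed=0)
        curve = res.diagnostics["accuracy_curve"]
        assert np.allclose(curve, curve[0])
        assert res.diagnostics["chosen_size"] == 1

    def test_planted_signal_ranked_first_and_selected(self):
        table = make_planted_signal_table(0)
        res = ps.sfs_select(table, cv_folds=3, n_estimators=20, seed=0)
        assert res.diagnostics["ranking"][0] == "sig"
        assert "sig" in res.selected

    def test_returned_accuracy_is_curve_maximum_and_final_point_uses_all(self):
        table = make_planted_signal_table(1)
        res = ps.sfs_select(table, cv_folds=3, n_estimators=20, seed=1)
        curve = np.asarray(res.diagnostics["accuracy_curve"])
        assert res.diagnostics["accuracy"] == curve.max()
        assert len(curve) == len(table.feature_names)

    def test_deterministic_given_seed(self):
        table = make_planted_signal_table(2)
        a = ps.sfs_select(table, cv_folds=3, n_estimators=20, seed=9)
        b = ps.sfs_select(table, cv_folds=3, n_estimators=20, seed=9)
        assert a.selected == b.selected


class TestCollinearityReduction:
    def test_spa_subset_less_collinear_than_full_set(self):
        table = make_planted_pair_table(4)
        res = ps.spa_select(table, size_range=(2, 10), seed=4)
        corr_full = table.values.corr().abs().to_numpy()
        np.fill_diagonal(corr_full, 0)
        sub = table.values[res.selected].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0)
        assert sub.max() <= corr_full.max() + 1e-12
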