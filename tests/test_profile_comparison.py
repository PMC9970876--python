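"""Paule–Mandel pooling, δ-test, FDR, Boruta and single-linkage outliers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from discoprofile.profile_comparison import (
    PooledEffect,
    bh_fdr,
    boruta_select,
    compare_profiles,
    delta_test,
    pm_meta,
    single_linkage_outliers,
)
from discoprofile.sumstats_io import DegenerateInputError, EmptyInputError


def pm_grid_oracle(betas, ses, grid_hi=1.0, n_grid=20_001):
    """Dense grid search of the Paule–Mandel equation (independent oracle).

    A coarse pass over [0, grid_hi] is refined by a second dense grid around
    the coarse minimizer, giving ~1e-8 resolution on the |Q(tau2) - (k-1)|
    objective without a million-point grid.
    """
    b = np.asarray(betas)
    s = np.asarray(ses)
    k = len(b)

    def objective(grid):
        w = 1.0 / (s[None, :] ** 2 + grid[:, None])
        mu = np.sum(w * b[None, :], axis=1) / np.sum(w, axis=1)
        q = np.sum(w * (b[None, :] - mu[:, None]) ** 2, axis=1)
        return np.abs(q - (k - 1))

    grid = np.linspace(0.0, grid_hi, n_grid)
    best = grid[int(np.argmin(objective(grid)))]
    step = grid[1] - grid[0]
    fine = np.linspace(max(best - 2 * step, 0.0), best + 2 * step, n_grid)
    return float(fine[int(np.argmin(objective(fine)))])


class TestPmMeta:
    def test_single_study(self):
        pe = pm_meta([0.3], [0.1])
        assert (pe.beta_hat, pe.se, pe.tau2) == (0.3, 0.1, 0.0)

    def test_identical_betas_zero_tau2(self):
        pe = pm_meta([0.2, 0.2, 0.2], [0.1, 0.05, 0.2])
        assert pe.tau2 == 0.0
        assert pe.beta_hat == pytest.approx(0.2)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            k = int(rng.integers(4, 12))
            tau = 0.2
            s = rng.uniform(0.05, 0.3, k)
            b = rng.standard_normal(k) * np.sqrt(s**2 + tau**2)
            pe = pm_meta(b, s)
            oracle = pm_grid_oracle(b, s)
            assert pe.tau2 == pytest.approx(oracle, abs=1e-6)

    def test_reduces_to_fixed_effect_when_tau_zero(self):
        b = np.array([0.11, 0.1, 0.105])
        s = np.array([0.2, 0.3, 0.25])
        pe = pm_meta(b, s)
        assert pe.tau2 == 0.0
        w = 1 / s**2
        assert pe.beta_hat == pytest.approx(np.sum(w * b) / np.sum(w))
        assert pe.se == pytest.approx(1 / np.sqrt(np.sum(w)))

    def test_empty_and_degenerate_inputs(self):
        with pytest.raises(EmptyInputError):
            pm_meta([], [])
        with pytest.raises(DegenerateInputError):
            pm_meta([0.1], [0.0])


class TestDeltaTest:
    def pe(self, beta, se, profile="C"):
        return PooledEffect("t", profile, beta, se, 0.0, 5)

    def test_equal_estimates_give_p_one(self):
        d = delta_test(self.pe(0.1, 0.02), self.pe(0.1, 0.03, "D"))
        assert d.delta == 0.0 and d.p == pytest.approx(1.0)

    def test_symmetry_in_profiles(self):
        a = delta_test(self.pe(0.2, 0.02), self.pe(-0.1, 0.03, "D"))
        b = delta_test(self.pe(-0.1, 0.03), self.pe(0.2, 0.02, "D"))
        assert a.delta == b.delta and a.p == b.p

    def test_se_combination(self):
        d = delta_test(self.pe(0.2, 0.03), self.pe(0.1, 0.04, "D"))
        assert d.se_delta == pytest.approx(0.05)

    def test_sbp_worked_example(self):
        """Systolic blood pressure: profile effects 0.002 (CI -0.001,0.004) vs
        -0.008 (CI -0.012,-0.004) s.d./allele must separate at p < 1.39e-4."""
        se_c = (0.004 - (-0.001)) / (2 * 1.96)
        se_d = (-0.004 - (-0.012)) / (2 * 1.96)
        d = delta_test(self.pe(0.002, se_c), self.pe(-0.008, se_d, "D"))
        assert d.p <= 1.39e-4


def brute_force_bh(p, alpha=0.05):
    """Explicit step-up: largest k with p_(k) <= k/m * alpha is rejected."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k / m * alpha:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


class TestBhFdr:
    def test_all_ones_no_flags(self):
        q, flags = bh_fdr([1.0, 1.0, 1.0])
        assert not flags.any()

    def test_hand_computation(self):
        q, flags = bh_fdr([0.001, 0.02, 0.9])
        assert q == pytest.approx([0.003, 0.03, 0.9])
        assert list(flags) == [True, True, False]

    def test_flags_match_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = int(rng.integers(1, 13))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            _, flags = bh_fdr(p)
            np.testing.assert_array_equal(flags, brute_force_bh(p))

    @given(st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=12))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_q_values_order_invariant(self, p):
        q1, _ = bh_fdr(p)
        perm = np.random.RandomState(0).permutation(len(p))
        q2, _ = bh_fdr(np.asarray(p)[perm])
        np.testing.assert_allclose(np.sort(q1), np.sort(q2))


class TestBoruta:
    def matrix(self, n_snps=40, n_traits=15, planted=False, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array(["concordant"] * (n_snps // 2) + ["discordant"] * (n_snps - n_snps // 2))
        X = rng.standard_normal((n_snps, n_traits))
        cols = [f"t{j}" for j in range(n_traits)]
        if planted:
            X[:, 0] += np.where(labels == "concordant", 1.5, -1.5)
        return pd.DataFrame(X, columns=cols), labels

    def test_planted_trait_confirmed(self):
        X, labels = self.matrix(planted=True, seed=1)
        res = boruta_select(X, labels, n_iter=60, n_trees=80, seed=2)
        decisions = {r.trait_id: r.decision for r in res}
        assert decisions["t0"] == "confirmed"

    def test_constant_column_rejected(self):
        X, labels = self.matrix(seed=3)
        X["t1"] = 0.0
        res = boruta_select(X, labels, n_iter=60, n_trees=80, seed=4)
        decisions = {r.trait_id: r.decision for r in res}
        assert decisions["t1"] == "rejected"

    def test_single_class_rejected(self):
        X, labels = self.matrix()
        with pytest.raises(DegenerateInputError):
            boruta_select(X, np.array(["concordant"] * len(X)), n_iter=5)

    def test_deterministic_given_seed(self):
        X, labels = self.matrix(planted=True, seed=5)
        a = boruta_select(X, labels, n_iter=20, n_trees=50, seed=7)
        b = boruta_select(X, labels, n_iter=20, n_trees=50, seed=7)
        assert [(r.trait_id, r.decision, r.hits) for r in a] == [
            (r.trait_id, r.decision, r.hits) for r in b
        ]


def brute_force_single_linkage(X):
    """O(n^3) agglomeration tracking minimum inter-cluster distance."""
    n = len(X)
    clusters = {i: {i} for i in range(n)}
    heights = []
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            dist = min(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return sorted(heights)


class TestSingleLinkage:
    def test_distant_row_is_last_joined(self):
        X = pd.DataFrame(
            [[0.0, 0.0], [0.01, 0.0], [0.0, 0.01], [5.0, 5.0]],
            index=["a", "b", "c", "far"],
        )
        tree = single_linkage_outliers(X)
        assert tree.last_joined_leaf == "far"

    def test_heights_match_brute_force(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((6, 4))
        tree = single_linkage_outliers(pd.DataFrame(X))
        expected = brute_force_single_linkage(X)
        np.testing.assert_allclose(sorted(tree.merges["height"]), expected, rtol=1e-12)

    def test_merge_heights_permutation_invariant(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((7, 3)), index=[f"r{i}" for i in range(7)])
        t1 = single_linkage_outliers(X)
        t2 = single_linkage_outliers(X.sample(frac=1, random_state=1))
        np.testing.assert_allclose(
            sorted(t1.merges["height"]), sorted(t2.merges["height"])
        )
        assert t1.last_joined_leaf == t2.last_joined_leaf


class TestCompareProfiles:
    def test_empty_panel_gives_empty_outputs(self):
        pooled, delta, selected = compare_profiles(pd.DataFrame())
        assert pooled.empty and delta.empty and selected == []

    def test_planted_separating_trait_selected(self, scan):
        _, _, selected = compare_profiles(scan)
        assert "sep_trait_00" in selected and "sep_trait_01" in selected

    def test_delta_equals_pool_difference(self, scan):
        pooled, delta, _ = compare_profiles(scan)
        wide = pooled.pivot_table(index="trait_id", columns="profile", values="beta_hat")
        for r in delta.itertuples():
            assert r.delta == pytest.approx(
                abs(wide.loc[r.trait_id, "C"] - wide.loc[r.trait_id, "D"])
            )
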