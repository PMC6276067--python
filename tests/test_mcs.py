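import numpy as np
import pytest

from mortset import (
    LossMatrix,
    compute_differentials,
    run_mcs,
    select_block_length,
)
from mortset.mcs import MCSError
from mortset.mcs import test_epa as epa_test  # alias: keep pytest collection clean


def make_losses(L, labels=None):
    L = np.asarray(L, dtype=float)
    labels = labels or [f"m{j}" for j in range(L.shape[1])]
    return LossMatrix(labels, list(range(L.shape[0])), L)


class TestDifferentials:
    def test_identical_columns_give_zero_differentials(self, rng):
        col = rng.normal(size=30)
        diff = compute_differentials(
            make_losses(np.column_stack([col, col])), B=200, block_length=1, seed=0
        )
        np.testing.assert_allclose(diff.dbar_pair, 0.0, atol=1e-15)
        np.testing.assert_allclose(diff.dbar_dot, 0.0, atol=1e-15)

    def test_antisymmetry_and_row_mean_identity(self, rng):
        L = rng.normal(1.0, 0.2, size=(25, 4))
        diff = compute_differentials(make_losses(L), B=200, block_length=1, seed=1)
        np.testing.assert_allclose(diff.dbar_pair, -diff.dbar_pair.T, atol=1e-15)
        np.testing.assert_allclose(
            diff.dbar_dot, diff.dbar_pair.mean(axis=1), atol=1e-15
        )
        assert np.all(diff.var_pair >= 0) and np.all(diff.var_dot >= 0)

    def test_iid_bootstrap_variance_matches_closed_form(self, rng):
        N = 100
        L = rng.normal(0.0, 1.0, size=(N, 2))
        diff = compute_differentials(make_losses(L), B=5000, block_length=1, seed=2)
        d = L[:, 0] - L[:, 1]
        expected = d.var() / N  # iid closed form for the variance of the mean
        assert diff.var_pair[0, 1] == pytest.approx(expected, rel=0.05)

    def test_single_model_rejected(self, rng):
        with pytest.raises(MCSError):
            compute_differentials(make_losses(rng.normal(size=(10, 1))), B=10)


class TestBlockLength:
    def test_white_noise_selects_one(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(300 + rep)
            L = rng.normal(size=(100, 3))
            hits += select_block_length(make_losses(L)) == 1
        assert hits / 50 > 0.8

    def test_persistent_differentials_need_longer_blocks(self):
        # the rule takes a max over all pairwise differential series, so a
        # pool of AR(1)-driven loss columns yields blocks of length >= 2
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(400 + rep)
            cols = []
            for _ in range(8):
                ar = np.zeros(200)
                e = rng.normal(size=200)
                for t in range(1, 200):
                    ar[t] = 0.9 * ar[t - 1] + e[t]
                cols.append(ar)
            hits += select_block_length(make_losses(np.column_stack(cols))) >= 2
        assert hits / 50 > 0.8

    def test_constant_series_floors_at_one(self):
        L = np.column_stack([np.ones(20), np.ones(20)])
        assert select_block_length(make_losses(L)) == 1


class TestEpaTest:
    def test_identical_losses_accept_null(self, rng):
        col = rng.normal(size=20)
        diff = compute_differentials(
            make_losses(np.column_stack([col, col, col])), B=500, block_length=1, seed=3
        )
        for stat in ("T_R", "T_max"):
            observed, p, _ = epa_test(diff, stat)
            assert observed == 0.0
            assert p == 1.0

    def test_two_model_statistics_agree_on_worst(self):
        agree = 0
        for rep in range(50):
            rng = np.random.default_rng(500 + rep)
            L = rng.normal(1.0, 0.3, size=(30, 2)) + rng.normal(0, 0.2, size=2)
            diff = compute_differentials(make_losses(L), B=300, block_length=1, seed=rep)
            _, _, worst_r = epa_test(diff, "T_R")
            _, _, worst_m = epa_test(diff, "T_max")
            agree += worst_r == worst_m
        assert agree == 50

    def test_shifted_model_is_rejected_and_worst(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(600 + rep)
            L = rng.normal(1.0, 0.1, size=(20, 3))
            L[:, 1] += 1.0  # +10 SD shift
            diff = compute_differentials(make_losses(L), B=500, block_length=1, seed=rep)
            observed, p, worst = epa_test(diff, "T_max")
            hits += (p < 0.01) and (worst == "m1")
        assert hits / 50 > 0.95

    def test_brute_force_statistics_on_small_instance(self, rng):
        L = rng.normal(1.0, 0.5, size=(10, 3))
        diff = compute_differentials(make_losses(L), B=400, block_length=1, seed=9)
        m = 3
        # explicit loops, no vectorization
        dbar = [[0.0] * m for _ in range(m)]
        for r in range(m):
            for x in range(m):
                s = 0.0
                for ell in range(10):
                    s += L[ell, r] - L[ell, x]
                dbar[r][x] = s / 10
        for r in range(m):
            for x in range(m):
                assert diff.dbar_pair[r, x] == pytest.approx(dbar[r][x], abs=1e-12)
            ddot = sum(dbar[r]) / m
            assert diff.dbar_dot[r] == pytest.approx(ddot, abs=1e-12)
        # studentized forms and max statistics
        t_pair = np.zeros((m, m))
        for r in range(m):
            for x in range(m):
                if r != x:
                    t_pair[r, x] = dbar[r][x] / np.sqrt(diff.var_pair[r, x])
        T_R_expected = max(abs(t_pair[r][x]) for r in range(m) for x in range(m))
        observed, _, _ = epa_test(diff, "T_R")
        assert observed == pytest.approx(T_R_expected, abs=1e-12)
        t_dot = [diff.dbar_dot[r] / np.sqrt(diff.var_dot[r]) for r in range(m)]
        observed_max, _, _ = epa_test(diff, "T_max")
        assert observed_max == pytest.approx(max(t_dot), abs=1e-12)


class TestRunMcs:
    def test_single_model_is_its_own_superior_set(self, rng):
        # bypass the m >= 2 loss-matrix path via select
        lm = make_losses(rng.normal(size=(10, 2))).select(["m0"])
        res = run_mcs(lm, seed=0)
        assert res.superior == ["m0"]
        assert res.eliminated == []

    def test_dominated_model_is_trimmed(self, rng):
        L = rng.normal(1.0, 0.1, size=(40, 4))
        L[:, 2] += 0.5
        res = run_mcs(make_losses(L), alpha=0.10, B=500, block_length=1, seed=1)
        assert "m2" not in res.superior

    def test_mcs_pvalues_nondecreasing(self, rng):
        L = rng.normal(1.0, 0.1, size=(30, 5)) + np.linspace(0, 0.4, 5)
        res = run_mcs(make_losses(L), alpha=0.5, B=500, block_length=1, seed=2)
        pvals = [p for _, _, p in res.eliminated]
        assert pvals == sorted(pvals)

    def test_superior_sets_nested_across_confidence_levels(self, rng):
        L = rng.normal(1.0, 0.2, size=(30, 5)) + np.linspace(0, 0.25, 5)
        sets = {}
        for alpha in (0.05, 0.10, 0.25):
            res = run_mcs(make_losses(L), alpha=alpha, B=500, block_length=1, seed=3)
            sets[alpha] = set(res.superior)
        assert sets[0.25] <= sets[0.10] <= sets[0.05]

    def test_label_permutation_equivariance(self, rng):
        L = rng.normal(1.0, 0.2, size=(25, 4)) + np.linspace(0, 0.3, 4)
        lm = make_losses(L, labels=["a", "b", "c", "d"])
        res = run_mcs(lm, alpha=0.10, B=400, block_length=1, seed=4)
        perm = [2, 0, 3, 1]
        lm_p = make_losses(L[:, perm], labels=[lm.models[j] for j in perm])
        res_p = run_mcs(lm_p, alpha=0.10, B=400, block_length=1, seed=4)
        assert set(res.superior) == set(res_p.superior)

    def test_partition_into_superior_and_eliminated(self, rng):
        L = rng.normal(1.0, 0.2, size=(30, 5)) + np.linspace(0, 0.4, 5)
        res = run_mcs(make_losses(L), alpha=0.25, B=400, block_length=1, seed=5)
        eliminated = {lab for lab, _, _ in res.eliminated}
        assert eliminated.isdisjoint(res.superior)
        assert eliminated | set(res.superior) == set(make_losses(L).models)
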