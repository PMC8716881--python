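import numpy as np
import pytest

import landsyn as ls
from landsyn.exceptions import (ConfigurationError, DataError,
                                DegenerateInputError)

from conftest import gaussian_bump


def _synthetic_v(p=3, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    M = rng.random((13, p)) + 0.1
    P = np.vstack([gaussian_bump(c, 50) for c in
                   np.linspace(60, 240, p)])
    V = M @ P
    if noise:
        V = np.clip(V + noise * rng.standard_normal(V.shape), 0, None)
    return V, M, P


class TestNmfFactorize:
    def test_exact_rank_one_outer_product(self):
        m = np.abs(np.random.default_rng(1).random(13)) + 0.1
        p = gaussian_bump(150, 60) + 0.05
        V = np.outer(m, p)
        _, _, r2 = ls.nmf_factorize(V, 1, seed=3)
        assert r2 >= 0.999

    def test_nested_models_never_lose_fit(self):
        V, _, _ = _synthetic_v(noise=0.02, seed=5)
        r2 = [ls.nmf_factorize(V, p, seed=10 + p, n_restarts=5)[2]
              for p in (12, 13)]
        assert r2[1] >= r2[0] - 1e-4

    def test_objective_improves_with_iteration_budget(self):
        V, _, _ = _synthetic_v(noise=0.05, seed=9)
        r2s = [ls.nmf_factorize(V, 4, seed=2, n_restarts=2, max_iter=n,
                                patience=10**9)[2]
               for n in (5, 20, 80, 320)]
        assert np.all(np.diff(r2s) >= -1e-12)

    def test_factors_nonnegative_and_deterministic(self):
        V, _, _ = _synthetic_v(noise=0.02, seed=5)
        M1, P1, _ = ls.nmf_factorize(V, 3, seed=42, n_restarts=3)
        M2, P2, _ = ls.nmf_factorize(V, 3, seed=42, n_restarts=3)
        assert np.array_equal(M1, M2) and np.array_equal(P1, P2)
        assert M1.min() >= 0 and P1.min() >= 0

    def test_degenerate_and_invalid_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            ls.nmf_factorize(np.zeros((13, 300)), 3)
        with pytest.raises(ConfigurationError):
            ls.nmf_factorize(np.ones((13, 300)), 14)
        with pytest.raises(DataError):
            ls.nmf_factorize(-np.ones((13, 300)), 2)

    def test_ground_truth_recovery_with_hungarian_matching(self):
        from scipy.optimize import linear_sum_assignment
        V, Mt, Pt = _synthetic_v(p=3, seed=17)
        M, P, r2 = ls.nmf_factorize(V, 3, seed=6)
        assert r2 >= 0.999
        C = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                C[a, b] = (Mt[:, a] @ M[:, b]) / (
                    np.linalg.norm(Mt[:, a]) * np.linalg.norm(M[:, b]))
        ri, ci = linear_sum_assignment(-C)
        assert C[ri, ci].min() > 0.95


class TestNormalizeFactors:
    def test_scale_transferred_to_modules(self):
        M = np.ones((13, 2))
        P = np.vstack([4.0 * gaussian_bump(100, 40),
                       2.0 * gaussian_bump(200, 40)])
        Mn, Pn = ls.normalize_factors(M, P)
        assert Pn.max(axis=1) == pytest.approx([1.0, 1.0])
        assert Mn[:, 0] == pytest.approx(4.0 * M[:, 0])

    def test_reconstruction_invariant(self):
        rng = np.random.default_rng(2)
        M, P = rng.random((13, 3)), rng.random((3, 300))
        Mn, Pn = ls.normalize_factors(M, P)
        assert np.allclose(M @ P, Mn @ Pn, rtol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        M, P = rng.random((13, 3)), rng.random((3, 300))
        once = ls.normalize_factors(M, P)
        twice = ls.normalize_factors(*once)
        assert np.allclose(once[0], twice[0]) and np.allclose(once[1], twice[1])

    def test_zero_primitive_dropped_with_warning(self):
        M = np.ones((13, 2))
        P = np.vstack([gaussian_bump(100, 40), np.zeros(300)])
        with pytest.warns(UserWarning, match="all-zero"):
            Mn, Pn = ls.normalize_factors(M, P)
        assert Pn.shape[0] == 1 and Mn.shape[1] == 1


class TestRankSelection:
    def test_globally_linear_curve_selects_one(self):
        curve = np.linspace(0.5, 0.98, 13)
        assert ls.select_rank(curve) == (1, False)

    def test_saturating_curve_elbow_found_by_brute_force(self):
        # linear from rank 3 onward; brute-force segment MSEs locate 3
        curve = np.concatenate([[0.5, 0.8],
                                0.95 + 0.004 * np.arange(11)])
        ranks = np.arange(1, 14, dtype=float)
        brute = None
        for k in range(1, 14):
            x, y = ranks[k - 1:], curve[k - 1:]
            coef = np.polyfit(x, y, 1)
            if np.mean((y - np.polyval(coef, x)) ** 2) < 1e-5:
                brute = k
                break
        assert brute == 3
        assert ls.select_rank(curve) == (3, False)

    def test_curve_never_linear_flagged_at_max_rank(self):
        rng = np.random.default_rng(0)
        curve = np.sort(np.clip(0.5 + 0.5 * rng.random(13), 0, 1))
        curve += np.linspace(0, 0.01, 13) * np.sin(np.arange(13))
        curve = np.clip(np.sort(curve), 0, 1)
        rank, flagged = ls.select_rank(curve, mse_threshold=1e-12)
        assert flagged is True and rank == 13

    def test_non_monotone_curve_warns(self):
        curve = np.array([0.5, 0.8, 0.79, 0.9] + [0.95] * 9)
        with pytest.warns(UserWarning, match="decreases"):
            ls.select_rank(curve)


class TestSynergyNMFEstimator:
    def test_fixed_rank_fit_exposes_sklearn_style_attributes(self):
        V, _, _ = _synthetic_v(noise=0.02, seed=5)
        est = ls.SynergyNMF(rank=3, n_restarts=3, random_state=0).fit(V)
        assert est.modules_.shape == (13, 3)
        assert est.primitives_.shape == (3, 300)
        assert est.primitives_.max(axis=1) == pytest.approx([1.0] * 3)
        assert 0.9 <= est.r_squared_ <= 1.0
        assert est.get_params()["rank"] == 3

    def test_auto_selection_on_clean_three_synergy_matrix(self):
        V, _, _ = _synthetic_v(p=3, seed=23, noise=0.03)
        est = ls.SynergyNMF(random_state=1).fit(V)
        assert np.all(np.diff(est.r_squared_curve_) >= -1e-4)
        assert est.rank_ == 3

    def test_reconstruction_shape_and_transform(self):
        V, _, _ = _synthetic_v(noise=0.02, seed=5)
        est = ls.SynergyNMF(rank=2, n_restarts=2, random_state=0).fit(V)
        assert est.reconstruct().shape == V.shape
        assert est.transform().shape == (2, 300)
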