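"""Muscle-synergy extraction by non-negative matrix factorization.

Each trial's normalized EMG matrix V (m muscles x 300 cycle points) is
factorized as V ~ M P, where M (m x p) holds the time-invariant motor
modules (muscle weightings) and P (p x 300) the time-dependent motor
primitives (activation patterns). The factorization uses the classical
Gaussian NMF of Lee & Seung: multiplicative updates minimizing the squared
Frobenius reconstruction error, which keep both factors nonnegative at
every iteration.

Model order (the number of synergies p) is selected from the curve of
reconstruction R^2 versus candidate rank: the chosen rank is the smallest
k such that a least-squares line fitted to the curve restricted to ranks
k..m has mean squared error below 1e-5, i.e. the first rank beyond which
adding synergies yields only a linear (noise-absorbing) R^2 gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import ConfigurationError, DataError, DegenerateInputError

_EPS = 1e-12

RANK_MSE_THRESHOLD = 1e-5


def _r_squared(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    resid = V - W @ H
    ss_res = float(np.square(resid).sum())
    ss_tot = float(np.square(V - V.mean()).sum())
    return 1.0 - ss_res / ss_tot


def _mu_nmf_batched(V, p, rng, n_restarts, tol, patience, max_iter):
    """Multiplicative updates run on all restarts as one stacked batch."""
    m, n = V.shape
    # uniform in (0, 1]: avoids exact zeros that would lock under MU
    W = 1.0 - rng.random((n_restarts, m, p))
    H = 1.0 - rng.random((n_restarts, p, n))
    ss_tot = float(np.square(V - V.mean()).sum())
    Vb = V[None]
    r2 = 1.0 - np.square(Vb - W @ H).sum(axis=(1, 2)) / ss_tot
    history = [r2]
    for it in range(max_iter):
        H *= (W.transpose(0, 2, 1) @ Vb) / (W.transpose(0, 2, 1) @ W @ H + _EPS)
        W *= (Vb @ H.transpose(0, 2, 1)) / (W @ (H @ H.transpose(0, 2, 1)) + _EPS)
        r2 = 1.0 - np.square(Vb - W @ H).sum(axis=(1, 2)) / ss_tot
        history.append(r2)
        # stop when no restart gained more than tol over the last
        # `patience` iterations
        if it + 1 >= patience and np.all(
                r2 - history[-patience - 1] < tol):
            break
    best = int(np.argmax(r2))
    return W[best], H[best], float(r2[best])


def nmf_factorize(V, p: int, seed=None, n_restarts: int = 10,
                  tol: float = 1e-5, patience: int = 20,
                  max_iter: int = 1000):
    """Factorize V (m x n, nonnegative) at rank p; best of seeded restarts.

    Returns ``(M, P, r_squared)`` with M (m x p), P (p x n), both
    nonnegative, reconstruction R^2 = 1 - ||V - MP||_F^2 / ||V - mean||_F^2.
    Each restart starts from elementwise-uniform factors and iterates the
    multiplicative updates until R^2 improves by less than ``tol`` over
    ``patience`` consecutive iterations (hard cap ``max_iter``). Seeded
    runs are bit-reproducible.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    m = V.shape[0]
    if np.any(V < 0) or not np.all(np.isfinite(V)):
        raise DataError("V must be nonnegative and finite")
    if not 1 <= p <= m:
        raise ConfigurationError(f"rank {p} outside 1..{m}")
    if not V.any():
        raise DegenerateInputError("all-zero EMG matrix cannot be factorized")
    rng = np.random.default_rng(seed)
    return _mu_nmf_batched(V, p, rng, n_restarts, tol, patience, max_iter)


def normalize_factors(M, P):
    """Rescale each primitive to unit maximum, transferring scale to M.

    NMF has a per-synergy scale indeterminacy; fixing max(P_i) = 1 makes
    primitives comparable across trials while leaving the reconstruction
    M @ P unchanged. All-zero primitives are dropped with a warning.
    """
    M = np.array(M, dtype=float)
    P = np.atleast_2d(np.array(P, dtype=float))
    scales = P.max(axis=1)
    keep = scales > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} all-zero primitives",
                      stacklevel=2)
        M, P, scales = M[:, keep], P[keep], scales[keep]
    return M * scales[None, :], P / scales[:, None]


def select_rank(r_squared_curve, mse_threshold: float = RANK_MSE_THRESHOLD,
                monotone_tol: float = 1e-4) -> tuple[int, bool]:
    """Model order from the R^2-vs-rank curve.

    Returns ``(rank, flagged)``: the smallest rank k whose trailing curve
    segment (ranks k..m) is fitted by a least-squares line with MSE below
    ``mse_threshold``. If no segment satisfies the criterion the maximum
    rank is returned with ``flagged=True``.
    """
    curve = np.asarray(r_squared_curve, dtype=float).ravel()
    m = curve.size
    if m < 1 or np.any(curve < -1e-9) or np.any(curve > 1 + 1e-9):
        raise DataError("R^2 curve must contain values in [0, 1]")
    if np.any(np.diff(curve) < -monotone_tol):
        warnings.warn("R^2 curve decreases beyond tolerance; proceeding",
                      stacklevel=2)
    ranks = np.arange(1, m + 1, dtype=float)
    for k in range(1, m + 1):
        x, y = ranks[k - 1:], curve[k - 1:]
        if x.size < 3:
            # a line through <= 2 points is vacuous, not evidence of
            # saturation
            break
        slope, intercept = np.polyfit(x, y, 1)
        mse = float(np.mean((y - (slope * x + intercept)) ** 2))
        if mse < mse_threshold:
            return k, False
    return m, True


@dataclass(frozen=True)
class SynergySet:
    """One trial's factorization: modules, primitives, rank, fit quality."""

    modules: np.ndarray = field(repr=False)
    primitives: np.ndarray = field(repr=False)
    rank: int = 0
    r_squared: float = 0.0
    r_squared_curve: np.ndarray = field(default=None, repr=False)
    rank_flagged: bool = False
    seed: int | None = None


class SynergyNMF(BaseEstimator):
    """NMF synergy extractor with automatic model-order selection.

    Fits the full rank family 1..n_muscles on one trial's normalized EMG
    matrix (muscles x 300), builds the R^2 curve, selects the rank by the
    trailing-linear-regression rule and exposes the selected factorization.

    Parameters
    ----------
    rank : int or None
        Fixed model order; ``None`` (default) selects it from the R^2 curve.
    n_restarts : int
        Random restarts per rank; the best-R^2 run is kept.
    tol, patience, max_iter : convergence controls of the multiplicative
        updates (stop after ``patience`` consecutive iterations improving
        R^2 by less than ``tol``).
    rank_mse_threshold : float
        MSE bound of the rank-selection regression rule.
    random_state : int or None
        Seed; restarts and ranks draw from independent substreams.

    Attributes
    ----------
    modules_ : ndarray (m, p) — motor modules (muscle weightings).
    primitives_ : ndarray (p, 300) — motor primitives, unit maximum each.
    rank_ : int — selected number of synergies.
    r_squared_ : float — reconstruction R^2 at the selected rank.
    r_squared_curve_ : ndarray (m,) — R^2 over candidate ranks 1..m.
    rank_flagged_ : bool — True when no trailing segment met the MSE rule.
    """

    def __init__(self, rank: int | None = None, n_restarts: int = 10,
                 tol: float = 1e-5, patience: int = 20, max_iter: int = 1000,
                 rank_mse_threshold: float = RANK_MSE_THRESHOLD,
                 random_state: int | None = None):
        self.rank = rank
        self.n_restarts = n_restarts
        self.tol = tol
        self.patience = patience
        self.max_iter = max_iter
        self.rank_mse_threshold = rank_mse_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        V = np.atleast_2d(np.asarray(X, dtype=float))
        m = V.shape[0]
        ss = np.random.SeedSequence(self.random_state)
        rank_seeds = ss.spawn(m)
        curve = np.empty(m)
        factors = {}
        ranks = range(1, m + 1) if self.rank is None else [self.rank]
        if self.rank is not None and not 1 <= self.rank <= m:
            raise ConfigurationError(f"rank {self.rank} outside 1..{m}")
        for p in ranks:
            M, P, r2 = nmf_factorize(
                V, p, seed=rank_seeds[p - 1], n_restarts=self.n_restarts,
                tol=self.tol, patience=self.patience, max_iter=self.max_iter,
            )
            factors[p] = (M, P, r2)
            curve[p - 1] = r2
        if self.rank is None:
            self.r_squared_curve_ = curve
            self.rank_, self.rank_flagged_ = select_rank(
                curve, mse_threshold=self.rank_mse_threshold)
        else:
            self.r_squared_curve_ = None
            self.rank_, self.rank_flagged_ = self.rank, False
        M, P, r2 = factors[self.rank_]
        self.modules_, self.primitives_ = normalize_factors(M, P)
        self.r_squared_ = r2
        self.n_features_in_ = V.shape[1]
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the primitives of the fitted trial (p x 300)."""
        return self.primitives_

    def reconstruct(self) -> np.ndarray:
        """Reconstructed EMG matrix M @ P at the selected rank."""
        return self.modules_ @ self.primitives_

    def to_synergy_set(self) -> SynergySet:
        return SynergySet(
            modules=self.modules_,
            primitives=self.primitives_,
            rank=self.rank_,
            r_squared=self.r_squared_,
            r_squared_curve=self.r_squared_curve_,
            rank_flagged=self.rank_flagged_,
            seed=self.random_state,
        )
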