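"""Unsupervised classification of extracted synergies.

Synergies pooled across the trials of one condition are assigned to
functional clusters without operator intervention:

1. k-means (20 restarts) clusters the 300-point motor primitives for every
   candidate cluster count k = 1..m (m = number of muscles); the curve of
   within-cluster sum of squares (WSS) versus k is min-max normalized.
2. The cluster count is the number of muscles minus the number of trailing
   curve points that can be linearly interpolated (chord through the
   segment's endpoints) with MSE below 1e-3 — an automated elbow rule.
3. Motor modules are clustered with that same k imposed.
4. Each clustering is scored by (mean FWHM + mean CoA) / 300 of the
   primitives as grouped by it; the module-based partition is aligned to
   the primitive-based one by maximal co-occurrence. Synergies on which the
   two partitions agree are fundamental; discordant ones are combined
   (spurious merges). If the partitions do not match (score difference
   beyond tolerance, or aligned agreement at chance level) only the
   primitive-based classification is retained.

Clusters are finally named by the circular center of activity (CoA) of
their centroid primitives: for three clusters, touchdown, weight
acceptance and stabilization in increasing CoA order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .exceptions import ConfigurationError, DataError
from .metrics import coa, fwhm
from .muscles import N_MUSCLES

ELBOW_MSE_THRESHOLD = 1e-3
FUNCTIONAL_NAMES_3 = ("touchdown", "weight_acceptance", "stabilization")


def _kmeans(X: np.ndarray, k: int, seed, n_init: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)


def cluster_primitives(primitives, m: int = N_MUSCLES, seed=None,
                       n_init: int = 20):
    """k-means over candidate counts 1..m on pooled 300-point primitives.

    Returns ``(wss_norm, models)``: the min-max normalized WSS curve and
    the fitted k-means model per candidate k (k capped at the number of
    series).
    """
    X = np.atleast_2d(np.asarray(primitives, dtype=float))
    if X.shape[0] < 2:
        raise DataError("need at least two primitives to cluster")
    rng = np.random.default_rng(seed)
    k_max = min(m, X.shape[0])
    models = {}
    wss = np.empty(m)
    for k in range(1, m + 1):
        kk = min(k, k_max)
        if kk not in models:
            models[kk] = _kmeans(X, kk, int(rng.integers(2**31)), n_init)
        wss[k - 1] = models[kk].inertia_
    span = wss.max() - wss.min()
    wss_norm = (wss - wss.min()) / span if span > 0 else np.zeros(m)
    return wss_norm, models


def select_k(wss_curve, m: int = N_MUSCLES,
             mse_threshold: float = ELBOW_MSE_THRESHOLD) -> int:
    """Cluster count from the normalized WSS curve (automated elbow).

    Returns the smallest k such that the least-squares line fitted to the
    trailing curve segment (cluster counts k..m) interpolates it with MSE
    below ``mse_threshold`` — the first count from which adding clusters
    only shaves WSS linearly. A curve that is linear over all m points
    yields k = 1; the rule mirrors the R^2-regression rule used for the
    NMF model order, with the elbow threshold 1e-3 on the [0, 1]-normalized
    curve.
    """
    curve = np.asarray(wss_curve, dtype=float).ravel()
    if curve.size != m:
        raise DataError(f"WSS curve must have {m} points, got {curve.size}")
    x = np.arange(1, m + 1, dtype=float)
    for k in range(1, m + 1):
        xx, yy = x[k - 1:], curve[k - 1:]
        if xx.size < 3:  # a chord through <= 2 points carries no evidence
            break
        slope, intercept = np.polyfit(xx, yy, 1)
        if float(np.mean((yy - (slope * xx + intercept)) ** 2)) < mse_threshold:
            return k
    return m


def cluster_modules(modules, k: int, seed=None, n_init: int = 20) -> np.ndarray:
    """k-means on module vectors with the primitive-derived k imposed."""
    X = np.atleast_2d(np.asarray(modules, dtype=float))
    if k > X.shape[0]:
        raise ConfigurationError(
            f"cannot form {k} clusters from {X.shape[0]} synergies")
    return _kmeans(X, k, seed, n_init).labels_


def score_classification(primitives, assignments) -> float:
    """Partition score (mean FWHM + mean CoA) / 300 of grouped primitives.

    FWHM and CoA are averaged within each cluster, those cluster means are
    averaged across clusters, and the two grand means are summed and
    divided by the cycle length. The score depends on the grouping only
    through the unweighted cluster means, and is invariant to relabeling.
    """
    P = np.atleast_2d(np.asarray(primitives, dtype=float))
    labels = np.asarray(assignments)
    f_means, c_means = [], []
    for lab in np.unique(labels):
        rows = P[labels == lab]
        f_means.append(np.mean([fwhm(r) for r in rows]))
        c_means.append(np.mean([coa(r) for r in rows]))
    return float((np.mean(f_means) + np.mean(c_means)) / P.shape[1])


def _align_labels(ref: np.ndarray, other: np.ndarray, k: int) -> np.ndarray:
    """Map ``other``'s labels onto ``ref``'s by maximal co-occurrence."""
    cont = np.zeros((k, k))
    for r, o in zip(ref, other):
        cont[r, o] += 1
    if k <= 6:
        best, best_perm = -1.0, tuple(range(k))
        for perm in permutations(range(k)):
            s = sum(cont[i, perm[i]] for i in range(k))
            if s > best:
                best, best_perm = s, perm
        mapping = {perm_j: i for i, perm_j in enumerate(best_perm)}
    else:
        rows, cols = linear_sum_assignment(-cont)
        mapping = {c: r for r, c in zip(rows, cols)}
    return np.array([mapping[o] for o in other])


def label_synergies(assignments_primitive, assignments_module,
                    score_primitive: float, score_module: float,
                    score_tol: float = 0.05, min_agreement: float = 0.5):
    """Fundamental/combined labels from the two partitions.

    Module-cluster labels are aligned to primitive-cluster labels by the
    optimal one-to-one matching on the contingency table. A synergy whose
    aligned assignments agree is fundamental, a discordant one combined.
    Matching fails — and the primitive-based partition alone is retained,
    with every synergy labeled fundamental by it — when the two partition
    scores differ by more than ``score_tol`` or the aligned agreement rate
    does not exceed ``min_agreement``.

    Returns ``(labels, aligned_module_assignments, matching_failed)``.
    """
    ap = np.asarray(assignments_primitive)
    am = np.asarray(assignments_module)
    if ap.size != am.size:
        raise DataError("partition lengths differ")
    k = int(max(ap.max(), am.max())) + 1
    aligned = _align_labels(ap, am, k)
    agreement = float(np.mean(aligned == ap))
    failed = abs(score_primitive - score_module) > score_tol or \
        agreement <= min_agreement
    if failed:
        labels = np.full(ap.size, "fundamental", dtype=object)
    else:
        labels = np.where(aligned == ap, "fundamental", "combined").astype(object)
    return labels, aligned, failed


@dataclass(frozen=True)
class ClusteringResult:
    """Full classification of a pooled set of synergies."""

    k: int
    assignments_primitive: np.ndarray = field(repr=False)
    assignments_module: np.ndarray = field(repr=False)
    wss_curve: np.ndarray = field(repr=False)
    score_primitive: float = 0.0
    score_module: float = 0.0
    labels: np.ndarray = field(default=None, repr=False)
    centroid_primitives: np.ndarray = field(default=None, repr=False)
    matching_failed: bool = False
    functional_names: tuple[str, ...] = ()


class SynergyClassifier(BaseEstimator):
    """Primitive- and module-based k-means classification of synergies.

    Parameters
    ----------
    n_muscles : int
        Upper bound m of the candidate cluster counts (defaults to 13).
    elbow_mse_threshold : float
        MSE bound of the WSS elbow rule.
    n_init : int
        Random k-means restarts per candidate count.
    score_tol, min_agreement : float
        Matching-failure thresholds of :func:`label_synergies`.
    random_state : int or None

    Attributes
    ----------
    k_ : selected cluster count.
    assignments_primitive_, assignments_module_ : per-synergy labels
        (module labels aligned to the primitive clustering).
    labels_ : per-synergy 'fundamental' / 'combined'.
    wss_curve_ : normalized WSS over k = 1..m.
    score_primitive_, score_module_ : partition scores.
    centroid_primitives_ : (k, 300) cluster centroids.
    functional_names_ : per-cluster names ordered by cluster index; for
        k = 3: touchdown / weight_acceptance / stabilization by centroid CoA.
    matching_failed_ : bool.
    """

    def __init__(self, n_muscles: int = N_MUSCLES,
                 elbow_mse_threshold: float = ELBOW_MSE_THRESHOLD,
                 n_init: int = 20, score_tol: float = 0.05,
                 min_agreement: float = 0.5,
                 random_state: int | None = None):
        self.n_muscles = n_muscles
        self.elbow_mse_threshold = elbow_mse_threshold
        self.n_init = n_init
        self.score_tol = score_tol
        self.min_agreement = min_agreement
        self.random_state = random_state

    def fit(self, primitives, modules):
        """Classify pooled synergies given (n, 300) primitives and (n, m) modules."""
        P = np.atleast_2d(np.asarray(primitives, dtype=float))
        M = np.atleast_2d(np.asarray(modules, dtype=float))
        if P.shape[0] != M.shape[0]:
            raise DataError("primitive and module counts differ")
        ss = np.random.SeedSequence(self.random_state).spawn(2)
        wss, models = cluster_primitives(
            P, m=self.n_muscles, seed=ss[0], n_init=self.n_init)
        self.wss_curve_ = wss
        self.k_ = select_k(wss, m=self.n_muscles,
                           mse_threshold=self.elbow_mse_threshold)
        km = models[min(self.k_, max(models))]
        ap = km.labels_
        am_raw = cluster_modules(
            M, self.k_, seed=int(np.random.default_rng(ss[1]).integers(2**31)),
            n_init=self.n_init)
        self.score_primitive_ = score_classification(P, ap)
        self.score_module_ = score_classification(P, am_raw)
        labels, aligned, failed = label_synergies(
            ap, am_raw, self.score_primitive_, self.score_module_,
            score_tol=self.score_tol, min_agreement=self.min_agreement)
        self.assignments_primitive_ = ap
        self.assignments_module_ = aligned
        self.labels_ = labels
        self.matching_failed_ = failed
        self.centroid_primitives_ = km.cluster_centers_
        self.functional_names_ = self._name_clusters()
        return self

    def _name_clusters(self) -> tuple[str, ...]:
        """Name clusters by centroid CoA order along the cycle."""
        coas = [coa(c) for c in self.centroid_primitives_]
        order = np.argsort(coas)
        names = [""] * self.k_
        base = FUNCTIONAL_NAMES_3 if self.k_ == 3 else tuple(
            f"cluster_{i + 1}" for i in range(self.k_))
        for rank, cluster in enumerate(order):
            names[cluster] = base[rank]
        return tuple(names)

    def predict(self, primitives) -> np.ndarray:
        """Assign new primitives to the fitted primitive clusters."""
        P = np.atleast_2d(np.asarray(primitives, dtype=float))
        d = ((P[:, None, :] - self.centroid_primitives_[None]) ** 2).sum(-1)
        return np.argmin(d, axis=1)

    def to_result(self) -> ClusteringResult:
        return ClusteringResult(
            k=self.k_,
            assignments_primitive=self.assignments_primitive_,
            assignments_module=self.assignments_module_,
            wss_curve=self.wss_curve_,
            score_primitive=self.score_primitive_,
            score_module=self.score_module_,
            labels=self.labels_,
            centroid_primitives=self.centroid_primitives_,
            matching_failed=self.matching_failed_,
            functional_names=self.functional_names_,
        )
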