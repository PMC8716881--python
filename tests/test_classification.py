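import numpy as np
import pytest

import landsyn as ls
from landsyn.exceptions import ConfigurationError

from conftest import gaussian_bump


def _bump_family(center, n, rng, jitter=4.0, width=40.0):
    return np.vstack([gaussian_bump(center + rng.normal(0, jitter), width)
                      for _ in range(n)])


class TestClusterPrimitives:
    def test_two_separated_families_split_purely(self):
        rng = np.random.default_rng(0)
        X = np.vstack([_bump_family(80, 10, rng), _bump_family(180, 10, rng)])
        wss, models = ls.cluster_primitives(X, seed=1)
        km = models[2]
        labels = km.labels_
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        # brute-force nearest-centroid agreement
        d = ((X[:, None] - km.cluster_centers_[None]) ** 2).sum(-1)
        assert np.array_equal(np.argmin(d, axis=1), labels)

    def test_identical_series_have_zero_wss_at_one_cluster(self):
        X = np.tile(gaussian_bump(150, 40), (6, 1))
        wss, models = ls.cluster_primitives(X, seed=0)
        assert models[1].inertia_ == pytest.approx(0.0, abs=1e-12)

    def test_seeded_runs_reproducible(self):
        rng = np.random.default_rng(3)
        X = np.vstack([_bump_family(80, 6, rng), _bump_family(200, 6, rng)])
        w1, m1 = ls.cluster_primitives(X, seed=9)
        w2, m2 = ls.cluster_primitives(X, seed=9)
        assert np.array_equal(w1, w2)
        assert np.array_equal(m1[3].labels_, m2[3].labels_)


class TestSelectK:
    @staticmethod
    def _brute(curve, thr=1e-3):
        x = np.arange(1, 14, dtype=float)
        for k in range(1, 14):
            xx, yy = x[k - 1:], curve[k - 1:]
            if xx.size < 2:
                return k
            coef = np.polyfit(xx, yy, 1)
            if np.mean((yy - np.polyval(coef, xx)) ** 2) < thr:
                return k
        return 13

    def test_linear_curve_clamps_to_one(self):
        assert ls.select_k(np.linspace(1, 0, 13)) == 1

    def test_sharp_elbow_located_by_brute_force(self):
        curve = np.concatenate([[1.0, 0.45], 0.05 * np.linspace(1, 0, 11)])
        assert self._brute(curve) == 3
        assert ls.select_k(curve) == 3

    def test_tiny_tail_noise_does_not_move_elbow(self):
        rng = np.random.default_rng(7)
        curve = np.concatenate([[1.0, 0.45], 0.05 * np.linspace(1, 0, 11)])
        noisy = curve + np.concatenate([[0, 0], 1e-5 * rng.standard_normal(11)])
        assert ls.select_k(noisy) == ls.select_k(curve)


class TestClusterModules:
    def test_disjoint_muscle_groups_recovered(self):
        rng = np.random.default_rng(1)
        groups = [np.arange(0, 4), np.arange(4, 9), np.arange(9, 13)]
        mods = []
        for g in groups:
            for _ in range(8):
                v = 0.05 * rng.random(13)
                v[g] += 1.0
                mods.append(v)
        labels = ls.cluster_modules(np.vstack(mods), k=3, seed=2)
        for i in range(3):
            assert len(set(labels[8 * i:8 * (i + 1)])) == 1

    def test_single_cluster_trivial(self):
        X = np.random.default_rng(0).random((5, 13))
        assert set(ls.cluster_modules(X, k=1, seed=0)) == {0}

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(4)
        X = np.vstack([_bump_family(80, 5, rng)[:, :13],
                       _bump_family(200, 5, rng)[:, :13]])
        perm = rng.permutation(10)
        a = ls.cluster_modules(X, k=2, seed=3)
        b = ls.cluster_modules(X[perm], k=2, seed=3)
        same = (a[perm] == b).all()
        flipped = (a[perm] == 1 - b).all()
        assert same or flipped

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ConfigurationError):
            ls.cluster_modules(np.ones((2, 13)), k=3)


class TestScore:
    def test_single_primitive_arithmetic(self):
        x = np.zeros(300)
        x[120:180] = 1.0  # FWHM 60, CoA ~ 150
        score = ls.score_classification(x[None, :], [0])
        assert score == pytest.approx((60 + 149.5) / 300, abs=0.01)

    def test_identical_partitions_identical_scores(self):
        rng = np.random.default_rng(2)
        X = np.vstack([_bump_family(80, 4, rng), _bump_family(200, 4, rng)])
        labels = np.array([0] * 4 + [1] * 4)
        assert ls.score_classification(X, labels) == \
            ls.score_classification(X, labels.copy())

    def test_invariant_to_cluster_relabeling(self):
        rng = np.random.default_rng(2)
        X = np.vstack([_bump_family(80, 4, rng), _bump_family(200, 4, rng)])
        labels = np.array([0] * 4 + [1] * 4)
        assert ls.score_classification(X, labels) == \
            pytest.approx(ls.score_classification(X, 1 - labels))


class TestLabeling:
    def test_consistent_partitions_all_fundamental(self):
        ap = np.array([0, 0, 1, 1, 2, 2])
        am = np.array([2, 2, 0, 0, 1, 1])  # same partition, relabeled
        labels, aligned, failed = ls.label_synergies(ap, am, 0.5, 0.5)
        assert not failed
        assert np.array_equal(aligned, ap)
        assert set(labels) == {"fundamental"}

    def test_one_swapped_synergy_exactly_one_combined(self):
        ap = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        am = ap.copy()
        am[0] = 1  # one discordant synergy
        labels, _, failed = ls.label_synergies(ap, am, 0.5, 0.5)
        assert not failed
        assert list(labels).count("combined") == 1
        assert labels[0] == "combined"

    def test_random_module_partition_fails_matching(self):
        rng = np.random.default_rng(0)
        ap = np.repeat([0, 1, 2], 30)
        am = rng.integers(0, 3, ap.size)
        labels, _, failed = ls.label_synergies(ap, am, 0.5, 0.5)
        assert failed
        assert set(labels) == {"fundamental"}  # primitive-only retained

    def test_score_gap_beyond_tolerance_fails_matching(self):
        ap = np.array([0, 1, 0, 1])
        labels, _, failed = ls.label_synergies(ap, ap, 0.70, 0.60)
        assert failed


class TestSynergyClassifierEstimator:
    def test_three_family_cohort_fully_recovered(self):
        rng = np.random.default_rng(10)
        prims, mods = [], []
        centers = [(90, 0), (120, 1), (210, 2)]
        groups = [np.arange(0, 4), np.arange(4, 9), np.arange(9, 13)]
        for c, gi in centers:
            for _ in range(12):
                prims.append(gaussian_bump(c + rng.normal(0, 4), 45))
                v = 0.1 * rng.random(13)
                v[groups[gi]] += 1.0
                mods.append(v)
        clf = ls.SynergyClassifier(random_state=0).fit(
            np.vstack(prims), np.vstack(mods))
        assert clf.k_ == 3
        assert not clf.matching_failed_
        assert np.mean(clf.labels_ == "fundamental") == 1.0
        by_coa = dict(zip(clf.functional_names_,
                          [ls.coa(c) for c in clf.centroid_primitives_]))
        assert by_coa["touchdown"] < by_coa["weight_acceptance"] \
            < by_coa["stabilization"]

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(11)
        P = np.vstack([_bump_family(80, 8, rng), _bump_family(200, 8, rng)])
        M = rng.random((16, 13))
        a = ls.SynergyClassifier(random_state=3).fit(P, M)
        b = ls.SynergyClassifier(random_state=3).fit(P, M)
        assert a.k_ == b.k_
        assert np.array_equal(a.assignments_primitive_,
                              b.assignments_primitive_)
        assert np.array_equal(a.labels_, b.labels_)
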