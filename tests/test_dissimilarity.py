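import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon, pdist, squareform
from scipy.stats import rankdata

from comland.dissimilarity import (anosim, jsd_matrix, jsd_pair, pcoa)


def naive_jsd(p, q, base=2):
    """Independent double-loop KL evaluation with the 0 log 0 convention."""
    m = 0.5 * (np.asarray(p) + np.asarray(q))
    total = 0.0
    for a, b in ((p, m), (q, m)):
        for ai, bi in zip(a, b):
            if ai > 0:
                total += 0.5 * ai * np.log(ai / bi)
    return total / np.log(base)


def brute_anosim_r(d, labels):
    """Rank-formula oracle written as an explicit double loop."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    within, between = [], []
    for (i, j), r in zip(zip(*iu), ranks):
        (within if labels[i] == labels[j] else between).append(r)
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4)


class TestJsdPair:
    def test_identical_distributions_give_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jsd_pair(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_supports_give_maximum(self):
        assert jsd_pair([1, 0], [0, 1], base=2) == pytest.approx(1.0)

    def test_hand_derived_value(self):
        # 0.5 KL((.5,.5)||(.75,.25)) + 0.5 KL((1,0)||(.75,.25)) in bits
        assert jsd_pair([0.5, 0.5], [1.0, 0.0], base=2) == pytest.approx(
            0.311278, abs=1e-6)

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            jsd_pair([0.5, 0.4], [0.5, 0.5])

    def test_agrees_with_scipy(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.full(15, 0.5))
            q = rng.dirichlet(np.full(15, 0.5))
            assert jsd_pair(p, q, base=2) == pytest.approx(
                jensenshannon(p, q, base=2) ** 2, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.full(8, 0.4))
        q = rng.dirichlet(np.full(8, 0.4))
        d = jsd_pair(p, q, base=2)
        assert d == pytest.approx(jsd_pair(q, p, base=2), abs=1e-12)
        assert 0 <= d <= 1


class TestJsdMatrix:
    def test_matches_double_loop_oracle(self, rng):
        comp = rng.dirichlet(np.full(12, 0.6), size=10)
        d = jsd_matrix(comp, as_distance=False)
        for i in range(10):
            for j in range(10):
                assert d.data[i, j] == pytest.approx(
                    naive_jsd(comp[i], comp[j]), abs=1e-12)

    def test_single_sample_matrix(self, rng):
        d = jsd_matrix(rng.dirichlet([1, 1, 1], size=1))
        assert d.shape == (1, 1) and d.data[0, 0] == 0

    def test_sqrt_distance_satisfies_triangle_inequality(self, rng):
        comp = rng.dirichlet(np.full(10, 0.4), size=30)
        d = jsd_matrix(comp, as_distance=True).data
        trips = rng.integers(0, 30, size=(1000, 3))
        for i, j, k in trips:
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_symmetric_zero_diagonal(self, rng):
        comp = rng.dirichlet(np.full(6, 0.5), size=8)
        d = jsd_matrix(comp).data
        np.testing.assert_allclose(d, d.T, atol=1e-15)
        assert np.all(np.diag(d) == 0)


class TestPcoa:
    def test_recovers_planar_configuration(self, rng):
        pts = rng.normal(size=(15, 2))
        d = squareform(pdist(pts))
        res = pcoa(d)
        np.testing.assert_allclose(squareform(pdist(res.coordinates)), d,
                                   atol=1e-10)

    def test_agrees_with_skbio(self, rng):
        pts = rng.normal(size=(10, 3))
        d = squareform(pdist(pts))
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d),
                                             method="eigh")
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues)[::-1],
            np.sort(np.asarray(theirs.eigvals))[::-1][:len(ours.eigenvalues)],
            atol=1e-8)

    def test_duplicate_samples_get_identical_coordinates(self):
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(d)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1],
                                   atol=1e-10)

    def test_eigenvalues_sorted_and_positive(self, rng):
        comp = rng.dirichlet(np.full(8, 0.5), size=12)
        res = pcoa(jsd_matrix(comp))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues > 0)

    def test_axis_truncation_warns(self, rng):
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            res = pcoa(d, n_axes=10)
        assert res.coordinates.shape[1] <= 5


class TestAnosim:
    def test_spec_hand_ranked_example(self):
        # groups {A,A,B,B}; within pairs ranked 1,2; between ranked 3..6
        d = np.array([
            [0.0, 0.1, 0.5, 0.6],
            [0.1, 0.0, 0.7, 0.8],
            [0.5, 0.7, 0.0, 0.2],
            [0.6, 0.8, 0.2, 0.0]])
        res = anosim(d, ["A", "A", "B", "B"], n_perm=99, seed=0)
        assert res.r == pytest.approx(brute_anosim_r(d, ["A", "A", "B", "B"]))
        assert res.r == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            a = rng.random((10, 10))
            d = (a + a.T) / 2
            np.fill_diagonal(d, 0)
            labels = rng.integers(0, 3, 10)
            if len(np.unique(labels)) < 2:
                labels[0] = (labels[0] + 1) % 3
            res = anosim(d, labels, n_perm=5, seed=0)
            assert res.r == pytest.approx(brute_anosim_r(d, labels),
                                          abs=1e-12)

    def test_matches_skbio(self, rng):
        a = rng.random((12, 12))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        labels = list("AAAABBBBCCCC")
        ours = anosim(d, labels, n_perm=9, seed=0)
        theirs = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d), labels, permutations=9)
        assert ours.r == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_permutation_null_centred_at_zero(self, rng):
        a = rng.random((20, 20))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        labels = np.repeat([0, 1], 10)
        res = anosim(d, labels, n_perm=1000, seed=1)
        assert abs(res.permuted_r.mean()) < 0.05

    def test_rank_invariance_under_monotone_transform(self, rng):
        a = rng.random((15, 15))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        labels = rng.integers(0, 2, 15)
        labels[:2] = [0, 1]
        r1 = anosim(d, labels, n_perm=5, seed=0).r
        r2 = anosim(d ** 2, labels, n_perm=5, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_planted_clusters_beat_permutation_null(self, rng):
        pts = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(4, 1, (10, 3))])
        d = squareform(pdist(pts))
        labels = np.repeat([0, 1], 10)
        res = anosim(d, labels, n_perm=500, seed=2)
        assert res.r > np.percentile(res.permuted_r, 95)
        assert res.p_value < 0.05

    def test_p_value_floor_and_group_validation(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValueError):
            anosim(d, ["A", "A"], n_perm=9)
        with pytest.raises(ValueError):
            anosim(d, ["A", "B"], n_perm=9)  # every sample its own group
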