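"""Distance, PAM, CH index, cluster-number voting, PCoA and heatmap ordering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from conftest import euclidean_distance_matrix
from infantgut.community import (
    MAX_JSD_DISTANCE,
    DistanceMatrix,
    ch_index,
    estimate_k,
    hclust_complete,
    jsd_distance,
    jsd_matrix,
    pam,
    pcoa,
)
from infantgut.profiles import AbundanceTable
from infantgut.simulate import SyntheticCohortConfig, generate_cohort


def _prob_vectors(dim):
    return st.lists(
        st.floats(0.0, 1.0, allow_nan=False), min_size=dim, max_size=dim
    ).map(lambda v: np.asarray(v) + 1e-9).map(lambda v: v / v.sum())


class TestJsdDistance:
    def test_identical_distributions_zero(self):
        assert jsd_distance([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_supports_analytic_maximum(self):
        assert jsd_distance([1, 0], [0, 1]) == pytest.approx(
            math.sqrt(math.log(2)), abs=1e-12
        )
        assert MAX_JSD_DISTANCE == pytest.approx(math.sqrt(math.log(2)))

    def test_matches_term_by_term_entropy_evaluation(self):
        p, q = np.array([0.5, 0.5]), np.array([0.25, 0.75])
        m = (p + q) / 2

        def h(v):
            return -sum(x * math.log(x) for x in v if x > 0)

        expected = math.sqrt(h(m) - (h(p) + h(q)) / 2)
        assert jsd_distance(p, q) == pytest.approx(expected, abs=1e-15)

    def test_agrees_with_scipy_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            assert jsd_distance(p, q) == pytest.approx(
                jensenshannon(p, q), abs=1e-12
            )

    def test_rejects_negative_and_mismatched(self):
        with pytest.raises(ValueError):
            jsd_distance([1.2, -0.2], [0.5, 0.5])
        with pytest.raises(ValueError):
            jsd_distance([1.0], [0.5, 0.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(p=_prob_vectors(5), q=_prob_vectors(5), r=_prob_vectors(5))
    def test_metric_properties(self, p, q, r):
        dpq = jsd_distance(p, q)
        assert 0 <= dpq <= MAX_JSD_DISTANCE + 1e-12
        assert dpq == pytest.approx(jsd_distance(q, p), abs=1e-12)
        assert dpq <= jsd_distance(p, r) + jsd_distance(r, q) + 1e-9


class TestJsdMatrix:
    def test_identical_rows_give_zero_off_diagonal(self):
        df = pd.DataFrame([[0.4, 0.6], [0.4, 0.6]], index=["x", "y"],
                          columns=["A", "B"])
        dm = jsd_matrix(AbundanceTable(df))
        assert dm.d[0, 1] == 0.0

    def test_triangle_inequality_all_triples(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.dirichlet(np.ones(4), size=6),
                          index=[f"s{i}" for i in range(6)],
                          columns=list("ABCD"))
        dm = jsd_matrix(AbundanceTable(df))
        for i, j, k in itertools.permutations(range(6), 3):
            assert dm.d[i, j] <= dm.d[i, k] + dm.d[k, j] + 1e-9

    def test_permutation_equivariance(self, tiny_table):
        dm = jsd_matrix(tiny_table)
        perm = ["b2", "a1", "b1", "a2"]
        dm2 = jsd_matrix(tiny_table.subset(perm))
        for i, si in enumerate(perm):
            for j, sj in enumerate(perm):
                oi, oj = dm.sample_ids.index(si), dm.sample_ids.index(sj)
                assert dm2.d[i, j] == pytest.approx(dm.d[oi, oj], abs=1e-15)

    def test_single_sample_rejected(self):
        df = pd.DataFrame([[1.0]], index=["s"], columns=["A"])
        with pytest.raises(ValueError):
            jsd_matrix(AbundanceTable(df))


def _brute_force_pam_cost(d, k):
    n = d.shape[0]
    return min(
        d[:, list(m)].min(axis=1).sum() for m in itertools.combinations(range(n), k)
    )


class TestPam:
    def test_two_well_separated_pairs(self):
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 1.0
        dm = DistanceMatrix(list("ABCD"), d)
        sol = pam(dm, 2)
        assert sol.total_cost == pytest.approx(2.0)
        assert {frozenset(sol.members(c)) for c in (1, 2)} == {
            frozenset("AB"), frozenset("CD")
        }
        assert sol.total_cost == pytest.approx(_brute_force_pam_cost(d, 2))

    def test_k_equals_n_zero_cost(self):
        dm = euclidean_distance_matrix(np.arange(5.0))
        sol = pam(dm, 5)
        assert sol.total_cost == 0.0
        assert sorted(sol.medoid_ids) == sorted(dm.sample_ids)

    def test_matches_exhaustive_search_on_small_instances(self):
        """BUILD+SWAP reaches the global medoid optimum on nearly every tiny
        instance and is never worse than a single-swap local optimum."""
        from infantgut.community import _pam_build

        rng = np.random.default_rng(11)
        runs, global_matches = 60, 0
        for _ in range(runs):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, n))
            dm = euclidean_distance_matrix(rng.random((n, 2)))
            sol = pam(dm, k)
            best = _brute_force_pam_cost(dm.d, k)
            assert sol.total_cost >= best - 1e-12
            # SWAP never worsens the BUILD seeding
            build_cost = dm.d[:, _pam_build(dm.d, k)].min(axis=1).sum()
            assert sol.total_cost <= build_cost + 1e-12
            if sol.total_cost == pytest.approx(best, abs=1e-12):
                global_matches += 1
            else:
                # any miss must still be a genuine single-swap local optimum
                meds = {dm.sample_ids.index(s) for s in sol.medoid_ids}
                for m in list(meds):
                    for h in set(range(n)) - meds:
                        cand = list(meds - {m} | {h})
                        assert dm.d[:, cand].min(axis=1).sum() >= sol.total_cost - 1e-12
        # ~95% global-match rate, 3-sigma binomial allowance at 60 draws
        assert global_matches >= int(0.95 * runs - 3 * np.sqrt(runs * 0.05 * 0.95))

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        dm = euclidean_distance_matrix(rng.random((12, 2)))
        s1, s2 = pam(dm, 3), pam(dm, 3)
        assert s1.medoid_ids == s2.medoid_ids
        assert s1.assignment == s2.assignment

    def test_medoid_in_own_cluster_and_no_empty_cluster(self):
        rng = np.random.default_rng(4)
        dm = euclidean_distance_matrix(rng.random((15, 2)))
        sol = pam(dm, 4)
        assert set(sol.assignment.values()) == {1, 2, 3, 4}
        for c, mid in enumerate(sol.medoid_ids, start=1):
            assert sol.assignment[mid] == c

    def test_invalid_k_rejected(self):
        dm = euclidean_distance_matrix(np.arange(4.0))
        for k in (0, 5):
            with pytest.raises(ValueError):
                pam(dm, k)


class TestChIndex:
    def test_hand_worked_one_dimensional_case(self):
        # points 0,1,10,11 split into {0,1},{10,11}: W=1, B=100 -> CH=200
        dm = euclidean_distance_matrix([0.0, 1.0, 10.0, 11.0])
        assert ch_index(dm, [1, 1, 2, 2]) == pytest.approx(200.0, abs=1e-9)

    def test_equals_coordinate_oracle_on_random_point_sets(self):
        from sklearn.metrics import calinski_harabasz_score

        rng = np.random.default_rng(5)
        for _ in range(40):
            n = int(rng.integers(6, 20))
            k = int(rng.integers(2, 4))
            pts = rng.random((n, 3))
            labels = rng.integers(0, k, size=n)
            labels[:k] = np.arange(k)  # guarantee non-empty clusters
            dm = euclidean_distance_matrix(pts)
            assert ch_index(dm, labels) == pytest.approx(
                calinski_harabasz_score(pts, labels), rel=1e-9
            )

    def test_duplicating_samples_follows_closed_form(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        labels = [1, 1, 2, 2]
        dm1 = euclidean_distance_matrix(pts)
        dm2 = euclidean_distance_matrix(np.repeat(pts, 2))
        ch1 = ch_index(dm1, labels)
        ch2 = ch_index(dm2, np.repeat(labels, 2))
        # doubling n keeps cluster means and per-point dispersion ratios; CH
        # scales only through (n-k)/(k-1): B doubles, W doubles, factor 6/2
        n, k = 4, 2
        assert ch2 == pytest.approx(ch1 * (2 * n - k) / (n - k), rel=1e-9)

    def test_degenerate_k_rejected(self):
        dm = euclidean_distance_matrix([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            ch_index(dm, [1, 1, 1])
        with pytest.raises(ValueError):
            ch_index(dm, [1, 2, 3])


class TestEstimateK:
    def test_full_fraction_concentrates_all_votes(self):
        rng = np.random.default_rng(9)
        pts = np.concatenate([rng.normal(0, 0.05, (6, 2)),
                              rng.normal(5, 0.05, (6, 2))])
        dm = euclidean_distance_matrix(pts)
        vote = estimate_k(dm, range(2, 5), trials=10, subsample_fraction=1.0, seed=0)
        assert vote.votes[vote.optimal_k] == 10
        assert vote.optimal_k == 2

    def test_single_trial_is_unit_mass(self):
        rng = np.random.default_rng(10)
        dm = euclidean_distance_matrix(rng.random((12, 2)))
        vote = estimate_k(dm, range(2, 5), trials=1, subsample_fraction=0.9, seed=0)
        assert sum(vote.votes.values()) == 1

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(12)
        dm = euclidean_distance_matrix(rng.random((20, 2)))
        v1 = estimate_k(dm, range(2, 5), trials=20, subsample_fraction=0.8, seed=42)
        v2 = estimate_k(dm, range(2, 5), trials=20, subsample_fraction=0.8, seed=42)
        assert v1.votes == v2.votes

    def test_subsample_too_small_for_largest_k_rejected(self):
        rng = np.random.default_rng(13)
        dm = euclidean_distance_matrix(rng.random((10, 2)))
        with pytest.raises(ValueError):
            estimate_k(dm, range(2, 9), trials=5, subsample_fraction=0.5, seed=0)

    def test_single_regime_cohort_votes_low_k(self):
        """A homogeneous cohort must not produce a high-k mode."""
        cfg = SyntheticCohortConfig(
            n_subjects=8,
            days=list(range(1, 8)),
            initial_probs={"S": 0.0, "E": 0.0, "B": 1.0},
            transitions=pd.DataFrame(np.eye(3), index=list("SEB"), columns=list("SEB")),
            seed=21,
        )
        table, *_ = generate_cohort(cfg)
        dm = jsd_matrix(table)
        vote = estimate_k(dm, range(2, 7), trials=40, subsample_fraction=0.8, seed=3)
        assert vote.optimal_k == 2


class TestPcoa:
    def test_collinear_points_one_positive_eigenvalue(self):
        dm = euclidean_distance_matrix([0.0, 3.0, 4.0])
        res = pcoa(dm, n_axes=2)
        positive = res.eigenvalues > 1e-9
        assert positive.sum() == 1
        coords = res.coordinates
        recon = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        np.testing.assert_allclose(recon, dm.d, atol=1e-9)

    def test_reconstructs_distances_from_random_2d_points(self):
        rng = np.random.default_rng(14)
        pts = rng.random((10, 2))
        dm = euclidean_distance_matrix(pts)
        res = pcoa(dm, n_axes=2)
        c = res.coordinates
        recon = np.sqrt(((c[:, None] - c[None]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, dm.d, atol=1e-9)
        assert (res.eigenvalues[:2] > 0).all()

    def test_agrees_with_skbio_oracle(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(15)
        pts = rng.random((8, 3))
        dm = euclidean_distance_matrix(pts)
        ours = pcoa(dm, n_axes=3)
        theirs = skbio_pcoa(dm.d, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(ours.coordinates),
            np.abs(theirs.samples.to_numpy()[:, :3]),
            atol=1e-6,
        )

    def test_sign_convention_first_nonzero_loading_positive(self):
        rng = np.random.default_rng(16)
        dm = euclidean_distance_matrix(rng.random((6, 2)))
        res = pcoa(dm, n_axes=2)
        for a in range(res.coordinates.shape[1]):
            col = res.coordinates[:, a]
            nz = col[np.abs(col) > 1e-12]
            assert nz[0] > 0

    def test_zero_distances_zero_coordinates(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(dm, n_axes=2)
        assert res.coordinates.shape[1] == 0

    def test_small_n_rejected(self):
        dm = euclidean_distance_matrix([0.0, 1.0])
        with pytest.raises(ValueError):
            pcoa(dm)

    def test_proportion_explained_sums_below_one(self):
        rng = np.random.default_rng(17)
        dm = euclidean_distance_matrix(rng.random((9, 4)))
        res = pcoa(dm, n_axes=2)
        assert 0 < res.proportion_explained.sum() <= 1.0 + 1e-12


class TestHclustComplete:
    def test_hand_enumerated_merge_order(self):
        d = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
        dm = DistanceMatrix(list("ABC"), d)
        res = hclust_complete(dm)
        assert res.merges[0, 2] == pytest.approx(1.0)  # {A,B} first
        assert res.merges[1, 2] == pytest.approx(5.0)
        assert set(res.leaf_order) == set("ABC")

    def test_two_samples_single_merge(self):
        dm = euclidean_distance_matrix([0.0, 2.5])
        res = hclust_complete(dm)
        assert res.merges.shape == (1, 4)
        assert res.merges[0, 2] == pytest.approx(2.5)

    def test_duplicates_merge_at_zero_first(self):
        dm = euclidean_distance_matrix([1.0, 1.0, 7.0])
        res = hclust_complete(dm)
        assert res.merges[0, 2] == 0.0
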