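"""Trait profile groups: Gower, Euclidean-ness, Ward, ANOSIM, Gini."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import functhresh as ft
from functhresh.tpg import cut_dendrogram, linkage_to_newick
from tests.test_synthetic import gower_bruteforce


def frame(X, prefix="g"):
    X = np.asarray(X, float)
    idx = [f"{prefix}{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=idx, columns=[f"t{j}" for j in range(X.shape[1])])


class TestGower:
    def test_identical_profiles_distance_zero(self):
        D = ft.gower_matrix(frame([[0.2, 0.8], [0.2, 0.8], [1.0, 0.0]]))
        assert D.iloc[0, 1] == 0.0

    def test_maximally_different_profiles_distance_one(self):
        D = ft.gower_matrix(frame([[0.0, 1.0, 5.0], [1.0, 0.0, -5.0]]))
        assert D.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_exhaustively(self, rng):
        """Element-by-element agreement with a nested-loop oracle on random
        matrices up to n = 10."""
        for n in range(2, 11):
            X = rng.uniform(0, 1, size=(n, 7))
            X[:, 3] = 0.5  # a constant trait must be excluded by both paths
            with pytest.warns(UserWarning, match="constant traits"):
                D = ft.gower_matrix(frame(X))
            np.testing.assert_allclose(D.to_numpy(), gower_bruteforce(X), atol=1e-12)

    def test_single_genus_rejected(self):
        with pytest.raises(ValueError):
            ft.gower_matrix(frame([[1.0, 0.0]]))


class TestEuclideanDiagnostic:
    def test_collinear_points_are_exactly_euclidean(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        D = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        assert ft.check_euclidean(D) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_violating_structure_detected(self):
        # 4 points, one pair pulled far beyond what any embedding allows
        D = np.array(
            [
                [0, 1, 1, 1],
                [1, 0, 1, 1],
                [1, 1, 0, 2.9],
                [1, 1, 2.9, 0],
            ],
            dtype=float,
        )
        diag = ft.check_euclidean(pd.DataFrame(D))
        # oracle: eigendecompose the double-centred matrix directly
        J = np.eye(4) - 0.25
        eig = np.linalg.eigvalsh(-0.5 * J @ (D**2) @ J)
        expected = np.abs(eig[eig < 0]).sum() / np.abs(eig).sum()
        assert diag == pytest.approx(expected, abs=1e-12)
        assert diag > 0

    def test_permutation_invariance(self, analysis_matrix, rng):
        D = ft.gower_matrix(analysis_matrix.iloc[:12])
        perm = rng.permutation(12)
        D2 = D.iloc[perm, perm]
        assert ft.check_euclidean(D) == pytest.approx(ft.check_euclidean(D2), abs=1e-12)


class TestWard:
    def test_two_tight_pairs_merge_first(self):
        X = frame([[0.0, 0.0], [0.01, 0.0], [1.0, 1.0], [1.0, 1.01], [0.5, 0.0]])
        Z = ft.ward_cluster(ft.gower_matrix(X))
        first_two_merges = {tuple(sorted(row[:2].astype(int))) for row in Z[:2]}
        assert first_two_merges == {(0, 1), (2, 3)}

    def test_cut_at_n_gives_singletons(self, analysis_matrix):
        D = ft.gower_matrix(analysis_matrix.iloc[:8])
        Z = ft.ward_cluster(D)
        labels = cut_dendrogram(Z, 8, D.index)
        assert labels.nunique() == 8

    def test_merge_heights_match_lance_williams_recurrence(self, rng):
        """5-genus dendrogram reproduced by a hand-rolled Lance-Williams
        update for Ward's method."""
        X = rng.uniform(0, 1, size=(5, 6))
        D = ft.gower_matrix(frame(X))
        Z = ft.ward_cluster(D)

        # oracle: naive agglomeration with the Ward update on d^2
        d = {frozenset([i]): None for i in range(5)}
        active = {frozenset([i]) for i in range(5)}
        dist = {
            frozenset([frozenset([i]), frozenset([j])]): D.iloc[i, j]
            for i in range(5)
            for j in range(i + 1, 5)
        }
        sizes = {frozenset([i]): 1 for i in range(5)}
        heights = []
        while len(active) > 1:
            pair, dm = min(dist.items(), key=lambda kv: kv[1])
            a, b = tuple(pair)
            heights.append(dm)
            merged = a | b
            active -= {a, b}
            for c in list(active):
                na, nb, nc = sizes[a], sizes[b], sizes[c]
                n = na + nb + nc
                dac = dist.pop(frozenset([a, c]))
                dbc = dist.pop(frozenset([b, c]))
                new = np.sqrt(
                    ((na + nc) * dac**2 + (nb + nc) * dbc**2 - nc * dm**2) / n
                )
                dist[frozenset([merged, c])] = new
            del dist[pair]
            sizes[merged] = sizes[a] + sizes[b]
            active.add(merged)
        np.testing.assert_allclose(Z[:, 2], heights, atol=1e-10)

    def test_newick_serialization_is_parseable(self, analysis_matrix):
        D = ft.gower_matrix(analysis_matrix.iloc[:6])
        Z = ft.ward_cluster(D)
        nwk = linkage_to_newick(Z, [str(i) for i in D.index])
        assert nwk.endswith(";") and nwk.count("(") == 5


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        X = frame([[0, 0], [0.01, 0], [1, 1], [1, 1.01]])
        D = ft.gower_matrix(X)
        assert ft.anosim_r(D, ["a", "a", "b", "b"]) == pytest.approx(1.0)

    def test_matches_exhaustive_rank_oracle_on_toy(self):
        D = pd.DataFrame(
            [
                [0.0, 0.1, 0.6, 0.7],
                [0.1, 0.0, 0.5, 0.8],
                [0.6, 0.5, 0.0, 0.2],
                [0.7, 0.8, 0.2, 0.0],
            ]
        )
        labels = np.array(["x", "x", "y", "y"])
        d = D.to_numpy()[np.triu_indices(4, 1)]
        ranks = rankdata(d)
        within = np.array([True, False, False, False, False, True])
        expected = (ranks[~within].mean() - ranks[within].mean()) / (len(d) / 2)
        assert ft.anosim_r(D, labels) == pytest.approx(expected, abs=1e-12)

    def test_random_labels_center_on_zero(self, analysis_matrix, rng):
        D = ft.gower_matrix(analysis_matrix.iloc[:12])
        rs = []
        for _ in range(1000):
            labels = rng.permutation([0] * 6 + [1] * 6)
            rs.append(ft.anosim_r(D, labels))
        assert abs(np.mean(rs)) < 0.02
        assert all(-1 <= r <= 1 for r in rs)

    def test_invariant_to_monotone_distance_transform(self):
        D = pd.DataFrame(
            [[0.0, 0.1, 0.6], [0.1, 0.0, 0.5], [0.6, 0.5, 0.0]]
        )
        labels = ["x", "x", "y"]
        r1 = ft.anosim_r(D, labels)
        r2 = ft.anosim_r(D**2, labels)  # ranks unchanged
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_agrees_with_skbio_reference(self, analysis_matrix):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as skbio_anosim

        sub = analysis_matrix.iloc[:15]
        D = ft.gower_matrix(sub)
        labels = [i % 3 for i in range(15)]
        dm = skbio.DistanceMatrix(D.to_numpy(), ids=[str(i) for i in range(15)])
        ref = skbio_anosim(dm, np.asarray(labels), permutations=0)["test statistic"]
        assert ft.anosim_r(D, labels) == pytest.approx(ref, abs=1e-12)

    def test_permutation_p_value_small_for_real_structure(self, analysis_matrix,
                                                          default_dataset):
        D = ft.gower_matrix(analysis_matrix)
        labels = default_dataset.archetype_labels.to_numpy()
        r, p = ft.anosim_r(D, labels, n_permutations=199, seed=0)
        assert r > 0.9 and p <= 0.01

    def test_single_group_rejected(self):
        D = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]])
        with pytest.raises(ValueError):
            ft.anosim_r(D, ["x", "x"])


class TestSelectK:
    def test_three_equidistant_archetypes_recovered_with_r_one(self):
        """Zero-jitter archetypes: duplicates cluster exactly, k equals the
        archetype count and R = 1. Equidistant profiles keep coarser cuts
        from also reaching R = 1 (the parsimony tie-break would then win)."""
        profiles = np.eye(3)
        X = frame(np.repeat(profiles, 3, axis=0))
        assignment = ft.select_k_by_anosim(ft.gower_matrix(X))
        assert assignment.k == 3
        assert assignment.anosim_r == pytest.approx(1.0)
        # equidistant merge heights tie, so no dendrogram cut yields exactly
        # two groups; any coarser labelling recorded must score below 1
        assert all(r < 1.0 for k, r in assignment.r_by_k.items() if k < 3)

    def test_default_archetype_community_reaches_r_one_at_true_k(self):
        traits, labels = ft.generate_trait_matrix(
            ft.GeneratorConfig(seed=0, n_genera=15, trait_jitter=0.0)
        )
        matrix, _ = ft.build_analysis_matrix(traits)
        assignment = ft.select_k_by_anosim(ft.gower_matrix(matrix))
        # zero jitter makes several cuts perfect (R = 1); parsimony then
        # selects the smallest such k, never more than the archetype count
        assert assignment.anosim_r == pytest.approx(1.0)
        assert assignment.k <= len(ft.ARCHETYPES)
        assert assignment.r_by_k[len(ft.ARCHETYPES)] == pytest.approx(1.0)

    def test_genus_order_invariance(self, analysis_matrix, rng):
        D = ft.gower_matrix(analysis_matrix)
        a1 = ft.select_k_by_anosim(D)
        perm = rng.permutation(len(D))
        D2 = D.iloc[perm, perm]
        a2 = ft.select_k_by_anosim(D2)
        assert a1.k == a2.k
        # same partition up to label renaming
        merged = pd.concat([a1.labels.rename("one"), a2.labels.rename("two")], axis=1)
        assert merged.groupby("one")["two"].nunique().eq(1).all()

    def test_unstructured_profiles_score_below_real_structure(self, rng):
        """Ward-derived labels on pure noise still earn sizeable R (the
        statistic is computed on the same distances the labels came from),
        but stay clearly below the R ~= 1 of genuine archetype structure."""
        X = frame(rng.uniform(0, 1, size=(40, 12)))
        assignment = ft.select_k_by_anosim(ft.gower_matrix(X))
        assert assignment.anosim_r < 0.9

    def test_structureless_distances_warn_weak(self):
        # all pairwise distances equal -> every labelling has R = 0
        n = 10
        D = pd.DataFrame(np.ones((n, n)) - np.eye(n))
        with pytest.warns(UserWarning, match="weak cluster structure"):
            assignment = ft.select_k_by_anosim(D)
        assert assignment.anosim_r == pytest.approx(0.0, abs=1e-12)

    def test_k_max_respected(self, analysis_matrix):
        D = ft.gower_matrix(analysis_matrix)
        assignment = ft.select_k_by_anosim(D, k_max=3)
        assert 2 <= assignment.k <= 3


class TestGiniImportance:
    def test_single_informative_trait_dominates(self):
        rng = np.random.default_rng(0)
        X = frame(np.column_stack([
            np.r_[np.ones(10), np.zeros(20)],          # perfect separator
            rng.uniform(0.4, 0.6, 30),                 # noise
            np.full(30, 0.5),                          # constant
        ]))
        labels = ["a"] * 10 + ["b"] * 20
        gini = ft.gini_importance(X, labels, n_trees=100, seed=0)
        for _, sub in gini.groupby("group"):
            assert sub.loc[sub["gini"].idxmax(), "trait"] == "t0"

    def test_permuting_a_trait_degrades_its_importance(self, analysis_matrix,
                                                       default_dataset):
        labels = default_dataset.archetype_labels
        col = ("respiration", "spiracle")
        base = []
        degraded = []
        for seed in range(10):
            gini = ft.gini_importance(analysis_matrix, labels, n_trees=100, seed=seed)
            base.append(
                gini.set_index(["feature", "trait"]).groupby(level=[0, 1])["gini"]
                .sum()[col]
            )
            shuffled = analysis_matrix.copy()
            rng = np.random.default_rng(seed)
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            gini2 = ft.gini_importance(shuffled, labels, n_trees=100, seed=seed)
            degraded.append(
                gini2.set_index(["feature", "trait"]).groupby(level=[0, 1])["gini"]
                .sum()[col]
            )
        assert np.mean(degraded) < 0.5 * np.mean(base)

    def test_seeded_determinism(self, analysis_matrix, default_dataset):
        labels = default_dataset.archetype_labels
        g1 = ft.gini_importance(analysis_matrix, labels, n_trees=50, seed=3)
        g2 = ft.gini_importance(analysis_matrix, labels, n_trees=50, seed=3)
        pd.testing.assert_frame_equal(g1, g2)

    def test_singleton_group_warns(self, analysis_matrix):
        labels = ["a"] + ["b"] * (len(analysis_matrix) - 1)
        with pytest.warns(UserWarning, match="single member"):
            ft.gini_importance(analysis_matrix, labels, n_trees=20, seed=0)
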