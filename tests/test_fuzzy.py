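"""Fuzzy-relation clustering machinery: normalization, Chen distance,
compatibility relation, transitive closure, λ-cuts, validity index, Ward."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.sparse.csgraph import connected_components

from ftirseed import fuzzy
from ftirseed.errors import (
    DegenerateAttributeError,
    NotTransitiveError,
    ValidityUndefinedError,
)
from ftirseed.fuzzy import (
    TrapezoidalFuzzyNumber,
    chen_distance_sq,
    compatibility,
    crisp_matrix,
    lambda_cut,
    lambda_series,
    normalize,
    transitive_closure,
    validity_index,
    validity_table,
    ward_dendrogram,
)


def tfn_matrices(max_n=5, max_m=4):
    """Random (n, m, 4) rating arrays with sorted corners (valid TFNs)."""
    return st.integers(2, max_n).flatmap(
        lambda n: st.integers(1, max_m).flatmap(
            lambda m: hnp.arrays(
                float,
                (n, m, 4),
                elements=st.floats(-50, 50, allow_nan=False, width=32),
            ).map(lambda a: np.sort(a, axis=2))
        )
    )


class TestNormalize:
    def test_crisp_column_affine_map(self):
        norm = normalize(crisp_matrix(np.array([[2.0], [4.0], [6.0]])))
        assert np.allclose(norm.ratings[:, 0, 0], [0.0, 0.5, 1.0])
        assert norm.t_star[0] == pytest.approx(4.0)

    def test_extremes_map_to_unit_interval_ends(self):
        ratings = np.array(
            [[[0.0, 1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0, 7.0]], [[2.0, 2.5, 3.0, 5.0]]]
        )
        norm = normalize(fuzzy.AttributeMatrix(ratings))
        assert norm.ratings[0, 0, 0] == pytest.approx(0.0)  # attains c*
        assert norm.ratings[1, 0, 3] == pytest.approx(1.0)  # attains d*

    @settings(deadline=None, max_examples=50)
    @given(tfn_matrices())
    def test_all_components_in_unit_interval(self, ratings):
        matrix = fuzzy.AttributeMatrix(ratings)
        try:
            norm = normalize(matrix)
        except DegenerateAttributeError:
            return  # all columns constant: normalization rightly undefined
        assert np.all(norm.ratings >= 0.0) and np.all(norm.ratings <= 1.0)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(1)
        ratings = np.sort(rng.uniform(-5, 5, (6, 3, 4)), axis=2)
        once = normalize(fuzzy.AttributeMatrix(ratings))
        twice = normalize(fuzzy.AttributeMatrix(once.ratings))
        assert np.allclose(once.ratings, twice.ratings, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        values = np.array([[1.0, 5.0], [1.0, 7.0], [1.0, 6.0]])
        with pytest.warns(UserWarning, match="constant"):
            norm = normalize(crisp_matrix(values))
        assert norm.m == 1

    def test_all_constant_rejected(self):
        with pytest.raises(DegenerateAttributeError):
            normalize(crisp_matrix(np.ones((4, 2))))


class TestChenDistance:
    def test_identity(self):
        x = TrapezoidalFuzzyNumber(0.1, 0.2, 0.3, 0.4)
        assert chen_distance_sq(x, x) == 0.0

    def test_crisp_pair(self):
        x = TrapezoidalFuzzyNumber.crisp(1.0)
        y = TrapezoidalFuzzyNumber.crisp(3.0)
        assert chen_distance_sq(x, y) == pytest.approx(4.0)

    def test_mixed_pair(self):
        x = TrapezoidalFuzzyNumber(0, 0, 0, 0)
        y = TrapezoidalFuzzyNumber(0, 1, 1, 2)
        assert chen_distance_sq(x, y) == pytest.approx(1.5)

    def test_symmetry_and_ordering(self):
        x = TrapezoidalFuzzyNumber(0, 1, 2, 3)
        y = TrapezoidalFuzzyNumber(1, 1.5, 2.5, 4)
        assert chen_distance_sq(x, y) == chen_distance_sq(y, x)
        assert chen_distance_sq(x, y) > 0


class TestCompatibility:
    def test_three_crisp_points_hand_example(self):
        norm = normalize(crisp_matrix(np.array([[0.0], [0.5], [1.0]])))
        R = compatibility(norm)
        assert np.allclose(np.diag(R.values), 1.0)
        assert R.values[0, 2] == pytest.approx(0.0)
        assert R.values[0, 1] == pytest.approx(0.75)
        assert R.values[1, 2] == pytest.approx(0.75)
        assert R.eta == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30)
    @given(tfn_matrices())
    def test_entries_in_unit_interval(self, ratings):
        try:
            norm = normalize(fuzzy.AttributeMatrix(ratings))
        except DegenerateAttributeError:
            return
        R = compatibility(norm).values
        assert np.all(R >= 0.0) and np.all(R <= 1.0)
        assert np.allclose(R, R.T)
        assert R.min() == pytest.approx(0.0, abs=1e-12)

    def test_identical_objects_flagged(self):
        norm = normalize(crisp_matrix(np.array([[1.0, 2.0], [3.0, 4.0]])))
        norm.ratings = np.zeros_like(norm.ratings)  # force identical objects
        with pytest.warns(UserWarning, match="identical"):
            R = compatibility(norm)
        assert R.eta is None
        assert np.all(R.values == 1.0)


def _path_closure_oracle(R: np.ndarray) -> np.ndarray:
    """Max over all simple paths of the minimum edge weight (brute force)."""
    n = R.shape[0]
    out = R.copy()
    nodes = range(n)
    for i, j in itertools.product(nodes, nodes):
        best = R[i, j]
        others = [k for k in nodes if k not in (i, j)]
        for length in range(1, n - 1):
            for mids in itertools.permutations(others, length):
                path = (i, *mids, j)
                strength = min(R[a, b] for a, b in zip(path, path[1:]))
                best = max(best, strength)
        out[i, j] = best
    return out


def _random_relation(rng, n):
    R = rng.uniform(0, 1, (n, n))
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R


class TestTransitiveClosure:
    def test_fixpoint_of_transitive_relation(self):
        R = np.array([[1.0, 0.8, 0.8], [0.8, 1.0, 0.9], [0.8, 0.9, 1.0]])
        Rt = transitive_closure(fuzzy.CompatibilityMatrix(R, eta=1.0))
        assert np.array_equal(Rt.values, R)

    def test_chain_strengthens_weak_link(self):
        R = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.8], [0.1, 0.8, 1.0]])
        Rt = transitive_closure(fuzzy.CompatibilityMatrix(R, eta=1.0))
        assert Rt.values[0, 2] == pytest.approx(0.8)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_exhaustive_path_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            R = _random_relation(rng, n)
            Rt = transitive_closure(fuzzy.CompatibilityMatrix(R, eta=1.0))
            assert np.allclose(Rt.values, _path_closure_oracle(R))

    def test_is_fuzzy_equivalence_relation(self):
        rng = np.random.default_rng(7)
        R = _random_relation(rng, 8)
        Rt = transitive_closure(fuzzy.CompatibilityMatrix(R, eta=1.0)).values
        assert np.allclose(np.diag(Rt), 1.0)
        assert np.allclose(Rt, Rt.T)
        assert fuzzy.is_transitive(Rt)
        assert np.all(Rt >= R - 1e-12)


class TestLambdaCut:
    def _closure(self, seed=3, n=10):
        rng = np.random.default_rng(seed)
        R = _random_relation(rng, n)
        return R, transitive_closure(fuzzy.CompatibilityMatrix(R, eta=1.0))

    def test_extreme_lambdas(self):
        _, Rt = self._closure()
        assert lambda_cut(Rt, 0.0).h == 1
        off_diag = Rt.values[~np.eye(Rt.n, dtype=bool)]
        if np.all(off_diag < 1.0):
            assert lambda_cut(Rt, 1.0).h == Rt.n

    def test_rejects_non_transitive_input(self):
        R = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.8], [0.1, 0.8, 1.0]])
        with pytest.raises(NotTransitiveError):
            lambda_cut(fuzzy.CompatibilityMatrix(R, eta=1.0), 0.5)

    def test_cut_equals_single_linkage_components(self):
        """λ-cut of the max-min closure = connected components of R >= λ."""
        R, Rt = self._closure(seed=5, n=9)
        for lam in np.unique(Rt.values):
            part = lambda_cut(Rt, float(lam))
            _, comp = connected_components(R >= lam, directed=False)
            labels = part.labels()
            for i, j in itertools.combinations(range(Rt.n), 2):
                assert (labels[i] == labels[j]) == (comp[i] == comp[j])

    def test_series_is_nested(self):
        _, Rt = self._closure(seed=11, n=12)
        series = lambda_series(Rt)
        assert series[0].lam >= series[-1].lam
        for fine, coarse in zip(series, series[1:]):
            coarse_sets = [set(c) for c in coarse.clusters]
            for cluster in fine.clusters:
                assert any(set(cluster) <= cs for cs in coarse_sets)


class TestValidityIndex:
    def _blobs(self, rng, centers, n_each=6, spread=0.02):
        pts = np.vstack(
            [c + spread * rng.standard_normal((n_each, len(c))) for c in centers]
        )
        return normalize(crisp_matrix(pts))

    def test_minimized_at_true_cluster_count(self):
        rng = np.random.default_rng(21)
        norm = self._blobs(rng, [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)])
        Rt = transitive_closure(compatibility(norm))
        series = lambda_series(Rt)
        table = validity_table(norm, series)
        assert 3 in set(table["h"])
        assert int(table.loc[table["L"].idxmin(), "h"]) == 3

    def test_duplicating_objects_leaves_L_unchanged(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 1, (8, 3))
        norm = normalize(crisp_matrix(pts))
        part = fuzzy.Partition(
            lam=0.5,
            clusters=[list(range(4)), list(range(4, 8))],
            object_ids=list(range(8)),
        )
        L1 = validity_index(norm, part).L
        doubled = normalize(crisp_matrix(np.vstack([pts, pts])))
        part2 = fuzzy.Partition(
            lam=0.5,
            clusters=[
                list(range(4)) + list(range(8, 12)),
                list(range(4, 8)) + list(range(12, 16)),
            ],
            object_ids=list(range(16)),
        )
        L2 = validity_index(doubled, part2).L
        assert L2 == pytest.approx(L1, rel=1e-10)

    def test_requires_two_clusters(self):
        norm = normalize(crisp_matrix(np.array([[0.0], [1.0], [2.0]])))
        part = fuzzy.Partition(lam=0.0, clusters=[[0, 1, 2]], object_ids=[0, 1, 2])
        with pytest.raises(ValidityUndefinedError):
            validity_index(norm, part)

    def test_table_excludes_degenerate_partitions(self):
        norm = normalize(crisp_matrix(np.array([[0.0], [0.4], [1.0]])))
        Rt = transitive_closure(compatibility(norm))
        table = validity_table(norm, lambda_series(Rt))
        assert set(table["h"]) <= {2}  # n=3: only h=2 is non-degenerate


class TestWard:
    def test_identical_objects_merge_first_at_zero_height(self):
        X = np.array([[1.0, 2.0], [5.0, 5.0], [1.0, 2.0], [9.0, 0.0]])
        dend = ward_dendrogram(X)
        first = dend.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 2}
        assert first[2] == pytest.approx(0.0)

    def test_nearest_pair_merges_first(self):
        dend = ward_dendrogram(np.array([[0.0], [1.0], [10.0]]))
        assert {int(dend.linkage[0, 0]), int(dend.linkage[0, 1])} == {0, 1}

    def test_newick_export_is_well_formed(self):
        from io import StringIO

        from Bio import Phylo  # independent parser as cross-check

        X = np.random.default_rng(2).uniform(0, 1, (7, 3))
        dend = ward_dendrogram(X, object_ids=[f"s{i}" for i in range(7)])
        tree = Phylo.read(StringIO(dend.to_newick()), "newick")
        assert {t.name for t in tree.get_terminals()} == {f"s{i}" for i in range(7)}
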