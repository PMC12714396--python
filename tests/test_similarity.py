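import math
from io import StringIO

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metamda.similarity import (FingerprintSet, SimilarityError, SimilarityMatrix,
                                aggregate, fingerprints_from_smiles, genome_similarity,
                                gip_similarity, phylo_similarity, tanimoto_matrix)


class TestGIP:
    def test_identity_profiles_have_similarity_one(self):
        mat = np.array([[1, 0, 1], [1, 0, 1]])
        sim = gip_similarity(mat, ("a", "b"), "rows")
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_two_by_two_identity_case(self):
        # profiles (1,0) and (0,1): eta = 1 / ((1+1)/2) = 1, ||diff||^2 = 2
        sim = gip_similarity(np.eye(2), ("a", "b"), "rows")
        assert sim.values[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-12)

    def test_column_axis_transposes_profiles(self):
        mat = np.array([[1, 0], [0, 1], [1, 1]])
        by_cols = gip_similarity(mat, ("x", "y"), "cols")
        by_rows = gip_similarity(mat.T, ("x", "y"), "rows")
        np.testing.assert_allclose(by_cols.values, by_rows.values)

    def test_all_zero_matrix_returns_identity(self, caplog):
        sim = gip_similarity(np.zeros((3, 4)), ("a", "b", "c"), "rows")
        np.testing.assert_array_equal(sim.values, np.eye(3))

    @given(st.integers(0, 2 ** 20 - 1))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance(self, seed):
        # conjugating the profiles permutes the similarity matrix identically
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 7)), int(rng.integers(1, 7))
        mat = rng.integers(0, 2, size=(n, m))
        ids = tuple(f"n{i}" for i in range(n))
        perm = rng.permutation(n)
        base = gip_similarity(mat, ids, "rows").values
        permuted = gip_similarity(mat[perm], tuple(ids[i] for i in perm), "rows").values
        np.testing.assert_allclose(permuted, base[np.ix_(perm, perm)], atol=1e-12)

    @given(st.integers(0, 2 ** 20 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_is_valid_similarity_matrix(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 2, size=(int(rng.integers(2, 8)), int(rng.integers(1, 8))))
        sim = gip_similarity(mat, tuple(map(str, range(mat.shape[0]))), "rows")
        v = sim.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert v.min() >= 0 and v.max() <= 1


def brute_force_tanimoto(a, b):
    inter = len(set(a) & set(b))
    union = len(set(a) | set(b))
    return inter / union if union else 0.0


class TestTanimoto:
    def test_worked_example(self):
        fps = FingerprintSet(("a", "b"), {"a": frozenset({1, 2, 3}),
                                          "b": frozenset({2, 3, 4})})
        assert tanimoto_matrix(fps).values[0, 1] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        fps = FingerprintSet(("a", "b", "c"),
                             {"a": frozenset({1, 2}), "b": frozenset({1, 2}),
                              "c": frozenset({9})})
        v = tanimoto_matrix(fps).values
        assert v[0, 1] == 1.0 and v[0, 2] == 0.0

    def test_matches_brute_force_on_random_bitsets(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            sets = {f"x{i}": frozenset(int(b) for b in
                                       rng.choice(32, size=rng.integers(0, 10), replace=False))
                    for i in range(n)}
            fps = FingerprintSet(tuple(sets), sets)
            v = tanimoto_matrix(fps).values
            ids = list(sets)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    assert v[i, j] == pytest.approx(
                        brute_force_tanimoto(sets[ids[i]], sets[ids[j]]))

    def test_from_smiles_agrees_with_rdkit_tanimoto(self):
        from rdkit import Chem, DataStructs
        smiles = {"etoh": "CCO", "benzene": "c1ccccc1", "aspirin": "CC(=O)Oc1ccccc1C(=O)O"}
        fps = fingerprints_from_smiles(smiles)
        mine = tanimoto_matrix(fps).values
        rd = {nid: Chem.RDKFingerprint(Chem.MolFromSmiles(s), fpSize=2048)
              for nid, s in smiles.items()}
        for i, a in enumerate(fps.ids):
            for j, b in enumerate(fps.ids):
                assert mine[i, j] == pytest.approx(
                    DataStructs.TanimotoSimilarity(rd[a], rd[b]), abs=1e-12)

    def test_unparsable_smiles_excluded_and_recorded(self):
        fps = fingerprints_from_smiles({"ok": "CCO", "bad": "not_a_smiles(("})
        assert fps.failed == ("bad",)
        assert fps.ids == ("ok",)


def biophylo_patristic(newick, a, b):
    from Bio import Phylo
    tree = Phylo.read(StringIO(newick), "newick")
    return tree.distance(a, b)


def random_newick(rng, n_leaves):
    labels = [f"L{i}" for i in range(n_leaves)]
    nodes = [f"{lab}:{rng.uniform(0.1, 2.0):.3f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 2.0):.3f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]});", labels


class TestPhylo:
    def test_worked_example(self):
        sim = phylo_similarity("((A:1,B:2):0.5,C:3);")
        ids = list(sim.ids)
        a, b, c = ids.index("A"), ids.index("B"), ids.index("C")
        # d(A,B)=3, d(A,C)=4.5, d(B,C)=5.5 -> max 5.5
        assert sim.values[a, b] == pytest.approx(1 - 3 / 5.5)
        assert sim.values[a, c] == pytest.approx(1 - 4.5 / 5.5)
        assert sim.values[b, c] == pytest.approx(0.0)

    def test_max_distance_pair_has_similarity_zero(self):
        sim = phylo_similarity("((A:1,B:2):0.5,C:3);")
        assert sim.values.min() == pytest.approx(0.0)

    def test_single_cherry_degenerate(self):
        sim = phylo_similarity("(A:1,B:1);")
        i, j = sim.ids.index("A"), sim.ids.index("B")
        assert sim.values[i, j] == pytest.approx(0.0)

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(SimilarityError, match="duplicate"):
            phylo_similarity("((A:1,A:2):0.5,C:3);")

    def test_matches_independent_path_sum_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(6):
            newick, labels = random_newick(rng, int(rng.integers(3, 11)))
            from metamda.similarity import patristic_distances
            pd_ = patristic_distances(newick)
            for i, a in enumerate(pd_.ids):
                for j, b in enumerate(pd_.ids):
                    if i < j:
                        assert pd_.dp[i, j] == pytest.approx(
                            biophylo_patristic(newick, a, b), rel=1e-9)


class TestGenome:
    def test_similarity_is_one_minus_distance(self, tmp_path):
        p = tmp_path / "mash.csv"
        p.write_text(",a,b\na,0.0,0.12\nb,0.12,0.0\n")
        sim = genome_similarity(p)
        assert sim.values[0, 1] == pytest.approx(0.88)
        assert sim.values[0, 0] == 1.0

    def test_out_of_range_distance_rejected(self, tmp_path):
        p = tmp_path / "mash.csv"
        p.write_text(",a,b\na,0.0,1.5\nb,1.5,0.0\n")
        with pytest.raises(SimilarityError, match=r"\[0, 1\]"):
            genome_similarity(p)

    def test_asymmetric_input_symmetrized(self, tmp_path):
        p = tmp_path / "mash.csv"
        p.write_text(",a,b\na,0.0,0.2\nb,0.4,0.0\n")
        sim = genome_similarity(p)
        assert sim.values[0, 1] == pytest.approx(1 - 0.3)


class TestAggregate:
    def _mat(self, off):
        v = np.full((2, 2), off, dtype=float)
        np.fill_diagonal(v, 1.0)
        return SimilarityMatrix(("a", "b"), v)

    def test_equal_weight_mean(self):
        agg = aggregate([self._mat(0.8), self._mat(0.6)])
        assert agg.values[0, 1] == pytest.approx(0.7)

    def test_single_component_is_identity_of_aggregation(self):
        m = self._mat(0.42)
        np.testing.assert_allclose(aggregate([m]).values, m.values)

    def test_two_level_nesting_matches_hand_computation(self):
        # mean(mean(a, b), c) on a 3x3 toy, entry by entry
        rng = np.random.default_rng(1)
        mats = []
        for _ in range(3):
            v = rng.uniform(0, 1, (3, 3))
            v = 0.5 * (v + v.T)
            np.fill_diagonal(v, 1.0)
            mats.append(SimilarityMatrix(("x", "y", "z"), v))
        a, b, c = mats
        nested = aggregate([aggregate([a, b]), c])
        expected = ((a.values + b.values) / 2 + c.values) / 2
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(nested.values, expected, atol=1e-12)

    def test_empty_component_list_rejected(self):
        with pytest.raises(SimilarityError, match="no components"):
            aggregate([])

    def test_missing_entries_fall_back_to_available_components(self):
        full = self._mat(0.8)
        partial_vals = np.array([[1.0, np.nan], [np.nan, 1.0]])
        partial = SimilarityMatrix.__new__(SimilarityMatrix)
        partial.ids = ("a", "b")
        partial.values = partial_vals
        partial.components = {}
        agg = aggregate([full, partial])
        assert agg.values[0, 1] == pytest.approx(0.8)
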