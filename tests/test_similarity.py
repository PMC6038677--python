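import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tlhnmda.datasets_io import BipartiteAssociations, DataError, DiseaseDAG, SimilarityMatrix
from tlhnmda.similarity import (
    KernelConfig,
    SemanticConfig,
    combined_semantic_similarity,
    gaussian_profile_kernel,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    mirna_functional_similarity,
    semantic_contribution_m1,
    semantic_contribution_m2,
    semantic_similarity_m1,
    semantic_similarity_m2,
    semantic_value,
)

CFG = SemanticConfig(delta=0.5)


class TestSemanticModel1:
    def test_chain_contributions_decay_geometrically(self, chain_dag):
        c = semantic_contribution_m1(chain_dag, "D3", CFG)
        assert c == {"D3": 1.0, "D2": 0.5, "D1": 0.25}

    def test_root_contributes_only_itself(self, chain_dag):
        assert semantic_contribution_m1(chain_dag, "D1", CFG) == {"D1": 1.0}

    def test_diamond_takes_max_over_paths(self, diamond_dag):
        c = semantic_contribution_m1(diamond_dag, "D4", CFG)
        assert c["D1"] == pytest.approx(0.25, abs=1e-15)

    def test_unknown_disease_errors(self, chain_dag):
        with pytest.raises(DataError):
            semantic_contribution_m1(chain_dag, "D9", CFG)

    def test_semantic_values(self, chain_dag, diamond_dag):
        assert semantic_value({"D3": 1.0, "D2": 0.5, "D1": 0.25}) == pytest.approx(1.75)
        assert semantic_value({"D1": 1.0}) == 1.0
        c = semantic_contribution_m1(diamond_dag, "D4", CFG)
        assert semantic_value(c) == pytest.approx(2.25)

    def test_toy_similarities(self, toy_dag):
        ss1 = semantic_similarity_m1(toy_dag, CFG)
        assert ss1.value("D2", "D3") == pytest.approx(1 / 3, abs=1e-12)
        assert ss1.value("D1", "D2") == pytest.approx(0.6, abs=1e-12)
        assert all(ss1.value(d, d) == 1.0 for d in toy_dag.nodes)

    def test_adding_shared_root_never_decreases_similarity(self):
        """A new common ancestor adds shared semantic context for every pair."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            nodes = tuple(f"D{i}" for i in range(n))
            edges = {(nodes[i], nodes[int(rng.integers(0, i))]) for i in range(1, n)}
            dag = DiseaseDAG(nodes, frozenset(edges))
            roots = dag.roots
            aug = DiseaseDAG(nodes + ("TOP",),
                             frozenset(edges | {(r, "TOP") for r in roots}))
            before = semantic_similarity_m1(dag, CFG)
            after = semantic_similarity_m1(aug, CFG)
            idx = [after.index[d] for d in nodes]
            sub = after.matrix[np.ix_(idx, idx)]
            assert (sub - before.matrix).min() > -1e-12


class TestSemanticModel2:
    def test_ubiquitous_root_contributes_zero(self, toy_dag):
        dd2 = semantic_contribution_m2(toy_dag, CFG)
        assert dd2["D1"] == pytest.approx(0.0, abs=1e-15)

    def test_leaf_contribution_natural_log(self, toy_dag):
        dd2 = semantic_contribution_m2(toy_dag, CFG)
        assert dd2["D2"] == pytest.approx(math.log(3), abs=1e-12)

    def test_leaf_contribution_base10(self, toy_dag):
        dd2 = semantic_contribution_m2(toy_dag, SemanticConfig(log_base="10"))
        assert dd2["D2"] == pytest.approx(math.log10(3), abs=1e-12)

    def test_toy_similarities(self, toy_dag):
        ss2 = semantic_similarity_m2(toy_dag, CFG)
        # siblings share only the root, whose model-2 contribution is zero
        assert ss2.value("D2", "D3") == pytest.approx(0.0, abs=1e-15)
        assert ss2.value("D2", "D2") == 1.0
        # root-only disease has zero semantic value: degenerate convention
        assert ss2.value("D1", "D1") == 1.0


class TestCombined:
    def test_entrywise_mean(self, toy_dag):
        ss1 = semantic_similarity_m1(toy_dag, CFG)
        ss2 = semantic_similarity_m2(toy_dag, CFG)
        ss = combined_semantic_similarity(ss1, ss2)
        assert ss.value("D2", "D3") == pytest.approx(1 / 6, abs=1e-12)
        assert combined_semantic_similarity(ss1, ss1).matrix == pytest.approx(ss1.matrix)
        assert all(ss.value(d, d) == 1.0 for d in toy_dag.nodes)


class TestFunctionalSimilarity:
    def test_identical_singleton_sets(self, toy_dag):
        ss = semantic_similarity_m1(toy_dag, CFG)
        fs = mirna_functional_similarity({"m1": {"D2"}, "m2": {"D2"}}, ss)
        assert fs.value("m1", "m2") == pytest.approx(1.0)

    def test_disjoint_singletons_use_cross_similarity(self, toy_dag):
        ss = semantic_similarity_m1(toy_dag, CFG)
        fs = mirna_functional_similarity({"m1": {"D2"}, "m2": {"D3"}}, ss)
        assert fs.value("m1", "m2") == pytest.approx(1 / 3, abs=1e-12)

    def test_best_match_average(self, toy_dag):
        ss = semantic_similarity_m1(toy_dag, CFG)
        fs = mirna_functional_similarity({"m1": {"D2", "D3"}, "m2": {"D2"}}, ss)
        assert fs.value("m1", "m2") == pytest.approx((1 + 1 / 3 + 1) / 3, abs=1e-12)

    def test_empty_set_leaves_pair_uncovered(self, toy_dag):
        ss = semantic_similarity_m1(toy_dag, CFG)
        fs = mirna_functional_similarity({"m1": {"D2"}, "m2": set()}, ss)
        assert not fs.coverage[fs.index["m1"], fs.index["m2"]]
        assert fs.coverage[fs.index["m1"], fs.index["m1"]]

    def test_unknown_disease_errors(self, toy_dag):
        ss = semantic_similarity_m1(toy_dag, CFG)
        with pytest.raises(DataError):
            mirna_functional_similarity({"m1": {"D99"}}, ss)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_brute_force(self, seed):
        """Vectorized best-match average equals an explicit loop computation."""
        rng = np.random.default_rng(seed)
        nd = int(rng.integers(3, 9))
        labels = tuple(f"D{i}" for i in range(nd))
        m = rng.random((nd, nd))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ss = SimilarityMatrix(labels, m)
        sets = {
            f"m{j}": set(rng.choice(labels, size=int(rng.integers(1, 9)), replace=True))
            for j in range(4)
        }
        fs = mirna_functional_similarity(sets, ss)
        for mi, di in sets.items():
            for mj, dj in sets.items():
                total = sum(max(ss.value(a, b) for b in dj) for a in di)
                total += sum(max(ss.value(b, a) for a in di) for b in dj)
                expected = total / (len(di) + len(dj))
                assert fs.value(mi, mj) == pytest.approx(expected, abs=1e-12)


class TestGaussianKernel:
    def test_orthogonal_unit_profiles(self):
        ba = BipartiteAssociations(("d1", "d2"), ("m1", "m2"), np.eye(2, dtype=int))
        k = gaussian_profile_kernel(ba, "rows", 1.0)
        assert k.value("d1", "d2") == pytest.approx(math.exp(-2), abs=1e-12)
        assert k.value("d1", "d1") == 1.0

    def test_identical_profiles_have_similarity_one(self):
        ba = BipartiteAssociations(("d1", "d2"), ("m1", "m2"),
                                   np.array([[1, 0], [1, 0]]))
        k = gaussian_profile_kernel(ba, "rows", 1.0)
        assert k.value("d1", "d2") == pytest.approx(1.0)

    def test_zero_profile_entity_gets_positive_offdiagonal(self):
        ba = BipartiteAssociations(("d1", "d2"), ("m1", "m2"),
                                   np.array([[1, 1], [0, 0]]))
        k = gaussian_profile_kernel(ba, "rows", 1.0)
        # gamma = 1 / mean(norm^2) = 1 / 1 = 1; distance^2 = 2
        assert k.value("d1", "d2") == pytest.approx(math.exp(-2), abs=1e-12)
        assert k.value("d2", "d2") == 1.0

    def test_all_zero_profiles_error(self):
        ba = BipartiteAssociations(("d1",), ("m1",), np.zeros((1, 1), dtype=int))
        with pytest.raises(DataError, match="kernel undefined"):
            gaussian_profile_kernel(ba, "rows", 1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        mat = (rng.random((6, 5)) < 0.5).astype(int)
        mat[:, 0] = 1  # avoid empty profiles
        rows = tuple(f"d{i}" for i in range(6))
        cols = tuple(f"m{j}" for j in range(5))
        k = gaussian_profile_kernel(BipartiteAssociations(rows, cols, mat), "rows")
        perm = rng.permutation(6)
        k_p = gaussian_profile_kernel(
            BipartiteAssociations(tuple(rows[i] for i in perm), cols, mat[perm]),
            "rows",
        )
        for a in rows:
            for b in rows:
                assert k_p.value(a, b) == pytest.approx(k.value(a, b), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_kernel_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 8)), int(rng.integers(2, 8))
        mat = (rng.random((n, m)) < 0.5).astype(int)
        mat[0, 0] = 1
        ba = BipartiteAssociations(tuple(f"r{i}" for i in range(n)),
                                   tuple(f"c{j}" for j in range(m)), mat)
        for axis in ("rows", "cols"):
            k = gaussian_profile_kernel(ba, axis, 1.0)
            assert np.abs(k.matrix - k.matrix.T).max() < 1e-10
            assert k.matrix.min() > 0 and k.matrix.max() <= 1
            assert np.array_equal(np.diag(k.matrix), np.ones(k.n))


class TestIntegration:
    def _sim(self, labels, val, cov=None):
        n = len(labels)
        m = np.full((n, n), val, dtype=float)
        np.fill_diagonal(m, 1.0)
        return SimilarityMatrix(labels, m, cov)

    def test_covered_pairs_are_averaged(self):
        km = self._sim(("m1", "m2"), 0.2)
        fs = self._sim(("m1", "m2"), 0.6)
        sm = integrate_mirna_similarity(km, fs)
        assert sm.value("m1", "m2") == pytest.approx(0.4)

    def test_uncovered_pairs_fall_back_to_kernel(self):
        km = self._sim(("m1", "m2"), 0.2)
        cov = np.eye(2, dtype=bool)
        fs = SimilarityMatrix(("m1", "m2"), np.eye(2), cov)
        sm = integrate_mirna_similarity(km, fs)
        assert sm.value("m1", "m2") == pytest.approx(0.2)
        assert sm.coverage.all()

    def test_equal_inputs_are_a_fixed_point(self):
        km = self._sim(("d1", "d2"), 0.3)
        sd = integrate_disease_similarity(km, km)
        assert sd.matrix == pytest.approx(km.matrix)

    def test_missing_knowledge_matrix_returns_kernel(self):
        km = self._sim(("d1", "d2"), 0.3)
        assert integrate_disease_similarity(km, None).matrix == pytest.approx(km.matrix)

    def test_partial_label_overlap(self):
        km = self._sim(("m1", "m2", "m3"), 0.2)
        fs = self._sim(("m1", "m2"), 0.8)
        sm = integrate_mirna_similarity(km, fs)
        assert sm.value("m1", "m2") == pytest.approx(0.5)
        assert sm.value("m1", "m3") == pytest.approx(0.2)


class TestConfigs:
    def test_delta_range_enforced(self):
        with pytest.raises(ValueError):
            SemanticConfig(delta=1.0)

    def test_gamma_positive_enforced(self):
        with pytest.raises(ValueError):
            KernelConfig(gamma_prime_d=0.0)
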