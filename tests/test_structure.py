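import numpy as np
import pytest

from sweepscan.io_formats import MISSING, ValidationError
from sweepscan.structure import (
    DistanceMatrix,
    _project_rows_to_simplex,
    admixture_nmf,
    nj_tree,
    p_distance_matrix,
    pca,
    relationship_matrix,
    select_K,
)

from conftest import make_gm
from oracles import grm_oracle, p_distance_oracle, patristic_from_newick, random_additive_tree


class TestRelationshipMatrix:
    def test_matches_double_loop_oracle(self, small_sim):
        gm, _, _ = small_sim
        rel = relationship_matrix(gm)
        np.testing.assert_allclose(rel.values, grm_oracle(gm.dosage), atol=1e-10)

    def test_duplicate_samples_have_equal_entries(self):
        rng = np.random.default_rng(0)
        row = rng.choice([0, 1, 2], size=50).astype(np.int8)
        other = rng.choice([0, 1, 2], size=50).astype(np.int8)
        gm = make_gm(np.vstack([row, row, other]))
        rel = relationship_matrix(gm)
        assert rel.values[0, 0] == pytest.approx(rel.values[1, 1])
        assert rel.values[0, 1] == pytest.approx(rel.values[0, 0])

    def test_standardized_columns_centered(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0, 1, 2], size=(30, 100)).astype(np.int8)
        gm = make_gm(d)
        # column means of standardized genotypes are 0 when nothing is missing
        p = d.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        z = (d[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        # and the implementation's matrix equals the naive one built from z
        rel = relationship_matrix(gm)
        np.testing.assert_allclose(rel.values, z @ z.T / poly.sum(), atol=1e-10)

    def test_all_monomorphic_rejected(self):
        gm = make_gm(np.zeros((4, 5), dtype=np.int8))
        with pytest.raises(ValidationError):
            relationship_matrix(gm)


class TestPca:
    def test_identity_relationship_gives_equal_fractions(self):
        from sweepscan.structure import RelationshipMatrix

        n = 8
        rel = RelationshipMatrix(np.eye(n), [f"s{i}" for i in range(n)], 10)
        res = pca(rel, 3)
        np.testing.assert_allclose(res.variance_fraction, 1 / n, atol=1e-12)

    def test_variance_fractions_are_sorted_and_bounded(self, small_sim):
        gm, _, _ = small_sim
        res = pca(relationship_matrix(gm), 5)
        vf = res.variance_fraction
        assert (vf >= 0).all()
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() <= 1 + 1e-12

    def test_population_separation_on_pc1(self, two_pop_sim):
        gm, pm, _ = two_pop_sim
        res = pca(relationship_matrix(gm), 2)
        ia = pm.indices(gm.samples, "A")
        ib = pm.indices(gm.samples, "B")
        a, b = res.coordinates[ia, 0], res.coordinates[ib, 0]
        assert a.max() < b.min() or b.max() < a.min()

    def test_reorder_invariance(self, small_sim):
        gm, _, _ = small_sim
        res1 = pca(relationship_matrix(gm), 3)
        perm = list(reversed(gm.samples))
        gm2 = gm.take_samples(perm)
        res2 = pca(relationship_matrix(gm2), 3)
        back = [perm.index(s) for s in gm.samples]
        np.testing.assert_allclose(
            np.abs(res2.coordinates[back]), np.abs(res1.coordinates), atol=1e-8
        )


class TestPDistance:
    def test_trivial_distances(self):
        gm = make_gm(np.array([[0, 0], [2, 2], [1, 1]], dtype=np.int8))
        d = p_distance_matrix(gm).values
        assert d[0, 1] == pytest.approx(1.0)  # opposite homozygotes
        assert d[0, 2] == pytest.approx(0.5)  # hom vs het
        assert d[0, 0] == 0.0

    def test_matches_naive_oracle_with_missing(self, small_sim):
        gm, _, _ = small_sim
        sub = gm.take_samples(gm.samples[:8])
        np.testing.assert_allclose(
            p_distance_matrix(sub).values, p_distance_oracle(sub.dosage), atol=1e-12
        )

    def test_disjoint_missing_pair_rejected(self):
        d = np.array([[0, MISSING], [MISSING, 2], [1, 1]], dtype=np.int8)
        with pytest.raises(ValidationError, match="share no called sites"):
            p_distance_matrix(make_gm(d))


class TestNjTree:
    def test_three_taxon_branch_lengths(self):
        """d(A,B)=2, d(A,C)=3, d(B,C)=3 → a=1, b=1, c=2."""
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        nwk = nj_tree(DistanceMatrix(d, ["A", "B", "C"]))
        pat = patristic_from_newick(nwk)
        assert pat[("A", "B")] == pytest.approx(2.0)
        assert pat[("A", "C")] == pytest.approx(3.0)
        assert pat[("B", "C")] == pytest.approx(3.0)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrix_recovery(self, n_taxa):
        """NJ exactly recovers path lengths of random additive matrices."""
        rng = np.random.default_rng(n_taxa)
        for _ in range(10):
            names, dist = random_additive_tree(rng, n_taxa)
            nwk = nj_tree(DistanceMatrix(dist, names))
            pat = patristic_from_newick(nwk)
            for i in range(n_taxa):
                for j in range(i + 1, n_taxa):
                    assert pat[(names[i], names[j])] == pytest.approx(
                        dist[i, j], abs=1e-9
                    )

    def test_population_bipartition(self, two_pop_sim):
        """The NJ tree of two diverged populations has an edge splitting
        them exactly."""
        import dendropy

        gm, pm, _ = two_pop_sim
        nwk = nj_tree(p_distance_matrix(gm))
        tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        want = frozenset(s for s in gm.samples if pm.assignment[s] == "A")
        all_taxa = frozenset(t.label for t in tree.taxon_namespace)
        splits = set()
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is tree.seed_node:
                continue
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            splits.add(leaves)
            splits.add(all_taxa - leaves)
        assert want in splits

    def test_nan_rejected(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ["a", "b", "c"])
        dm.values[0, 1] = dm.values[1, 0] = np.nan
        with pytest.raises(ValidationError):
            nj_tree(dm)


class TestAdmixture:
    def test_simplex_projection(self):
        rng = np.random.default_rng(0)
        q = _project_rows_to_simplex(rng.normal(size=(40, 5)))
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-10)
        assert (q >= 0).all()

    def test_k1_gives_unit_column(self, small_sim):
        gm, _, _ = small_sim
        res = admixture_nmf(gm, 1, seed=0)
        np.testing.assert_allclose(res.Q, 1.0, atol=1e-10)

    def test_q_rows_stochastic_and_f_bounded(self, two_pop_sim):
        gm, _, _ = two_pop_sim
        res = admixture_nmf(gm, 3, seed=1)
        np.testing.assert_allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)
        assert (res.F >= 0).all() and (res.F <= 1).all()
        assert np.isfinite(res.masked_cross_entropy) and res.masked_cross_entropy > 0

    def test_loss_trace_non_increasing(self, two_pop_sim):
        gm, _, _ = two_pop_sim
        res = admixture_nmf(gm, 2, seed=2)
        trace = res.loss_trace
        assert len(trace) >= 2
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_two_population_recovery(self, two_pop_sim):
        gm, pm, _ = two_pop_sim
        res = admixture_nmf(gm, 2, seed=3)
        ia = pm.indices(gm.samples, "A")
        ib = pm.indices(gm.samples, "B")
        ca = res.Q[ia].mean(axis=0).argmax()
        cb = res.Q[ib].mean(axis=0).argmax()
        assert ca != cb
        own = np.concatenate([res.Q[ia, ca], res.Q[ib, cb]])
        assert own.mean() > 0.9

    def test_k_bounds_validated(self, small_sim):
        gm, _, _ = small_sim
        with pytest.raises(ValidationError):
            admixture_nmf(gm, gm.n_samples + 1, seed=0)


class TestSelectK:
    def test_single_candidate(self, small_sim):
        gm, _, _ = small_sim
        best, table = select_K(gm, [2], seeds_per_K=1, seed=0)
        assert best == 2 and set(table) == {2}

    def test_cross_entropy_finite_positive(self, two_pop_sim):
        gm, _, _ = two_pop_sim
        best, table = select_K(gm, range(2, 4), seeds_per_K=1, seed=1)
        assert all(np.isfinite(v) and v > 0 for v in table.values())
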