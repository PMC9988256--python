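"""Consensus network: bicor, adjacency, TOM, calibration, tree cut,
eigengenes, merging, connectivity, enrichment factor, sweep, associations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from myoatlas import network as net
from myoatlas import synthetic as syn


def brute_force_tom(A):
    """Independent O(n^3) double-loop implementation of topological overlap."""
    A = np.asarray(A, float).copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def block_expr(n_samples, blocks, n_noise, rho=0.8, seed=0):
    """Samples x genes matrix with latent-factor correlation blocks."""
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    lam = np.sqrt(rho / (1 - rho))
    for b, size in enumerate(blocks):
        z = rng.normal(size=n_samples)
        for _ in range(size):
            cols.append(lam * z + rng.normal(size=n_samples))
            labels.append(f"block{b}")
    for _ in range(n_noise):
        cols.append(rng.normal(size=n_samples))
        labels.append("unassigned")
    return np.column_stack(cols), np.array(labels)


class TestBicor:
    def test_exact_linear_relationships(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        C = net.bicor(np.column_stack([x, 2 * x + 3, -x]))
        assert C[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert C[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_robust_to_gross_outlier(self):
        """One corrupted sample of 20 perturbs bicor less than Pearson."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 0.8 * x + 0.6 * rng.normal(size=20)
        clean = np.corrcoef(x, y)[0, 1]
        xc = x.copy()
        xc[0] = 15.0
        contaminated_pearson = np.corrcoef(xc, y)[0, 1]
        contaminated_bicor = net.bicor(np.column_stack([xc, y]))[0, 1]
        assert abs(contaminated_bicor - clean) < abs(contaminated_pearson - clean)

    def test_zero_mad_fallback_and_min_samples(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 9.0])
        y = np.arange(6.0)
        with pytest.warns(UserWarning, match="zero-MAD"):
            C = net.bicor(np.column_stack([x, y]))
        pear = np.corrcoef(x, y)[0, 1]
        assert C[0, 1] == pytest.approx(pear, abs=0.35)  # hybrid, not Pearson
        with pytest.raises(ValueError):
            net.bicor(np.ones((3, 2)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_values_bounded_with_unit_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        C = net.bicor(rng.normal(size=(8, 5)))
        assert (np.abs(C) <= 1 + 1e-12).all()
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T)


class TestAdjacencyAndTOM:
    def test_signed_hybrid_values(self):
        cor = np.array([[1.0, 0.5], [0.5, 1.0]])
        A = net.adjacency_signed_hybrid(cor, 8)
        assert A[0, 1] == pytest.approx(0.5 ** 8)
        neg = np.array([[1.0, -0.3], [-0.3, 1.0]])
        assert net.adjacency_signed_hybrid(neg, 8)[0, 1] == 0.0
        cor2 = np.array([[1.0, 0.3, -0.2], [0.3, 1.0, 0.1], [-0.2, 0.1, 1.0]])
        A1 = net.adjacency_signed_hybrid(cor2, 1)
        assert np.allclose(A1, np.where(cor2 > 0, cor2, 0)
                           - np.eye(3), atol=1e-12)

    def test_single_edge_triangle(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        T = net.tom_similarity(A)
        assert T[0, 1] == pytest.approx(1.0)
        assert T[0, 2] == pytest.approx(0.0)
        assert T[1, 2] == pytest.approx(0.0)

    def test_complete_graph_saturates(self):
        n = 6
        A = np.ones((n, n)) - np.eye(n)
        T = net.tom_similarity(A)
        assert np.allclose(T, 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        A = rng.uniform(0, 1, (n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        T = net.tom_similarity(A)
        assert np.allclose(T, brute_force_tom(A), atol=1e-12)
        assert (T <= 1 + 1e-10).all() and (T >= 0).all()

    def test_asymmetric_input_rejected(self):
        A = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError):
            net.tom_similarity(A)


class TestConsensusTOM:
    @staticmethod
    def random_toms(k, n, seed):
        rng = np.random.default_rng(seed)
        toms = []
        for i in range(k):
            A = rng.uniform(0, 0.8, (n, n)) * (0.5 + i / k)
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            toms.append(net.tom_similarity(A))
        return toms

    def test_identical_inputs_return_themselves(self):
        T = self.random_toms(1, 12, 0)[0]
        cons = net.consensus_tom([T.copy(), T.copy(), T.copy()])
        assert np.allclose(cons, T, atol=1e-12)

    def test_scaling_one_tom_is_calibrated_away(self):
        """Multiplying a single input TOM by 2 (pre-clip) leaves the
        consensus unchanged when its calibration quantile stays on the same
        side of the median reference."""
        toms = self.random_toms(5, 12, 1)
        base = net.consensus_tom([t.copy() for t in toms])
        iu = np.triu_indices(12, 1)
        qs = [np.quantile(t[iu], 0.95) for t in toms]
        k = int(np.argmax(qs))  # scaling up the largest keeps the median
        scaled = [t.copy() for t in toms]
        scaled[k] = scaled[k] * 2.0
        cons = net.consensus_tom(scaled)
        assert np.abs(cons - base).max() < 1e-10

    def test_order_invariance(self):
        toms = self.random_toms(4, 10, 2)
        c1 = net.consensus_tom(list(toms))
        c2 = net.consensus_tom(toms[::-1])
        assert np.allclose(c1, c2, atol=1e-14)

    def test_input_validation(self):
        T = self.random_toms(1, 8, 3)[0]
        with pytest.raises(ValueError):
            net.consensus_tom([T])
        with pytest.raises(ValueError):
            net.consensus_tom([T, np.zeros((8, 8))])


class TestCutModules:
    def test_two_planted_blocks_recovered(self):
        X, labels = block_expr(60, [50, 50], 30, seed=4)
        C = net.bicor(X)
        T = net.tom_similarity(net.adjacency_signed_hybrid(C, 6))
        found = net.cut_modules(1 - T, net.NetworkParams(power=6),
                                gene_ids=[f"g{i}" for i in range(X.shape[1])])
        assert len([m for m in found.unique() if m != "unassigned"]) == 2
        assert adjusted_rand_score(labels, found.to_numpy()) > 0.9

    def test_pure_noise_mostly_unassigned(self):
        """Replicated pure-noise matrices leave at least 80% of genes
        without a module."""
        fracs = []
        for rep in range(20):
            rng = np.random.default_rng(rep)
            X = rng.normal(size=(40, 100))
            T = net.tom_similarity(
                net.adjacency_signed_hybrid(net.bicor(X), 6))
            found = net.cut_modules(1 - T, net.NetworkParams())
            fracs.append((found == "unassigned").mean())
        assert np.mean(fracs) >= 0.8

    def test_gene_relabeling_permutes_assignment(self):
        X, _ = block_expr(50, [30], 20, seed=5)
        T = net.tom_similarity(net.adjacency_signed_hybrid(net.bicor(X), 6))
        ids = [f"g{i}" for i in range(X.shape[1])]
        a1 = net.cut_modules(1 - T, net.NetworkParams(), gene_ids=ids)
        perm = np.random.default_rng(0).permutation(len(ids))
        a2 = net.cut_modules((1 - T)[np.ix_(perm, perm)], net.NetworkParams(),
                             gene_ids=[ids[i] for i in perm])
        assert a1.sort_index().equals(a2.sort_index())

    def test_fewer_genes_than_min_size_all_unassigned(self):
        D = 1 - np.eye(5)
        found = net.cut_modules(D, net.NetworkParams(min_module_size=20))
        assert (found == "unassigned").all()


class TestEigengenesAndMerge:
    def test_identical_member_genes_reproduce_profile(self, atlas_meta):
        rng = np.random.default_rng(6)
        base = rng.normal(size=len(atlas_meta))
        expr = pd.DataFrame(np.tile(base, (4, 1)),
                            index=[f"g{i}" for i in range(4)],
                            columns=atlas_meta.index)
        assign = pd.Series("M1", index=expr.index)
        me, ve = net.module_eigengenes(expr, assign)
        z = (base - base.mean()) / base.std()
        z /= np.linalg.norm(z)
        assert np.allclose(me["M1"], z, atol=1e-10)
        assert ve["M1"] == pytest.approx(1.0)

    def test_member_order_invariance(self, atlas_meta):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(6, len(atlas_meta))),
                            index=[f"g{i}" for i in range(6)],
                            columns=atlas_meta.index)
        a1 = pd.Series("M1", index=expr.index)
        me1, _ = net.module_eigengenes(expr, a1)
        me2, _ = net.module_eigengenes(expr.iloc[::-1], a1.iloc[::-1])
        assert np.allclose(me1["M1"], me2["M1"], atol=1e-10)

    def test_planted_factor_recovered(self, default_dataset, default_expr):
        truth = default_dataset["truth"]
        assign = truth.module_labels.reindex(default_expr.index).fillna(
            "unassigned")
        me, _ = net.module_eigengenes(default_expr, assign)
        for mod in me.columns:
            r = np.corrcoef(me[mod],
                            truth.module_factors[mod].reindex(me.index))[0, 1]
            assert abs(r) > 0.9

    def test_merge_by_eigengene_similarity(self, atlas_meta):
        rng = np.random.default_rng(8)
        z = rng.normal(size=len(atlas_meta))
        near = np.vstack([z + 0.1 * rng.normal(size=len(z)) for _ in range(8)])
        anti = np.vstack([-z + 0.3 * rng.normal(size=len(z)) for _ in range(4)])
        expr = pd.DataFrame(np.vstack([near[:4], near[4:], anti]),
                            index=[f"g{i}" for i in range(12)],
                            columns=atlas_meta.index)
        assign = pd.Series(["M1"] * 4 + ["M2"] * 4 + ["M3"] * 4,
                           index=expr.index)
        merged, me = net.merge_modules(expr, assign, 0.2)
        mods = set(merged.unique())
        assert len(mods) == 2  # M1 and M2 merged, anticorrelated M3 kept
        assert len(set(merged.iloc[:8])) == 1
        again, _ = net.merge_modules(expr, merged, 0.2)
        assert again.equals(merged)


class TestConnectivity:
    def test_star_center_has_max_kwithin(self):
        n = 6
        A = np.zeros((n, n))
        A[0, 1:] = A[1:, 0] = 0.9
        assign = pd.Series("M1", index=[f"g{i}" for i in range(n)])
        conn = net.intramodular_connectivity(A, assign)
        assert conn["kWithin"].idxmax() == "g0"
        assert conn.loc["g0", "hub"]

    def test_unassigned_genes_absent(self):
        A = np.ones((4, 4)) - np.eye(4)
        assign = pd.Series(["M1", "M1", "M1", "unassigned"],
                           index=[f"g{i}" for i in range(4)])
        conn = net.intramodular_connectivity(A, assign)
        assert "g3" not in conn.index

    def test_kwithin_sums_to_twice_module_mass(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(0, 1, (10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        ids = [f"g{i}" for i in range(10)]
        assign = pd.Series(["M1"] * 6 + ["M2"] * 4, index=ids)
        conn = net.intramodular_connectivity(A, assign)
        sub = A[:6, :6]
        mass = sub[np.triu_indices(6, 1)].sum()
        assert conn.loc[conn["module"] == "M1", "kWithin"].sum() == \
            pytest.approx(2 * mass)


class TestEnrichmentFactor:
    def test_six_gene_worked_example_vs_enumeration(self):
        genes = [f"g{i}" for i in range(1, 7)]
        assign = pd.Series(["A"] * 3 + ["B"] * 3, index=genes)
        pathways = {"p1": ["g1", "g2", "g4"], "p2": ["g3", "g5", "g6"]}
        res = net.enrichment_factor(assign, pathways)
        # exhaustive enumeration oracle over all 15 pairs
        counts = [0, 0, 0, 0]
        for a, b in itertools.combinations(genes, 2):
            sm = assign[a] == assign[b]
            sp = any(a in p and b in p for p in pathways.values())
            counts[0 if sm and sp else 1 if sm else 2 if sp else 3] += 1
        assert (res.n1, res.n2, res.n3, res.n4) == tuple(counts) == (2, 4, 4, 5)
        assert res.ef == pytest.approx(0.625)

    def test_pair_counts_partition_all_pairs(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(30)]
        assign = pd.Series(rng.choice(["M1", "M2", "M3"], 30), index=genes)
        pathways = {f"p{j}": list(rng.choice(genes, 10, replace=False))
                    for j in range(4)}
        res = net.enrichment_factor(assign, pathways)
        g = res.n_genes
        assert res.n1 + res.n2 + res.n3 + res.n4 == g * (g - 1) // 2

    def test_perfect_partition_flags_infinite(self):
        assign = pd.Series(["A"] * 3 + ["B"] * 3, index=list("abcdef"))
        res = net.enrichment_factor(assign, {"p1": list("abc"),
                                             "p2": list("def")})
        assert res.infinite and np.isinf(res.ef)


class TestSweepAndAssociations:
    def test_single_point_grid_returned(self, default_dataset, default_expr):
        truth = default_dataset["truth"]
        pathways = syn.simulate_knowledge_network(truth, 0.0)
        grid = {"powers": (8,), "min_module_sizes": (20,),
                "deep_splits": (0,), "merge_cut_heights": (0.2,)}
        results, best = net.parameter_sweep(default_expr,
                                            default_dataset["meta"], grid,
                                            pathways)
        assert len(results) == 1
        assert best == results[0].params
        assert best.power == 8 and best.min_module_size == 20

    def test_ef_list_length_matches_grid(self, default_dataset, default_expr):
        truth = default_dataset["truth"]
        pathways = syn.simulate_knowledge_network(truth, 0.2, seed=1)
        grid = {"powers": (6, 8), "min_module_sizes": (20,),
                "deep_splits": (0,), "merge_cut_heights": (0.15, 0.2)}
        results, _ = net.parameter_sweep(default_expr, default_dataset["meta"],
                                         grid, pathways)
        assert len(results) == 4

    def test_constant_me_not_muscle_related(self, atlas_meta):
        me = pd.DataFrame({"M1": np.zeros(len(atlas_meta)),
                           "M2": np.random.default_rng(11).normal(
                               size=len(atlas_meta))},
                          index=atlas_meta.index)
        summary, _ = net.module_muscle_association(me, atlas_meta)
        assert not summary.loc["M1", "muscle_related"]

    def test_planted_group_factor_detected(self, atlas_meta):
        rng = np.random.default_rng(12)
        groups = atlas_meta["muscle"].map(syn.DEFAULT_GROUP_MAP)
        me = pd.DataFrame({
            "hit": (groups == "G1").to_numpy(float)
            + 0.3 * rng.normal(size=len(atlas_meta)),
            "null": rng.normal(size=len(atlas_meta))}, index=atlas_meta.index)
        summary, _ = net.module_muscle_association(me, atlas_meta)
        assert summary.loc["hit", "muscle_related"]

    def test_generator_muscle_related_module_detected(self, default_dataset,
                                                      default_expr):
        """The planted group-differential latent factor makes its module
        muscle-related; the iid-factor modules stay null."""
        truth = default_dataset["truth"]
        assign = truth.module_labels.reindex(default_expr.index).fillna(
            "unassigned")
        me, _ = net.module_eigengenes(default_expr, assign)
        summary, _ = net.module_muscle_association(
            me, default_dataset["meta"])
        related = truth.extra["muscle_related_modules"]
        assert summary.loc[related, "muscle_related"].all()
        others = [m for m in me.columns if m not in related]
        assert summary.loc[others, "q"].min() > 0.05

    def test_null_modules_keep_type_one_error(self, atlas_meta):
        rng = np.random.default_rng(13)
        me = pd.DataFrame(rng.normal(size=(len(atlas_meta), 100)),
                          index=atlas_meta.index,
                          columns=[f"M{i}" for i in range(100)])
        summary, _ = net.module_muscle_association(me, atlas_meta)
        assert summary["muscle_related"].mean() <= 0.07


class TestModuleFlagsAndSelection:
    def test_marker_count_rule(self):
        genes = [f"g{i}" for i in range(20)]
        assign = pd.Series(["M1"] * 10 + ["M2"] * 10, index=genes)
        markers = {"endo": genes[:5], "fap": genes[10:14],
                   "imm": genes[14:18]}
        flags = net.flag_celltype_modules(assign, markers, min_markers=5)
        assert flags["M1"]          # 5 endothelial markers
        assert not flags["M2"]      # 4 + 4 of two different sets
        assert not net.flag_celltype_modules(assign, {}, 5).any()

    def test_quantile_selection_boundary(self):
        with pytest.warns(UserWarning, match="skipped"):
            sel = net.select_top_modules({
                "all_ten": np.full(20, 10.0),
                "exact_boundary": np.full(20, 5.5),
            })
        assert sel == ["all_ten"]

    def test_selection_matches_direct_quantile(self):
        rng = np.random.default_rng(14)
        fvals = {f"M{i}": rng.gamma(2, 2.5, size=30) for i in range(10)}
        qs = {f"M{i}": (0.001 if i % 2 == 0 else 0.5) for i in range(10)}
        sel = net.select_top_modules(fvals, annotation_q=qs)
        expected = [m for m in fvals
                    if np.quantile(fvals[m], 0.75) > 5.5 and qs[m] < 0.01]
        assert sel == expected
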