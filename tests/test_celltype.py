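"""Marker-set eigenvectors, the atlas mixed model, and muscle clustering."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from myoatlas import celltype as ct
from myoatlas import synthetic as syn
from myoatlas.lmm import fit_muscle_lmm, random_effect_lrt

from conftest import make_paired_metadata


def expr_frame(mat, meta):
    return pd.DataFrame(mat, index=[f"g{i}" for i in range(mat.shape[0])],
                        columns=meta.index)


class TestEigenvectors:
    def test_singleton_set_is_standardized_gene(self, atlas_meta):
        rng = np.random.default_rng(0)
        expr = expr_frame(rng.normal(size=(3, len(atlas_meta))), atlas_meta)
        eig = ct.celltype_eigenvectors(expr, {"solo": ["g1"]})
        x = expr.loc["g1"].to_numpy()
        z = (x - x.mean()) / x.std()
        z /= np.linalg.norm(z)
        assert np.allclose(eig.scores["solo"], z, atol=1e-10)

    def test_perfectly_correlated_pair_explains_everything(self, atlas_meta):
        rng = np.random.default_rng(1)
        base = rng.normal(size=len(atlas_meta))
        expr = expr_frame(np.stack([base, 3 * base + 5]), atlas_meta)
        eig = ct.celltype_eigenvectors(expr, {"ct": ["g0", "g1"]})
        assert eig.variance_explained["ct"] == pytest.approx(1.0, abs=1e-12)

    def test_scores_track_planted_fraction_gradient(self):
        """With a pronounced planted fraction gradient (low Dirichlet
        concentration, so fractions vary widely) the PC1 scores track the
        true simulated fractions closely."""
        from myoatlas import preprocess as pp
        prior = {g: tuple(np.asarray(v) / 4.0)
                 for g, v in syn.DEFAULT_FRACTION_PRIOR.items()}
        p = syn.GenerativeParams(n_genes=600, seed=13, planted_modules=(),
                                 muscle_effect_sd=0.0, group_effect_sd=0.0,
                                 markers_per_celltype=50,
                                 celltype_fraction_prior=prior)
        counts, meta, truth = syn.simulate_bulk_counts(syn.StudyDesign(), p)
        expr = pp.cpm_log(pp.filter_low_expressed(counts))
        eig = ct.celltype_eigenvectors(expr, truth.marker_sets)
        for name in eig.columns:
            r = np.corrcoef(eig.scores[name],
                            truth.fractions[name].reindex(eig.scores.index))[0, 1]
            assert abs(r) > 0.9

    def test_sign_orients_to_marker_expression(self, default_dataset,
                                               default_expr):
        truth = default_dataset["truth"]
        eig = ct.celltype_eigenvectors(default_expr, truth.marker_sets)
        for name, genes in truth.marker_sets.items():
            mat = default_expr.loc[genes].to_numpy()
            z = (mat - mat.mean(1, keepdims=True)) / mat.std(1, keepdims=True)
            assert np.dot(eig.scores[name], z.mean(axis=0)) > 0

    def test_invariant_to_marker_and_sample_order(self, atlas_meta):
        rng = np.random.default_rng(2)
        expr = expr_frame(rng.normal(size=(6, len(atlas_meta))), atlas_meta)
        genes = ["g0", "g1", "g2", "g3"]
        e1 = ct.celltype_eigenvectors(expr, {"ct": genes})
        e2 = ct.celltype_eigenvectors(expr, {"ct": genes[::-1]})
        assert np.allclose(e1.scores["ct"], e2.scores["ct"], atol=1e-10)
        perm = rng.permutation(expr.shape[1])
        e3 = ct.celltype_eigenvectors(expr.iloc[:, perm], {"ct": genes})
        assert np.allclose(e3.scores["ct"].reindex(e1.scores.index),
                           e1.scores["ct"], atol=1e-10)

    def test_unresolvable_markers_dropped_with_warning(self, atlas_meta):
        expr = expr_frame(np.random.default_rng(3).normal(size=(2, len(atlas_meta))),
                          atlas_meta)
        with pytest.warns(UserWarning, match="not in expression"):
            eig = ct.celltype_eigenvectors(expr, {"ct": ["g0", "g1", "missing"]})
        assert eig.n_markers_used["ct"] == 2
        with pytest.raises(ValueError):
            ct.celltype_eigenvectors(expr, {"ct": ["nope"]})


class TestMuscleLMM:
    def test_constant_response(self, atlas_meta):
        res = fit_muscle_lmm(np.ones(len(atlas_meta)), atlas_meta)
        assert res.fvalue == 0.0 and res.pvalue == 1.0
        assert (res.contrasts["estimate"] == 0).all()

    def test_noiseless_paired_shift_recovered_exactly(self, paired_meta):
        rng = np.random.default_rng(4)
        u = rng.normal(0, 1, 20)
        y = np.array([u[int(i[1:3])] + (1.0 if m == "B" else 0.0)
                      for i, m in zip(paired_meta["individual"],
                                      paired_meta["muscle"])])
        res = fit_muscle_lmm(y, paired_meta)
        est = res.contrasts.iloc[0]["estimate"]  # A - B
        assert est == pytest.approx(-1.0, abs=1e-8)

    def test_matches_paired_t_oracle(self):
        """Two-muscle paired design: the mixed-model muscle p-value matches
        the paired t-test (the exact analysis for this design)."""
        rng = np.random.default_rng(5)
        meta = make_paired_metadata(20)
        rel_errs = []
        for _ in range(200):
            u = rng.normal(0, 1, 20)
            delta = rng.normal(0.3, 0.2)
            ya = u + rng.normal(0, 0.5, 20)
            yb = u + delta + rng.normal(0, 0.5, 20)
            y = np.empty(40)
            y[0::2], y[1::2] = ya, yb
            res = fit_muscle_lmm(y, meta)
            p_t = stats.ttest_rel(ya, yb).pvalue
            if p_t > 1e-12:
                rel_errs.append(abs(res.pvalue - p_t) / p_t)
        assert np.median(rel_errs) < 0.10

    def test_agrees_with_statsmodels_mixedlm(self, atlas_meta):
        """Weighted fit agrees with statsmodels MixedLM on sqrt(w)-scaled
        data (independent REML implementation)."""
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        n = len(atlas_meta)
        u = {ind: rng.normal(0, 0.8) for ind in atlas_meta["individual"].unique()}
        y = np.array([u[i] for i in atlas_meta["individual"]]) + \
            rng.normal(0, 0.5, n)
        w = rng.uniform(0.4, 2.5, n)
        res = fit_muscle_lmm(y, atlas_meta, weights=w)
        sw = np.sqrt(w)
        X = pd.get_dummies(atlas_meta["muscle"], drop_first=True).to_numpy(float)
        X = np.column_stack([np.ones(n), X])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mm = sm.MixedLM(sw * y, sw[:, None] * X,
                            groups=atlas_meta["individual"].to_numpy(),
                            exog_re=sw[:, None]).fit(reml=True)
        assert res.var_residual == pytest.approx(mm.scale, rel=1e-3)
        assert res.var_individual == pytest.approx(
            float(np.asarray(mm.cov_re)[0, 0]), rel=1e-3, abs=1e-6)

    def test_weight_validation_and_few_individuals_fallback(self, paired_meta):
        y = np.random.default_rng(7).normal(size=len(paired_meta))
        with pytest.raises(ValueError):
            fit_muscle_lmm(y, paired_meta, weights=np.zeros(len(y)))
        solo = paired_meta[paired_meta["individual"] == "I00"]
        yy = np.r_[y[:1], y[:1], y[1:2], y[1:2]]
        meta4 = pd.concat([solo, solo]).copy()
        meta4.index = [f"s{i}" for i in range(4)]
        meta4["sample"] = meta4.index
        with pytest.warns(UserWarning, match="fewer than two individuals"):
            res = fit_muscle_lmm(yy + np.random.default_rng(1).normal(0, .1, 4),
                                 meta4)
        assert res.fallback_fixed

    def test_random_effect_lrt_detects_planted_intercepts(self, paired_meta):
        rng = np.random.default_rng(8)
        u = rng.normal(0, 2, 20)
        y = np.repeat(u, 2) + rng.normal(0, 0.3, 40)
        lr, p = random_effect_lrt(y, paired_meta)
        assert p < 1e-6
        y0 = rng.normal(0, 1, 40)
        _, p0 = random_effect_lrt(y0, paired_meta)
        assert p0 > 0.01


class TestCelltypeAssociation:
    def test_null_simulation_keeps_fdr(self):
        """No group differences: few cell types reach q<0.05 over replicates."""
        rng = np.random.default_rng(9)
        design = syn.StudyDesign(n_individuals=12, missingness_rate=0.0)
        rows = [(f"I{i:02d}_{m}", f"I{i:02d}", m) for i in range(12)
                for m in design.muscles]
        meta = pd.DataFrame(rows, columns=["sample", "individual", "muscle"]
                            ).set_index("sample", drop=False)
        hits, total = 0, 0
        for _ in range(60):
            scores = pd.DataFrame(
                rng.normal(size=(len(meta), 4)), index=meta.index,
                columns=list("abcd"))
            eig = ct.EigenTable(scores, pd.Series(1.0, index=list("abcd")),
                                pd.Series(5, index=list("abcd")))
            summary, _ = ct.celltype_association(eig, meta)
            hits += int(summary["significant"].sum())
            total += 4
        assert hits / total <= 0.07

    def test_planted_endothelial_shift_ranks_first(self):
        """When only the endothelial fraction differs between groups (+50%
        in G2/G3) that cell type tops the association F ranking."""
        from myoatlas import preprocess as pp
        prior = {"G1": (10.0, 10.0, 4.0, 3.0, 3.0),
                 "G2": (10.0, 10.0, 6.0, 3.0, 3.0),
                 "G3": (10.0, 10.0, 6.0, 3.0, 3.0)}
        for rep in range(5):
            p = syn.GenerativeParams(n_genes=400, seed=100 + rep,
                                     planted_modules=(), muscle_effect_sd=0.0,
                                     group_effect_sd=0.0,
                                     celltype_fraction_prior=prior)
            counts, meta, truth = syn.simulate_bulk_counts(syn.StudyDesign(), p)
            expr = pp.cpm_log(pp.filter_low_expressed(counts))
            eig = ct.celltype_eigenvectors(expr, truth.marker_sets)
            summary, _ = ct.celltype_association(eig, meta)
            assert summary["F"].idxmax() == "endothelial"

    def test_default_effect_size_detected_with_power(self):
        """At the generator-default composition (endothelial +50% in G2/G3,
        20 individuals) the endothelial association is detected reliably."""
        from myoatlas import preprocess as pp
        hits = 0
        for rep in range(5):
            p = syn.GenerativeParams(n_genes=400, seed=200 + rep,
                                     planted_modules=())
            counts, meta, truth = syn.simulate_bulk_counts(syn.StudyDesign(), p)
            expr = pp.cpm_log(pp.filter_low_expressed(counts))
            summary, _ = ct.celltype_association(
                ct.celltype_eigenvectors(expr, truth.marker_sets), meta)
            hits += bool(summary["significant"]["endothelial"])
        assert hits >= 4

    def test_label_permutation_destroys_significance(self, default_dataset,
                                                     default_expr):
        truth = default_dataset["truth"]
        meta = default_dataset["meta"].copy()
        eig = ct.celltype_eigenvectors(default_expr, truth.marker_sets)
        rng = np.random.default_rng(10)
        qs = []
        for _ in range(5):
            perm = meta.copy()
            perm["muscle"] = rng.permutation(perm["muscle"].to_numpy())
            # keep >=2 obs per muscle guaranteed by permutation of labels
            summary, _ = ct.celltype_association(eig, perm)
            qs.extend(summary["q"].tolist())
        assert np.median(qs) > 0.2


class TestClusterMuscles:
    def test_three_group_design_recovered(self, default_dataset, default_expr):
        truth = default_dataset["truth"]
        meta = default_dataset["meta"]
        eig = ct.celltype_eigenvectors(default_expr, truth.marker_sets)
        Z, means = ct.cluster_muscles(eig, meta)
        k3 = hierarchy.fcluster(Z, 3, criterion="maxclust")
        found = {m: k for m, k in zip(means.index, k3)}
        groups = {m: syn.DEFAULT_GROUP_MAP[m] for m in means.index}
        # same partition: equal labels iff equal groups
        for m1 in found:
            for m2 in found:
                assert (found[m1] == found[m2]) == (groups[m1] == groups[m2])

    def test_identical_muscles_zero_height(self, atlas_meta):
        scores = pd.DataFrame(
            {"a": np.tile([1.0, -1.0], len(atlas_meta) // 2),
             "b": np.tile([-1.0, 1.0], len(atlas_meta) // 2)},
            index=atlas_meta.index)
        # make every muscle's mean profile identical
        scores[:] = np.tile([[0.5, -0.5]], (len(atlas_meta), 1))
        eig = ct.EigenTable(scores, pd.Series(1.0, index=["a", "b"]),
                            pd.Series(2, index=["a", "b"]))
        Z, means = ct.cluster_muscles(eig, atlas_meta)
        assert means.shape == (7, 2)
        assert np.allclose(Z[:, 2], 0.0)

    def test_matrix_shape(self, default_dataset, default_expr):
        truth = default_dataset["truth"]
        eig = ct.celltype_eigenvectors(default_expr, truth.marker_sets)
        _, means = ct.cluster_muscles(eig, default_dataset["meta"])
        assert means.shape == (7, len(truth.marker_sets))
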