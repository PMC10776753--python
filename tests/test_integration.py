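"""Overlap, enrichment, PCA reduction, stepwise regression, LOOCV,
top-weight extraction and clinical models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import imgomix as im
from imgomix.errors import (
    DegenerateResponseError,
    EmptyFeatureSetError,
    InvalidArgumentError,
)
from imgomix.integration import (
    PCAReduction,
    SMLRFit,
    _candidate_pvalues,
    pca_reduce,
    smlr_fit,
)


class TestOverlap:
    def test_set_identities(self):
        assert im.overlap_genes(["a", "b"], ["c"]).overlap == set()
        assert im.overlap_genes(["a"], ["a", "b"]).overlap == {"a"}

    def test_matches_brute_force(self, rng):
        a = [f"g{i}" for i in rng.integers(0, 50, 30)]
        b = [f"g{i}" for i in rng.integers(0, 50, 30)]
        got = im.overlap_genes(a, b).overlap
        assert got == {g for g in a if g in set(b)}


class TestEnrichment:
    def test_hand_computed_hypergeometric(self):
        # N=10 genes, pathway of 5, drawn set of 4, all 4 inside:
        # p = C(5,4) C(5,0) / C(10,4) = 5/210
        universe = [f"g{i}" for i in range(10)]
        pathways = {"pw": universe[:5]}
        enr = im.enrich_pathways(universe[:4], pathways, universe)
        assert enr.loc["pw", "p"] == pytest.approx(5 / 210)

    def test_everything_drawn_gives_p_one(self):
        universe = [f"g{i}" for i in range(6)]
        enr = im.enrich_pathways(universe, {"pw": universe}, universe)
        assert enr.loc["pw", "p"] == pytest.approx(1.0)

    def test_members_outside_universe_dropped(self):
        universe = ["a", "b", "c", "d"]
        enr = im.enrich_pathways(["a"], {"pw": ["a", "zzz"]}, universe)
        assert enr.loc["pw", "K"] == 1


class TestFeatureSelection:
    def _dmps(self):
        return pd.DataFrame(
            {"gene": ["A", "A", "B", "C"]},
            index=pd.Index([f"cg{i}" for i in range(4)], name="cpg_id"))

    def test_no_enriched_pathway_halts(self):
        enr = pd.DataFrame({"q": [0.9]}, index=["pw"])
        with pytest.raises(EmptyFeatureSetError):
            im.select_dmp_features(self._dmps(), {"A"}, enr, 0.05, {"pw": ["A"]})

    def test_all_genes_in_one_enriched_pathway(self):
        enr = pd.DataFrame({"q": [0.001]}, index=["pw"])
        feats = im.select_dmp_features(self._dmps(), {"A", "B", "C"}, enr,
                                       0.05, {"pw": ["A", "B", "C"]})
        assert feats == ["cg0", "cg1", "cg2", "cg3"]

    def test_pool_intersection_applies(self):
        enr = pd.DataFrame({"q": [0.001]}, index=["pw"])
        feats = im.select_dmp_features(self._dmps(), {"A"}, enr, 0.05,
                                       {"pw": ["A", "B", "C"]})
        assert feats == ["cg0", "cg1"]


class TestPCA:
    def test_threshold_one_keeps_full_rank(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        red = pca_reduce(X, 1.0)
        assert red.k == np.linalg.matrix_rank(X - X.mean())

    def test_component_count_rule(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 12)))
        red = pca_reduce(X, 0.8)
        cum = np.cumsum(red.explained_ratio)
        assert cum[red.k - 1] >= 0.8
        assert red.k == 1 or cum[red.k - 2] < 0.8

    def test_matches_svd_eckart_young(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 7)))
        red = pca_reduce(X, 0.8)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        best = U[:, :red.k] @ np.diag(s[:red.k]) @ Vt[:red.k]
        recon = red.scores.to_numpy() @ red.loadings.to_numpy().T
        assert np.allclose(recon, best, atol=1e-8)

    def test_orthonormal_loadings_and_sign_convention(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 8)))
        red = pca_reduce(X, 0.9)
        L = red.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(red.k), atol=1e-10)
        for c in range(red.k):
            assert L[np.argmax(np.abs(L[:, c])), c] > 0

    def test_invalid_threshold(self, rng):
        with pytest.raises(InvalidArgumentError):
            pca_reduce(pd.DataFrame(rng.normal(size=(5, 3))), 1.5)


class TestSMLR:
    def test_single_perfect_predictor(self, rng):
        x = rng.normal(size=40)
        scores = pd.DataFrame({"C1": x, "C2": rng.normal(size=40)})
        fit = smlr_fit(2.0 * x + 0.001 * rng.normal(size=40), scores)
        assert fit.selected[0] == "C1"
        assert fit.r_squared > 0.99
        assert fit.p_model < 1e-6

    def test_first_entry_is_best_marginal_predictor(self, rng):
        for _ in range(10):
            scores = pd.DataFrame(rng.normal(size=(30, 5)),
                                  columns=list("ABCDE"))
            y = rng.normal(size=30) + 0.8 * scores["C"]
            cand = _candidate_pvalues(y.to_numpy(), scores, [])
            fit = smlr_fit(y.to_numpy(), scores)
            if fit.selected:
                assert fit.selected[0] == cand.idxmin()

    def test_final_model_self_consistent(self, rng):
        # every included term's p stays below p_remove; no excluded
        # candidate would enter at p_enter
        for _ in range(10):
            scores = pd.DataFrame(rng.normal(size=(40, 6)),
                                  columns=[f"C{i}" for i in range(6)])
            y = (rng.normal(size=40) + 0.7 * scores["C1"] - 0.5 * scores["C4"]
                 ).to_numpy()
            fit = smlr_fit(y, scores)
            if fit.selected:
                from imgomix.integration import _ols
                _, pvals, *_ = _ols(y, scores[fit.selected].to_numpy())
                assert (pvals[1:] <= 0.10 + 1e-12).all()
            cand = _candidate_pvalues(y, scores, fit.selected)
            if len(cand):
                assert cand.min() >= 0.05 - 1e-12

    def test_constant_response_rejected(self, rng):
        scores = pd.DataFrame(rng.normal(size=(20, 3)))
        with pytest.raises(DegenerateResponseError):
            smlr_fit(np.ones(20), scores)

    def test_null_model_when_nothing_enters(self):
        rng = np.random.default_rng(8)
        scores = pd.DataFrame({"C1": rng.normal(size=200)})
        y = np.concatenate([rng.normal(size=200)])
        # force a clearly unrelated predictor by regressing it out
        coef = np.polyfit(scores["C1"], y, 1)
        y = y - coef[0] * scores["C1"].to_numpy()
        fit = smlr_fit(y, scores)
        assert fit.is_null
        assert np.isnan(fit.fvalue)
        assert fit.p_model > 0.05


class TestLOOCV:
    def test_deterministic_and_correct_length(self, rng):
        feats = pd.DataFrame(rng.normal(size=(20, 6)))
        y = feats.iloc[:, 0].to_numpy() + 0.5 * rng.normal(size=20)
        a = im.loocv_validate(y, feats, 0.9)
        b = im.loocv_validate(y, feats, 0.9)
        assert np.array_equal(a[0], b[0])
        assert len(a[0]) == 20

    def test_signal_gives_positive_r(self, rng):
        feats = pd.DataFrame(rng.normal(size=(50, 8)))
        y = feats.iloc[:, 0].to_numpy() * 1.0 + 0.6 * rng.normal(size=50)
        _, r, p, _ = im.loocv_validate(y, feats, 0.9)
        assert r > 0.3

    def test_empty_folds_fall_back_to_training_mean(self, rng):
        feats = pd.DataFrame(rng.normal(size=(15, 3)))
        y = rng.normal(size=15)
        preds, r, p, n_empty = im.loocv_validate(y, feats, 0.9)
        assert np.isfinite(preds).all()

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            im.loocv_validate(np.ones(5), pd.DataFrame(rng.normal(size=(5, 2))))


class TestTopWeights:
    def _pca(self, loadings):
        L = pd.DataFrame(loadings, index=[f"cg{i}" for i in range(len(loadings))],
                         columns=["C1"])
        scores = pd.DataFrame(np.zeros((3, 1)), columns=["C1"])
        return PCAReduction(scores, L, np.array([1.0]), 1, np.zeros(len(loadings)))

    def _fit(self, std_coef):
        return SMLRFit(["C1"], pd.Series({"intercept": 0, "C1": 1.0}),
                       pd.Series({"C1": std_coef}), 1.0, 0.01, 0.01, 0.5,
                       n=3, n_offered=1)

    def test_weight_arithmetic(self):
        anno = pd.DataFrame({"gene": ["GX"]}, index=["cg0"])
        out = im.top_weight_dmps(self._pca([[0.5]]), {"R1": self._fit(0.6)},
                                 anno, 0.2)
        assert len(out) == 1
        assert out.loc[0, "weight"] == pytest.approx(0.30)
        assert out.loc[0, "gene"] == "GX"

    def test_below_threshold_empty(self):
        anno = pd.DataFrame({"gene": ["GX"]}, index=["cg0"])
        out = im.top_weight_dmps(self._pca([[0.2]]), {"R1": self._fit(0.6)},
                                 anno, 0.2)
        assert len(out) == 0

    def test_planted_dmps_dominate_ranking(self, small_study, small_tmap):
        # end-to-end on the small study: planted CpGs should concentrate at
        # the top of the composite-weight ranking
        study = small_study
        res = im.test_regions(study.cohort)
        sig = im.significant_regions(res)
        cres = im.fit_cpg_glm(study.methylation, study.cohort)
        dmps = im.select_dmps(cres)
        feats = sorted(set(dmps.index) & set(study.methylation.cpg_ids))
        pat = study.cohort.patients()
        feat_beta = study.methylation.beta.loc[pat.subjects.index, feats]
        pca = im.pca_reduce(feat_beta, 0.8)
        assoc = im.region_association(pat.gmv, pca, sig)
        fits = assoc.attrs["fits"]
        sig_regions = list(assoc.index[assoc["significant"]])
        assert sig_regions, "no significant region on the small study"
        top = im.top_weight_dmps(pca, {r: fits[r] for r in sig_regions},
                                 study.methylation.annotation,
                                 weight_threshold=0.0)
        ranked = top.groupby("cpg_id")["weight"].max().sort_values(ascending=False)
        td = set(study.truth["true_dmps"])
        top_k = set(ranked.index[: len(td)])
        assert len(top_k & td) / len(td) > 0.5


class TestClinicalModels:
    def test_four_fits_and_degenerate_response(self, rng):
        pat = pd.DataFrame({"hamd": rng.normal(20, 4, 30),
                            "hama": rng.normal(15, 4, 30)},
                           index=[f"S{i}" for i in range(30)])
        scores = pd.DataFrame(rng.normal(size=(30, 4)),
                              columns=list("ABCD"), index=pat.index)
        gmv = pd.DataFrame(rng.normal(0.5, 0.05, (30, 2)),
                           columns=["P1", "P2"], index=pat.index)
        out = im.clinical_models(pat, scores, gmv)
        assert set(out) == {"hamd~components", "hamd~gmv",
                            "hama~components", "hama~gmv"}
        pat["hamd"] = 20.0
        with pytest.raises(DegenerateResponseError):
            im.clinical_models(pat, scores, gmv)
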