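"""Spatial PLS: component contracts, spin permutation, bootstrap Z-scores."""

import numpy as np
import pandas as pd
import pytest

import imgomix as im
from imgomix.datatypes import ExpressionMatrix, ParcelMap
from imgomix.errors import (
    DegenerateResponseError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from imgomix.pls import (
    SpinTestResult,
    _standardize_columns,
    _standardize_y,
    random_rotation,
    spin_assignment,
)


def _random_instance(rng, n=30, p=10):
    ids = tuple(f"P{i}" for i in range(n))
    X = ExpressionMatrix(pd.DataFrame(rng.normal(size=(n, p)), index=list(ids),
                                      columns=[f"G{j}" for j in range(p)]))
    y = ParcelMap(ids, rng.normal(size=n))
    return X, y


class TestFitPLS:
    def test_rank_one_recovery(self, rng):
        n, p = 40, 15
        ids = tuple(f"P{i}" for i in range(n))
        yv = rng.normal(size=n)
        v = rng.normal(size=p)
        data = np.outer(yv, v) + 1e-6 * rng.normal(size=(n, p))
        X = ExpressionMatrix(pd.DataFrame(data, index=list(ids),
                                          columns=[f"G{j}" for j in range(p)]))
        fit = im.fit_pls(X, ParcelMap(ids, yv), 2)
        assert fit.variance_explained[0] > 0.99

    def test_orthogonal_response_explains_nothing(self, rng):
        n, p = 50, 5
        X, y = _random_instance(rng, n, p)
        Xs = _standardize_columns(X.data.to_numpy())
        yv = rng.normal(size=n)
        coef, *_ = np.linalg.lstsq(Xs, yv, rcond=None)
        resid = yv - Xs @ coef  # orthogonal to the column space
        fit = im.fit_pls(X, ParcelMap(y.parcel_ids, resid), 1)
        assert fit.variance_explained[0] < 0.05

    def test_first_weight_matches_eigen_oracle(self, rng):
        # brute force: dominant eigenvector of X' y y' X
        for _ in range(10):
            X, y = _random_instance(rng, 8, 5)
            Xs = _standardize_columns(X.data.to_numpy())
            ys = _standardize_y(y.values)
            M = Xs.T @ np.outer(ys, ys) @ Xs
            evals, evecs = np.linalg.eigh(M)
            w_oracle = evecs[:, -1]
            fit = im.fit_pls(X, y, 1)
            w = fit.weights[:, 0]
            assert min(np.abs(w - w_oracle).max(),
                       np.abs(w + w_oracle).max()) < 1e-6

    def test_variance_explained_is_squared_score_correlation(self, rng):
        for _ in range(20):
            X, y = _random_instance(rng)
            fit = im.fit_pls(X, y, 3)
            ys = _standardize_y(y.values)
            r = np.corrcoef(fit.pls1_scores.values, ys)[0, 1]
            assert abs(fit.variance_explained[0] - r * r) < 1e-10
            assert r >= 0  # sign convention

    def test_invalid_arguments(self, rng):
        X, y = _random_instance(rng, 10, 4)
        with pytest.raises(InvalidArgumentError):
            im.fit_pls(X, y, 10)
        with pytest.raises(DegenerateResponseError):
            im.fit_pls(X, ParcelMap(y.parcel_ids, np.ones(10)), 1)

    def test_gene_order_and_affine_invariance(self, rng):
        X, y = _random_instance(rng, 25, 8)
        fit = im.fit_pls(X, y, 1)
        w = fit.pls1_weights
        perm = rng.permutation(X.genes)
        fit_p = im.fit_pls(ExpressionMatrix(X.data[perm]), y, 1)
        assert np.allclose(fit_p.pls1_weights[w.index], w, atol=1e-8)
        rescaled = ExpressionMatrix(X.data * 3.7 + 11.0)
        fit_a = im.fit_pls(rescaled, y, 1)
        assert np.allclose(fit_a.pls1_weights, w, atol=1e-8)


class TestSpatialCorrelation:
    def test_identical_and_negated_maps(self, rng):
        v = rng.normal(size=20)
        assert im.spatial_correlation(v, v)[0] == pytest.approx(1.0)
        assert im.spatial_correlation(v, -v)[0] == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_hand = (np.sum((a - 3) * (b - 3.2))
                  / np.sqrt(np.sum((a - 3) ** 2) * np.sum((b - 3.2) ** 2)))
        assert im.spatial_correlation(a, b)[0] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            im.spatial_correlation(np.ones(5), np.arange(5.0))


class TestSpin:
    def test_identity_rotation_is_identity_assignment(self):
        parc = im.generate_parcellation(40, seed=0)
        assert np.array_equal(spin_assignment(parc.centroids, np.eye(3)),
                              np.arange(40))

    def test_rotations_are_proper_and_uniformish(self, rng):
        for _ in range(20):
            R = random_rotation(rng)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0)

    def test_p_spin_add_one_formula(self):
        res = SpinTestResult("s", 0.5, np.array([0.1, 0.6, 0.7, 0.2]), 4)
        assert res.p_spin == pytest.approx(3 / 5)

    def test_deterministic_given_seed(self, small_study, small_tmap):
        a = im.spin_test_pls(small_study.expression, small_tmap,
                             small_study.parcellation.centroids, 100, seed=5)
        b = im.spin_test_pls(small_study.expression, small_tmap,
                             small_study.parcellation.centroids, 100, seed=5)
        assert a.p_spin == b.p_spin
        assert np.array_equal(a.permuted, b.permuted)

    def test_planted_coupling_detected(self, small_study, small_tmap):
        res = im.spin_test_pls(small_study.expression, small_tmap,
                               small_study.parcellation.centroids, 200, seed=1)
        assert res.p_spin < 0.05

    def test_preconditions(self, small_study, small_tmap):
        with pytest.raises(InvalidArgumentError):
            im.spin_test_pls(small_study.expression, small_tmap,
                             small_study.parcellation.centroids * 2, 200)
        with pytest.raises(InvalidArgumentError):
            im.spin_test_pls(small_study.expression, small_tmap,
                             small_study.parcellation.centroids, 50)


class TestBootstrapZ:
    def test_planted_genes_dominate_z_ranking(self, small_study, small_tmap):
        # at the reduced fixture scale the absolute |Z|>3 cut is under-
        # powered (it is checked at full scale in the acceptance suite);
        # the planted genes must still separate cleanly from the nulls
        table = im.bootstrap_gene_z(small_study.expression, small_tmap,
                                    300, seed=2)
        coupled = set(small_study.truth["coupled_genes"])
        null_z = table.drop(index=list(coupled))["z"].abs()
        med_coupled = table.loc[list(coupled), "z"].abs().median()
        assert med_coupled > np.percentile(null_z, 95)
        ranked = set(table["z"].abs().sort_values(ascending=False)
                     .index[: 2 * len(coupled)])
        assert len(ranked & coupled) / len(coupled) > 0.8

    def test_iid_null_genes_at_normal_tail_rate(self, rng):
        # with spatially unstructured genes and response, |Z| > 3 should be
        # a rare normal-tail event (smooth null maps are intentionally NOT
        # calibrated here: correcting spatial autocorrelation is the spin
        # test's job, not the bootstrap's)
        X, y = _random_instance(rng, n=60, p=400)
        table = im.bootstrap_gene_z(X, y, 300, seed=0)
        assert (table["z"].abs() > 3).mean() < 0.02

    def test_z_stable_across_seeds(self, small_study, small_tmap):
        a = im.bootstrap_gene_z(small_study.expression, small_tmap, 400, seed=3)
        b = im.bootstrap_gene_z(small_study.expression, small_tmap, 400, seed=4)
        assert np.corrcoef(a["z"], b["z"])[0, 1] > 0.95

    def test_select_thresholds(self):
        table = pd.DataFrame(
            {"z": [3.5, -3.5, 2.9], "q": [0.01, 0.01, 0.01],
             "weight": [0.1, -0.1, 0.05], "se": [0.01] * 3, "p": [0.001] * 3},
            index=pd.Index(["g1", "g2", "g3"], name="gene"))
        pos, neg = im.select_pls_genes(table)
        assert pos == ["g1"] and neg == ["g2"]
        table["q"] = 1.0
        pos, neg = im.select_pls_genes(table)
        assert pos == [] and neg == []
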