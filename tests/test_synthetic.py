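"""Generator invariants: geometry, spatial autocorrelation, planted truth."""

import numpy as np
import pandas as pd
import pytest

import imgomix as im
from imgomix.errors import InvalidArgumentError
from imgomix.io import write_study
from imgomix.synthetic import (
    SynthConfig,
    default_effect_parcels,
    effect_pattern_map,
    exponential_kernel_cholesky,
    generate_parcellation,
    generate_smooth_map,
)


class TestParcellation:
    def test_unit_norm_and_distinct(self):
        for n in (4, 180):
            parc = generate_parcellation(n, seed=1)
            norms = np.linalg.norm(parc.centroids, axis=1)
            assert np.allclose(norms, 1.0, atol=1e-12)
            d = parc.geodesic_distances()
            assert (d[np.triu_indices(n, 1)] > 1e-6).all()

    def test_deterministic_given_seed(self):
        a = generate_parcellation(50, seed=3)
        b = generate_parcellation(50, seed=3)
        assert np.array_equal(a.centroids, b.centroids)
        c = generate_parcellation(50, seed=4)
        assert not np.allclose(a.centroids, c.centroids)

    def test_too_few_parcels_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_parcellation(3, seed=0)


class TestSmoothMap:
    def test_white_noise_limit_small_kappa(self, rng):
        parc = generate_parcellation(80, seed=2)
        draws = generate_smooth_map(parc.centroids, 1e-3, rng, size=200)
        # nearest-neighbour correlation across draws should vanish
        d = parc.geodesic_distances() + np.eye(80) * 10
        nn = d.argmin(axis=1)
        cors = [np.corrcoef(draws[i], draws[nn[i]])[0, 1] for i in range(80)]
        assert abs(np.mean(cors)) < 0.1

    def test_neighbour_correlation_matches_kernel(self, rng):
        # oracle: the stated covariance exp(-d/kappa) evaluated at the
        # nearest-neighbour distance predicts the empirical correlation
        parc = generate_parcellation(180, seed=2)
        kappa = 1.0
        draws = generate_smooth_map(parc.centroids, kappa, rng, size=200)
        d = parc.geodesic_distances() + np.eye(180) * 10
        nn = d.argmin(axis=1)
        cors = [np.corrcoef(draws[i], draws[nn[i]])[0, 1] for i in range(180)]
        expected = np.exp(-d[np.arange(180), nn] / kappa).mean()
        assert np.mean(cors) > 0.3
        assert abs(np.mean(cors) - expected) < 0.15

    def test_deterministic(self):
        parc = generate_parcellation(40, seed=5)
        a = generate_smooth_map(parc.centroids, 0.5, 11)
        b = generate_smooth_map(parc.centroids, 0.5, 11)
        assert np.array_equal(a, b)


class TestExpression:
    def test_zero_coupling_independent(self, rng):
        parc = generate_parcellation(80, seed=1)
        pattern = effect_pattern_map(parc, range(8))
        expr = im.generate_expression(parc.centroids, 100, pattern, 30, 0.0, rng)
        r = np.array([np.corrcoef(expr.data.iloc[:, j], pattern.values)[0, 1]
                      for j in range(30)])
        assert np.mean(np.abs(r)) < 2 / np.sqrt(80)

    def test_target_coupling_recovered(self):
        parc = generate_parcellation(180, seed=1)
        pattern = effect_pattern_map(parc, range(15))
        rs = []
        for seed in range(5):
            expr = im.generate_expression(parc.centroids, 150, pattern, 100,
                                          0.6, seed)
            vals = expr.data.to_numpy()
            r = [abs(np.corrcoef(vals[:, j], pattern.values)[0, 1])
                 for j in range(100)]
            rs.append(np.mean(r))
        assert abs(np.mean(rs) - 0.6) < 0.1

    def test_paper_scale_shape(self):
        parc = generate_parcellation(180, seed=1)
        pattern = effect_pattern_map(parc, range(15))
        expr = im.generate_expression(parc.centroids, 10027, pattern, 10, 0.5, 0)
        assert expr.data.shape == (180, 10027)

    def test_invalid_coupling_rejected(self, rng):
        parc = generate_parcellation(20, seed=1)
        pattern = effect_pattern_map(parc, range(3))
        with pytest.raises(InvalidArgumentError):
            im.generate_expression(parc.centroids, 10, pattern, 5, 1.0, rng)


class TestCohort:
    def test_null_effect_gives_nominal_rejection_rate(self):
        parc = generate_parcellation(300, seed=9)  # parcels double as null sims
        cohort = im.generate_cohort(parc, [], 0.0, 40, 40, seed=1)
        res = im.test_regions(cohort)
        rate = (res["p"] < 0.05).mean()
        assert abs(rate - 0.05) <= 0.03

    def test_planted_deficit_direction_and_power(self, small_study):
        truth = small_study.truth
        cohort = small_study.cohort
        case = cohort.subjects["group"] == "MDD"
        eff = truth["effect_parcels"]
        assert (cohort.gmv.loc[case, eff].mean()
                < cohort.gmv.loc[~case, eff].mean()).all()
        # covariate-adjusted test at nominal alpha: high power at d=0.8
        res = im.test_regions(cohort)
        assert (res.loc[eff, "p"] < 0.05).mean() > 0.9

    def test_gmv_positive_and_covariates_complete(self, small_study):
        sub = small_study.cohort.subjects
        assert (small_study.cohort.gmv.to_numpy() > 0).all()
        for col in ("age", "gender", "education", "medication", "tiv",
                    "hamd", "hama"):
            assert np.isfinite(sub[col].astype(float)).all()


class TestMethylation:
    def test_beta_range(self, small_study):
        b = small_study.methylation.beta.to_numpy()
        assert b.min() >= 0 and b.max() <= 1

    def test_planted_dmps_promoter_coupled_genes(self, small_study):
        truth = small_study.truth
        anno = small_study.methylation.annotation
        td = truth["true_dmps"]
        assert len(td) == 20
        assert anno.loc[td, "promoter_flag"].all()
        assert set(anno.loc[td, "gene"]) <= set(truth["coupled_genes"])

    def test_planted_delta_beta_magnitude(self, small_study):
        meth, cohort = small_study.methylation, small_study.cohort
        case = (cohort.subjects["group"] == "MDD").to_numpy()
        td = small_study.truth["true_dmps"]
        diff = (meth.beta.loc[case, td].mean() - meth.beta.loc[~case, td].mean())
        assert abs(diff.abs().mean() - 0.05) < 0.02

    def test_excessive_delta_rejected(self, small_study):
        with pytest.raises(InvalidArgumentError):
            im.generate_methylation(
                small_study.cohort, small_study.expression.genes,
                small_study.truth["coupled_genes"], 100, 10, 0.9, seed=0)

    def test_latent_composite_tracks_truth(self, small_study):
        u = pd.Series(small_study.truth["subject_latent"])
        comp = small_study.methylation.beta[
            small_study.truth["true_dmps"]].mean(axis=1)
        r = np.corrcoef(comp, u.loc[comp.index])[0, 1]
        assert abs(r) > 0.8


class TestPathways:
    def test_planted_enrichment_detectable(self, small_study):
        enr = im.enrich_pathways(set(small_study.truth["true_dmp_genes"]),
                                 small_study.pathways,
                                 small_study.expression.genes)
        flagged = set(enr.index[enr["q"] < 0.05])
        assert set(small_study.truth["enriched_pathways"]) <= flagged

    def test_uniform_fold_gives_null_enrichment(self, rng):
        genes = [f"G{i}" for i in range(500)]
        pws, names = im.generate_pathways(genes, 30, genes[:40], rng, fold=1.0)
        assert names == []
        enr = im.enrich_pathways(set(genes[:40]), pws, genes)
        assert 0.2 < enr["p"].mean() < 0.8

    def test_empty_universe_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            im.generate_pathways([], 5, [], rng)


class TestWholeStudy:
    def test_truth_indexes_existing_entities(self, small_study):
        s = small_study
        assert set(s.truth["effect_parcels"]) <= set(s.parcellation.parcel_ids)
        assert set(s.truth["coupled_genes"]) <= set(s.expression.genes)
        assert set(s.truth["true_dmps"]) <= set(s.methylation.cpg_ids)
        assert set(s.truth["enriched_pathways"]) <= set(s.pathways)

    def test_effect_parcels_contiguous_cluster(self):
        parc = generate_parcellation(100, seed=0)
        eff = default_effect_parcels(parc, 10, 4)
        d = parc.geodesic_distances()[np.ix_(eff, eff)]
        assert d.max() < np.pi / 2  # cluster, not scattered

    def test_byte_identical_on_disk(self, tmp_path):
        cfg = SynthConfig(n_parcels=30, n_genes=50, n_subjects_mdd=15,
                          n_subjects_hc=15, n_cpgs=200, n_pathways=8,
                          n_effect_parcels=4, n_coupled_genes=10,
                          n_true_dmps=5, seed=123)
        for d in ("a", "b"):
            write_study(im.generate_study(cfg), tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name
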