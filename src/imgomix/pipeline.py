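"""End-to-end orchestration: simulate -> gmv -> pls -> dmp -> integrate ->
methexpr, with per-stage seed substreams and a machine-readable run report.

A single root seed fans out through :class:`numpy.random.SeedSequence`
spawns, one per randomised stage, so the same config+seed reproduces
every stage byte-identically regardless of which stages run. Wall-clock
times live under the report's ``timing`` key only, so reports are
comparable after stripping that one key.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import dmp as dmp_mod
from . import gmv as gmv_mod
from . import integration as integ
from . import methexpr as mex
from . import pls as pls_mod
from .config import RunConfig, dump_config
from .datatypes import ParcelMap
from .errors import EmptyFeatureSetError, ImgomixError
from .io import read_study, write_json, write_matrix, write_study
from .synthetic import SynthConfig, generate_study

logger = logging.getLogger("imgomix")

_STAGES = ("simulate", "gmv", "pls", "dmp", "integrate", "methexpr")


class StageError(ImgomixError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _stage_seed(ss: np.random.SeedSequence, index: int) -> int:
    """Deterministic 31-bit seed for stage ``index`` of the root sequence."""
    child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(index,))
    return int(child.generate_state(1, np.uint32)[0] % (2 ** 31))


def run_all(config: RunConfig, out_dir=None) -> dict:
    """Execute the full pipeline; returns the run report (also written to
    ``<out>/report.json``). Stage failures abort with the stage name."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    substreams = {s: _stage_seed(ss, i) for i, s in enumerate(_STAGES)}
    report: dict = {
        "config": dump_config(config),
        "substreams": substreams,
        "stats": {},
        "timing": {},
    }
    t_all = time.perf_counter()

    def _timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                report["timing"][stage] = time.perf_counter() - self.t0
                return False
        return _T()

    stats = report["stats"]
    try:
        with _timed("simulate"):
            study = _stage_simulate(config, substreams["simulate"], out)
    except Exception as e:
        raise StageError("simulate", e) from e

    try:
        with _timed("gmv"):
            region_results, tmap, sig_regions = _stage_gmv(config, study, out, stats)
    except Exception as e:
        raise StageError("gmv", e) from e

    try:
        with _timed("pls"):
            gene_table, pls_pos, pls_neg = _stage_pls(
                config, study, tmap, substreams, out, stats)
    except Exception as e:
        raise StageError("pls", e) from e

    try:
        with _timed("dmp"):
            dmp_results, dmps, dmp_gene_map = _stage_dmp(config, study, out, stats)
    except Exception as e:
        raise StageError("dmp", e) from e

    try:
        with _timed("integrate"):
            integ_out = _stage_integrate(
                config, study, dmp_results, dmps, dmp_gene_map,
                pls_pos, pls_neg, sig_regions, out, stats)
    except Exception as e:
        raise StageError("integrate", e) from e

    try:
        with _timed("methexpr"):
            _stage_methexpr(config, study, integ_out, gene_table, tmap,
                            substreams["methexpr"], out, stats)
    except Exception as e:
        raise StageError("methexpr", e) from e

    report["timing"]["total"] = time.perf_counter() - t_all
    write_json(report, out / "report.json")
    return report


# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, seed: int, out: Path):
    if config.input_dir:
        logger.info("loading study from %s", config.input_dir)
        return read_study(config.input_dir)
    sim = config.simulate.model_dump()
    sim.pop("enabled")
    study = generate_study(SynthConfig(seed=seed, **sim))
    write_study(study, out / "study")
    return study


def _stage_gmv(config: RunConfig, study, out: Path, stats: dict):
    res = gmv_mod.test_regions(study.cohort, config.gmv.covariates,
                               config.gmv.fdr_method)
    tmap = gmv_mod.build_tmap(res, study.parcellation)
    sig = gmv_mod.significant_regions(res, config.gmv.alpha)
    write_matrix(res, out / "region_results.tsv", sep="\t")
    write_matrix(tmap.to_series().rename_axis("parcel_id").to_frame(),
                 out / "tmap.csv")
    stats["gmv"] = {
        "n_regions": int(len(res)),
        "n_significant_regions": len(sig),
        "significant_regions": list(sig),
        "tmap_mean": float(np.mean(tmap.values)),
        "tmap_min": float(np.min(tmap.values)),
    }
    return res, tmap, sig


def _stage_pls(config: RunConfig, study, tmap: ParcelMap, substreams, out: Path,
               stats: dict):
    c = config.pls
    n_comp = min(c.n_components, study.parcellation.n_parcels - 1)
    fit = pls_mod.fit_pls(study.expression, tmap, n_comp)
    r, p = pls_mod.spatial_correlation(fit.pls1_scores, tmap)
    spin = pls_mod.spin_test_pls(study.expression, tmap,
                                 study.parcellation.centroids,
                                 c.n_spins, np.random.default_rng(substreams["pls"]),
                                 statistic=c.spin_statistic)
    gene_table = pls_mod.bootstrap_gene_z(
        study.expression, tmap, c.n_boot,
        np.random.default_rng(substreams["pls"] + 1),
        z_threshold=c.z_threshold, alpha=c.alpha)
    pos, neg = pls_mod.select_pls_genes(gene_table, c.z_threshold, c.alpha)

    write_matrix(gene_table, out / "pls_genes.tsv", sep="\t")
    write_matrix(pd.DataFrame(fit.scores, index=list(tmap.parcel_ids),
                              columns=[f"PLS{i+1}" for i in range(fit.n_components)]
                              ).rename_axis("parcel_id"),
                 out / "pls_scores.csv")
    write_matrix(pd.DataFrame({"permuted": spin.permuted}), out / "spin_null.csv")
    summary = {
        "variance_explained": fit.variance_explained.tolist(),
        "pls1_variance_explained": float(fit.variance_explained[0]),
        "pls1_tmap_r": r, "pls1_tmap_p": p,
        "p_spin": spin.p_spin, "spin_statistic": spin.statistic,
        "n_pls_pos": len(pos), "n_pls_neg": len(neg),
    }
    write_json(summary, out / "pls_summary.json")
    stats["pls"] = summary
    return gene_table, pos, neg


def _stage_dmp(config: RunConfig, study, out: Path, stats: dict):
    c = config.dmp
    res = dmp_mod.fit_cpg_glm(study.methylation, study.cohort, c.covariates,
                              c.use_m_values)
    dmps = dmp_mod.select_dmps(res, c.alpha, c.correction, c.promoter_only)
    gene_map = dmp_mod.dmps_to_genes(dmps)
    write_matrix(res, out / "dmp_results.tsv", sep="\t")
    write_json({g: list(cp) for g, cp in gene_map.items()}, out / "dmp_genes.json")
    stats["dmp"] = {"n_cpgs": int(len(res)), "n_dmps": int(len(dmps)),
                    "n_dmp_genes": len(gene_map)}
    return res, dmps, gene_map


def _stage_integrate(config: RunConfig, study, dmp_results, dmps, dmp_gene_map,
                     pls_pos, pls_neg, sig_regions, out: Path, stats: dict):
    c = config.integrate
    pls_genes = list(pls_pos) + list(pls_neg)
    ov = integ.overlap_genes(pls_genes, dmp_gene_map.keys())
    universe = list(study.expression.genes)
    enr = integ.enrich_pathways(ov.overlap, study.pathways, universe)
    write_matrix(enr, out / "enrichment.tsv", sep="\t")
    write_json({"pls_genes": sorted(ov.pls_genes),
                "dmp_genes": sorted(ov.dmp_genes),
                "overlap": sorted(ov.overlap)}, out / "overlap.json")
    enriched = list(enr.index[enr["q"] < c.enrich_q])
    st = {"n_pls_genes": len(ov.pls_genes), "n_dmp_genes": len(ov.dmp_genes),
          "n_overlap_genes": len(ov.overlap),
          "n_enriched_pathways": len(enriched),
          "enriched_pathways": enriched}
    stats["integrate"] = st

    empty = {"significant_regions": [], "pca": None, "fits": {}, "features": [],
             "top_dmps": pd.DataFrame(columns=["cpg_id", "gene", "region", "weight"])}
    if not sig_regions:
        st["note"] = "no significant GMV regions; PCR skipped"
        return empty
    try:
        feats = integ.select_dmp_features(dmps, ov.overlap, enr, c.enrich_q,
                                          study.pathways)
    except EmptyFeatureSetError as e:
        st["note"] = str(e)
        return empty

    patients = study.cohort.patients()
    feat_beta = study.methylation.beta.loc[patients.subjects.index, feats]
    pca = integ.pca_reduce(feat_beta, c.variance_threshold)
    assoc = integ.region_association(patients.gmv, pca, sig_regions,
                                     c.p_enter, c.p_remove, c.alpha)
    fits = assoc.attrs["fits"]
    sig_assoc = list(assoc.index[assoc["significant"]])

    loocv_rows = []
    for r in sig_assoc:
        preds, rr, pp, n_empty = integ.loocv_validate(
            patients.gmv[r].to_numpy(), feat_beta, c.variance_threshold,
            c.p_enter, c.p_remove, refit_pca=c.loocv_refit_pca, pca=pca)
        loocv_rows.append({"region": r, "loocv_r": rr, "loocv_p": pp,
                           "n_empty_folds": n_empty})
        pd.DataFrame({"observed": patients.gmv[r].to_numpy(),
                      "predicted": preds},
                     index=patients.subjects.index).to_csv(
            out / f"loocv_{r}.csv", float_format="%.12g")
    loocv_df = pd.DataFrame(loocv_rows, columns=["region", "loocv_r",
                                                 "loocv_p", "n_empty_folds"])
    top = integ.top_weight_dmps(pca, {r: fits[r] for r in sig_assoc},
                                study.methylation.annotation, c.weight_threshold)
    clin = integ.clinical_models(patients.subjects, pca.scores,
                                 patients.gmv[sig_regions], c.p_enter, c.p_remove)

    write_matrix(assoc.drop(columns=[], errors="ignore"),
                 out / "pcr_regions.tsv", sep="\t")
    write_matrix(loocv_df.set_index("region") if len(loocv_df) else loocv_df,
                 out / "loocv.tsv", sep="\t")
    write_matrix(top.set_index("cpg_id") if len(top) else top,
                 out / "top_dmps.tsv", sep="\t")

    st.update({
        "n_features": len(feats),
        "n_components": int(pca.k),
        "cumulative_variance": pca.cumulative_variance,
        "n_regions_tested": len(sig_regions),
        "significant_regions": sig_assoc,
        "n_top_dmps": int(len(top)),
        "loocv": loocv_rows,
        "clinical": {name: {"selected": f.selected, "F": f.fvalue,
                            "f_pvalue": f.f_pvalue, "p_model": f.p_model,
                            "significant": bool(f.p_model < c.alpha and f.selected)}
                     for name, f in clin.items()},
    })
    return {"significant_regions": sig_assoc, "pca": pca, "features": feats,
            "fits": {r: fits[r] for r in sig_assoc}, "top_dmps": top}


def _stage_methexpr(config: RunConfig, study, integ_out, gene_table, tmap,
                    seed: int, out: Path, stats: dict):
    c = config.methexpr
    top = integ_out["top_dmps"]
    feats = integ_out.get("features", [])
    results = []
    if len(top) or feats:
        rng = np.random.default_rng(seed)
        patients = study.cohort.patients().subjects.index
        anno = study.methylation.annotation
        expr_genes = set(study.expression.data.columns)
        fallback = pd.DataFrame(
            {"cpg_id": feats,
             "gene": [anno.loc[cp, "gene"] for cp in feats]})
        for region in integ_out["significant_regions"]:
            table = top.loc[top["region"] == region]
            used = "top_weight"
            if len(set(table["gene"]) & expr_genes - {""}) < 3:
                # too few top-weight genes at this scale: fall back to the
                # region's full PCR feature set so the coupling test runs
                table = fallback.assign(region=region)
                used = "all_features"
                logger.info("region %s: top-weight table too small; "
                            "using all %d PCR features", region, len(feats))
            res = mex.analyze_region(region, table, study.methylation,
                                     study.expression, patients,
                                     n_perm=c.n_perm, method=c.method,
                                     tail=c.tail, seed=rng)
            if res is not None:
                results.append({"region": res.region, "n_genes": len(res.genes),
                                "rho": res.rho, "p": res.p,
                                "p_perm": res.p_perm, "gene_set": used})
        top_genes = sorted(set(top["gene"]) - {""})
        z = gene_table["z"]
        classes = {"PLS+": [g for g in top_genes if g in z.index and z[g] > 0],
                   "PLS-": [g for g in top_genes if g in z.index and z[g] < 0]}
        cls = mex.expression_map_vs_tmap(classes, study.expression, tmap)
        write_matrix(cls.set_index("class"), out / "methexpr_classes.tsv", sep="\t")
        stats.setdefault("methexpr", {})["class_correlations"] = \
            cls.to_dict(orient="records")
    df = pd.DataFrame(results, columns=["region", "n_genes", "rho", "p",
                                        "p_perm", "gene_set"])
    write_matrix(df.set_index("region") if len(df) else df,
                 out / "methexpr.tsv", sep="\t")
    stats.setdefault("methexpr", {})["regions"] = results
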