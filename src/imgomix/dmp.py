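"""Epigenome-wide differential methylation.

Per-CpG covariate-adjusted group testing on beta values (the regional GMV
model minus TIV: age, gender, education, medication), DMP selection with a
promoter filter, adjusted delta-beta, and the CpG -> gene roll-up consumed
by the integration stage.

Tests run on the beta scale by default; an M-value mode (logit2 of beta)
is available since beta-scale heteroscedasticity can distort variances at
extreme methylation levels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._glm import listwise_complete, mass_group_ttest
from .datatypes import CPG_COVARIATES, CohortTable, MethylationSet
from .errors import InvalidArgumentError
from .gmv import fdr_adjust

logger = logging.getLogger("imgomix")


def _beta_matrix(meth: MethylationSet, use_m_values: bool) -> np.ndarray:
    B = meth.beta.to_numpy(float)
    if use_m_values:
        Bc = np.clip(B, 1e-6, 1 - 1e-6)
        return np.log2(Bc / (1 - Bc))
    return B


def fit_cpg_glm(meth: MethylationSet, cohort: CohortTable,
                covariates=CPG_COVARIATES, use_m_values: bool = False
                ) -> pd.DataFrame:
    """Per-CpG group t, p, adjusted delta and BH q.

    Returns a frame indexed by cpg_id with columns ``t``, ``p``, ``q``,
    ``delta_beta`` (adjusted MDD-HC difference on the analysis scale),
    ``direction`` ('hyper'/'hypo'), plus the gene and promoter annotation.
    """
    covariates = list(covariates)
    meth = meth.aligned_to_cohort(cohort)
    mask = listwise_complete(cohort.subjects, covariates) if covariates else \
        np.ones(len(cohort.subjects), bool)
    sub = cohort.subjects.loc[mask]
    Y = _beta_matrix(MethylationSet(meth.beta.loc[mask], meth.annotation),
                     use_m_values)
    group = (sub["group"] == "MDD").to_numpy(int)
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise InvalidArgumentError("need at least 2 subjects per group")
    cov = sub[covariates].to_numpy(float) if covariates else None
    res = mass_group_ttest(Y, group, cov, covariates)
    anno = meth.annotation.loc[meth.beta.columns]
    out = pd.DataFrame(
        {"t": res["t"], "p": res["p"], "q": fdr_adjust(res["p"]),
         "delta_beta": res["coef"],
         "direction": np.where(res["coef"] > 0, "hyper", "hypo"),
         "gene": anno["gene"].to_numpy(),
         "promoter_flag": anno["promoter_flag"].to_numpy(bool)},
        index=pd.Index(meth.beta.columns, name="cpg_id"))
    return out


def select_dmps(results: pd.DataFrame, alpha: float = 0.05,
                correction: str = "uncorrected",
                promoter_only: bool = True) -> pd.DataFrame:
    """Rows of ``results`` passing the significance rule.

    ``correction`` is 'uncorrected' (nominal p < alpha; the default, which
    matches the scale of the reported DMP-gene counts) or 'fdr' (q < alpha).
    """
    if correction == "uncorrected":
        keep = results["p"] < alpha
    elif correction == "fdr":
        keep = results["q"] < alpha
    else:
        raise InvalidArgumentError(f"unknown correction {correction!r}")
    if promoter_only:
        keep = keep & results["promoter_flag"]
    logger.info("selected %d DMPs (correction=%s, promoter_only=%s)",
                int(keep.sum()), correction, promoter_only)
    return results.loc[keep]


def compute_delta_beta(meth: MethylationSet, cohort: CohortTable, cpg_ids,
                       covariates=CPG_COVARIATES) -> pd.Series:
    """Covariate-adjusted MDD-HC mean beta difference for selected CpGs."""
    res = fit_cpg_glm(MethylationSet(meth.beta[list(cpg_ids)], meth.annotation),
                      cohort, covariates)
    return res["delta_beta"]


def dmps_to_genes(dmp_results: pd.DataFrame) -> dict:
    """Unique gene symbols with their member DMPs; unannotated CpGs dropped
    (count logged)."""
    anno = dmp_results["gene"].fillna("")
    dropped = int((anno == "").sum())
    if dropped:
        logger.info("dropped %d DMPs without gene annotation", dropped)
    keep = dmp_results.loc[anno != ""]
    out: dict = {}
    for cpg, gene in keep["gene"].items():
        out.setdefault(gene, []).append(cpg)
    return {g: sorted(c) for g, c in sorted(out.items())}
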