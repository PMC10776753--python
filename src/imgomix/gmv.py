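"""Region-wise covariate-adjusted case-control testing of gray-matter volume.

Fits, for every parcel, the linear model ``gmv ~ group + covariates`` and
reports the Wald t for the group indicator, two-sided p, BH-adjusted q and
the direction of the adjusted case-control difference. The resulting
t-map is the response of the downstream spatial PLS stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._glm import listwise_complete, mass_group_ttest
from .datatypes import GMV_COVARIATES, CohortTable, ParcelMap, Parcellation
from .errors import IncompleteMapError, InvalidArgumentError


@dataclass
class RegionTestResult:
    parcel_id: str
    t_stat: float
    p_value: float
    q_value: float
    direction: int  # sign of the adjusted (MDD - HC) difference


def fdr_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (or Benjamini-Yekutieli) step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    meth = {"bh": "fdr_bh", "by": "fdr_by"}.get(method.lower())
    if meth is None:
        raise InvalidArgumentError(f"unknown FDR method {method!r}")
    return multipletests(p, method=meth)[1]


def test_regions(cohort: CohortTable, covariates=GMV_COVARIATES,
                 fdr_method: str = "bh") -> pd.DataFrame:
    """Group GLM t-test for every parcel; returns a frame indexed by parcel.

    Columns: ``t``, ``p``, ``q``, ``coef`` (adjusted MDD-HC difference),
    ``direction``. Subjects with missing covariates are dropped listwise.
    """
    covariates = list(covariates)
    mask = listwise_complete(cohort.subjects, covariates) if covariates else \
        np.ones(len(cohort.subjects), bool)
    sub = cohort.subjects.loc[mask]
    Y = cohort.gmv.loc[mask].to_numpy(float)
    group = (sub["group"] == "MDD").to_numpy(int)
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise InvalidArgumentError("need at least 2 subjects per group")
    cov = sub[covariates].to_numpy(float) if covariates else None
    res = mass_group_ttest(Y, group, cov, covariates)
    q = fdr_adjust(res["p"], fdr_method)
    return pd.DataFrame(
        {"t": res["t"], "p": res["p"], "q": q, "coef": res["coef"],
         "direction": np.sign(res["coef"]).astype(int)},
        index=pd.Index(cohort.parcel_ids, name="parcel_id"))


def fit_region_glm(cohort: CohortTable, parcel_id, covariates=GMV_COVARIATES
                   ) -> RegionTestResult:
    """Single-region convenience wrapper around :func:`test_regions`."""
    res = test_regions(cohort, covariates)
    if parcel_id not in res.index:
        raise InvalidArgumentError(f"unknown parcel {parcel_id!r}")
    row = res.loc[parcel_id]
    return RegionTestResult(parcel_id, float(row["t"]), float(row["p"]),
                            float(row["q"]), int(row["direction"]))


def build_tmap(results: pd.DataFrame, parcellation: Parcellation) -> ParcelMap:
    """Ordered t-statistic map aligned to the parcellation; errors if any
    parcel is missing a result."""
    missing = [p for p in parcellation.parcel_ids if p not in results.index]
    if missing:
        raise IncompleteMapError(f"no test result for parcels {missing[:5]}")
    t = results.loc[list(parcellation.parcel_ids), "t"].to_numpy(float)
    return ParcelMap(parcellation.parcel_ids, t, name="t")


def significant_regions(results: pd.DataFrame, alpha: float = 0.05) -> list:
    """Parcels whose BH-adjusted q is below ``alpha``."""
    return list(results.index[results["q"] < alpha])
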