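"""Integration of PLS genes with DMP genes and principal component regression.

Chain: overlap the PLS1+/- gene lists with the DMP genes; hypergeometric
pathway enrichment of the overlap; select as features the DMPs whose
genes sit both in the overlap pool and in an enriched pathway; PCA the
patient x feature beta matrix down to the top components reaching the
cumulative-variance threshold (80% by default); stepwise multiple linear
regression (SMLR) of each abnormal region's GMV on the component scores,
with FDR across regions; leave-one-out cross-validation of the whole
PCA+SMLR chain; extraction of top-weight DMPs per significant region;
and SMLR models of the clinical scores (HAMD, HAMA) on the same feature
blocks.

Region-level inference
----------------------
Classical stepwise entry (best candidate enters when its partial-F p is
below ``p_enter``) is used to build the model, but the final model's F
p-value is not a valid test after selection: with 25 candidate
components it would flag the majority of pure-noise regions. The
region-level p reported for FDR is therefore the selection-adjusted
first-entry p, a Sidak correction of the best single-component p over
the k candidates offered (exact under orthogonal component scores).
Both p-values are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateResponseError,
    EmptyFeatureSetError,
    InvalidArgumentError,
)
from .gmv import fdr_adjust

logger = logging.getLogger("imgomix")


# ---------------------------------------------------------------------------
# overlap and enrichment

@dataclass
class OverlapResult:
    pls_genes: set
    dmp_genes: set
    overlap: set
    enrichment: pd.DataFrame | None = None


def overlap_genes(pls_genes, dmp_genes) -> OverlapResult:
    """Exact intersection of the PLS gene list and the DMP gene set."""
    a, b = set(pls_genes), set(dmp_genes)
    return OverlapResult(a, b, a & b)


def enrich_pathways(gene_set, pathways: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric upper-tail enrichment per pathway, BH q.

    Pathway members outside the universe are dropped with a log entry.
    Columns: k (overlap in set), K (pathway size), n (set size), N
    (universe size), p, q; sorted ascending by p.
    """
    universe = set(universe)
    if not pathways:
        raise InvalidArgumentError("no pathways supplied")
    gene_set = set(gene_set) & universe
    N, n = len(universe), len(gene_set)
    rows = []
    for name, members in pathways.items():
        inside = set(members) & universe
        dropped = len(set(members)) - len(inside)
        if dropped:
            logger.info("pathway %s: dropped %d members outside universe",
                        name, dropped)
        K = len(inside)
        k = len(inside & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["pathway", "k", "K", "n", "N", "p"]
                      ).set_index("pathway")
    df["q"] = fdr_adjust(df["p"].to_numpy())
    return df.sort_values("p")


def select_dmp_features(dmp_results: pd.DataFrame, overlap: set,
                        enrichment: pd.DataFrame, q_threshold: float = 0.05,
                        pathways: dict | None = None) -> list:
    """DMPs whose gene is in the overlap pool AND in >=1 enriched pathway.

    Returns cpg_ids in deterministic (sorted) order; raises
    :class:`EmptyFeatureSetError` when nothing survives, which halts the
    pipeline with an explanatory message.
    """
    enriched = enrichment.index[enrichment["q"] < q_threshold]
    enriched_genes = set()
    for name in enriched:
        enriched_genes |= set((pathways or {}).get(name, []))
    pool = set(overlap) & enriched_genes
    feats = sorted(dmp_results.index[dmp_results["gene"].isin(pool)])
    if not feats:
        raise EmptyFeatureSetError(
            "no DMP features: overlap genes and enriched pathways do not "
            "intersect (nothing for the PCR stage to model)")
    return feats


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAReduction:
    scores: pd.DataFrame      # subjects x components
    loadings: pd.DataFrame    # features x components
    explained_ratio: np.ndarray  # all ratios, full rank
    k: int
    mean: np.ndarray
    scale: np.ndarray | None = None

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_ratio[: self.k].sum())

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, float) - self.mean
        if self.scale is not None:
            Xc = Xc / self.scale
        return Xc @ self.loadings.to_numpy()


def pca_reduce(features: pd.DataFrame, variance_threshold: float = 0.80,
               scale: bool = False) -> PCAReduction:
    """PCA of the (centered) patient x feature matrix, keeping the smallest
    k whose cumulative explained variance reaches the threshold.

    Loadings are orthonormal right singular vectors, sign-fixed so each
    loading vector's largest-|value| element is positive (reproducible
    component orientation).
    """
    if not 0 < variance_threshold <= 1:
        raise InvalidArgumentError("variance_threshold must be in (0, 1]")
    X = features.to_numpy(float)
    if X.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 subjects for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    sc = None
    if scale:
        sc = Xc.std(axis=0, ddof=0)
        sc[sc == 0] = 1.0
        Xc = Xc / sc
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0)
    rank = int((s > tol).sum())
    s, Vt, U = s[:rank], Vt[:rank], U[:, :rank]
    var = s ** 2
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, rank)
    flip = np.sign(Vt[np.arange(rank), np.argmax(np.abs(Vt), axis=1)])
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    comp_names = [f"C{i + 1}" for i in range(rank)]
    scores = pd.DataFrame(U * s, index=features.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=features.columns, columns=comp_names)
    return PCAReduction(scores.iloc[:, :k], loadings.iloc[:, :k], ratio, k,
                        mean, sc)


# ---------------------------------------------------------------------------
# stepwise regression

@dataclass
class SMLRFit:
    selected: list
    coef: pd.Series            # includes 'intercept'
    std_coef: pd.Series        # standardised coefficients of selected terms
    fvalue: float
    f_pvalue: float            # naive final-model F p (post-selection)
    p_model: float             # selection-adjusted region/model p (for FDR)
    r_squared: float
    n: int
    n_offered: int
    q_value: float = np.nan

    @property
    def is_null(self) -> bool:
        return len(self.selected) == 0


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS with intercept; returns coef, t p-values per column, F, F-p, R2."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    df_resid = n - D.shape[1]
    sse = resid @ resid
    sst = ((y - y.mean()) ** 2).sum()
    if df_resid <= 0 or sst == 0:
        return coef, np.full(D.shape[1], np.nan), np.nan, np.nan, np.nan
    sigma2 = sse / df_resid
    XtX_inv = np.linalg.inv(D.T @ D)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    k = X.shape[1]
    if k == 0:
        return coef, pvals, np.nan, np.nan, 0.0
    r2 = 1 - sse / sst
    F = (r2 / k) / ((1 - r2) / df_resid)
    f_p = float(stats.f.sf(F, k, df_resid))
    return coef, pvals, float(F), f_p, float(r2)


def _candidate_pvalues(y, scores: pd.DataFrame, current: list) -> pd.Series:
    """Partial-F (equivalently t) p of each remaining candidate when added
    to the current model."""
    out = {}
    cur = scores[current].to_numpy() if current else np.empty((len(y), 0))
    for c in scores.columns:
        if c in current:
            continue
        _, pvals, *_ = _ols(y, np.column_stack([cur, scores[c].to_numpy()]))
        out[c] = pvals[-1]
    return pd.Series(out, dtype=float)


def smlr_fit(y, scores: pd.DataFrame, p_enter: float = 0.05,
             p_remove: float = 0.10, max_iter: int = 100) -> SMLRFit:
    """Forward-entry / backward-removal stepwise regression on partial-F p.

    ``p_model`` is the Sidak-adjusted best first-step p over the offered
    candidates: 1 - (1 - min_j p_j)^k. It is the model-level p used for
    FDR across regions (see module docstring); the naive final-model F p
    is reported alongside.
    """
    y = np.asarray(y, float)
    if y.std(ddof=0) == 0:
        raise DegenerateResponseError("response is constant")
    k_offered = scores.shape[1]
    first = _candidate_pvalues(y, scores, [])
    p_model = float(1.0 - (1.0 - np.nanmin(first)) ** k_offered) if k_offered else 1.0

    selected: list = []
    for _ in range(max_iter):
        changed = False
        cand = _candidate_pvalues(y, scores, selected)
        if len(cand) and np.nanmin(cand) < p_enter:
            selected.append(cand.idxmin())
            changed = True
        if selected:
            _, pvals, *_ = _ols(y, scores[selected].to_numpy())
            included = pd.Series(pvals[1:], index=selected)
            worst = included.idxmax()
            if included[worst] > p_remove:
                selected.remove(worst)
                changed = True
        if not changed:
            break

    coef_arr, _, F, f_p, r2 = _ols(y, scores[selected].to_numpy()
                                   if selected else np.empty((len(y), 0)))
    names = ["intercept"] + selected
    coef = pd.Series(coef_arr, index=names)
    sy = y.std(ddof=0)
    std_coef = pd.Series(
        {c: coef[c] * scores[c].std(ddof=0) / sy for c in selected},
        dtype=float)
    return SMLRFit(selected, coef, std_coef, F, f_p, p_model, r2,
                   n=len(y), n_offered=k_offered)


def smlr_predict(fit: SMLRFit, scores: pd.DataFrame) -> np.ndarray:
    X = scores[fit.selected].to_numpy() if fit.selected else \
        np.empty((len(scores), 0))
    return np.column_stack([np.ones(len(scores)), X]) @ fit.coef.to_numpy()


def region_association(gmv_patients: pd.DataFrame, pca: PCAReduction,
                       regions, p_enter: float = 0.05, p_remove: float = 0.10,
                       alpha: float = 0.05) -> pd.DataFrame:
    """SMLR of each region's patient GMV on the component scores, with BH
    FDR of the selection-adjusted model p across regions.

    Returns a frame indexed by region with the fit object and summary
    columns; ``significant`` means q < alpha and a non-empty model.
    """
    fits = {}
    for r in regions:
        fits[r] = smlr_fit(gmv_patients[r].to_numpy(), pca.scores,
                           p_enter, p_remove)
    p = np.array([fits[r].p_model for r in regions])
    q = fdr_adjust(p)
    rows = []
    for i, r in enumerate(regions):
        f = fits[r]
        f.q_value = float(q[i])
        rows.append({"region": r, "n_selected": len(f.selected),
                     "selected": ",".join(f.selected),
                     "F": f.fvalue, "f_pvalue": f.f_pvalue,
                     "p_model": f.p_model, "q": f.q_value,
                     "r_squared": f.r_squared,
                     "significant": bool(f.q_value < alpha and f.selected)})
    df = pd.DataFrame(rows).set_index("region")
    df.attrs["fits"] = fits
    return df


# ---------------------------------------------------------------------------
# LOOCV

def loocv_validate(y, features: pd.DataFrame, variance_threshold: float = 0.80,
                   p_enter: float = 0.05, p_remove: float = 0.10,
                   refit_pca: bool = True, pca: PCAReduction | None = None):
    """Leave-one-out predictions of ``y`` from the PCA+SMLR chain.

    By default the entire chain (PCA included) is refit on each training
    fold, so the held-out subject never leaks into the component space; a
    fixed-components mode (``refit_pca=False`` with a supplied ``pca``)
    mirrors the cheaper literal protocol. Folds whose stepwise selection
    is empty predict the training mean (count logged).

    Returns (predictions, pearson_r, p_value, n_empty_folds).
    """
    y = np.asarray(y, float)
    n = len(y)
    if n < 10:
        raise InvalidArgumentError("LOOCV needs at least 10 subjects")
    preds = np.empty(n)
    n_empty = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        train_feat = features.iloc[mask]
        if refit_pca:
            fold_pca = pca_reduce(train_feat, variance_threshold)
        else:
            if pca is None:
                raise InvalidArgumentError("fixed-components mode needs pca")
            fold_pca = pca
        train_scores = pd.DataFrame(
            fold_pca.transform(train_feat.to_numpy()),
            index=train_feat.index, columns=fold_pca.scores.columns)
        fit = smlr_fit(y[mask], train_scores, p_enter, p_remove)
        if fit.is_null:
            n_empty += 1
            preds[i] = y[mask].mean()
        else:
            test_scores = pd.DataFrame(
                fold_pca.transform(features.iloc[[i]].to_numpy()),
                columns=fold_pca.scores.columns)
            preds[i] = smlr_predict(fit, test_scores)[0]
    if n_empty:
        logger.info("LOOCV: %d folds had empty selection (training mean used)",
                    n_empty)
    if np.std(preds) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(y, preds)
    return preds, float(r), float(p), n_empty


# ---------------------------------------------------------------------------
# top-weight DMPs and clinical models

def top_weight_dmps(pca: PCAReduction, region_fits: dict, annotation,
                    weight_threshold: float = 0.2) -> pd.DataFrame:
    """Composite DMP weight per significant region.

    weight(dmp, region) = sum over the region's selected components of
    |loading(dmp, comp) * standardised coefficient(comp)|; rows above the
    threshold are reported with their gene, sorted descending.
    """
    rows = []
    for region, fit in region_fits.items():
        if not fit.selected:
            continue
        L = pca.loadings[fit.selected].to_numpy()
        w = np.abs(L * fit.std_coef[fit.selected].to_numpy()[None, :]).sum(axis=1)
        for cpg, wv in zip(pca.loadings.index, w):
            if wv > weight_threshold:
                gene = annotation.loc[cpg, "gene"] if cpg in annotation.index else ""
                rows.append({"cpg_id": cpg, "gene": gene, "region": region,
                             "weight": float(wv)})
    df = pd.DataFrame(rows, columns=["cpg_id", "gene", "region", "weight"])
    return df.sort_values("weight", ascending=False).reset_index(drop=True)


def clinical_models(cohort_patients: pd.DataFrame, scores: pd.DataFrame,
                    gmv_regions: pd.DataFrame, p_enter: float = 0.05,
                    p_remove: float = 0.10) -> dict:
    """SMLR of HAMD and HAMA on the DMP components and on regional GMV.

    Four fits: hamd~components, hamd~gmv, hama~components, hama~gmv.
    """
    out = {}
    for score_name in ("hamd", "hama"):
        y = cohort_patients[score_name].to_numpy(float)
        out[f"{score_name}~components"] = smlr_fit(y, scores, p_enter, p_remove)
        out[f"{score_name}~gmv"] = smlr_fit(y, gmv_regions, p_enter, p_remove)
    return out
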