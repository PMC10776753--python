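"""Spatial PLS of a case-control t-map on regional gene expression.

The first latent component (PLS1) is the gene-weight axis whose regional
score map most covaries with the GMV t-map. Its significance against
spatial autocorrelation is assessed with a spin permutation test (random
3-D rotations of the spherical parcel centroids, values pulled from the
nearest original centroid), and per-gene weights are normalised to
Z-scores by bootstrap resampling of parcels. Genes with Z above / below
+-z_threshold at FDR alpha form the PLS1+ / PLS1- lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .datatypes import ExpressionMatrix, ParcelMap
from .errors import (
    DegenerateResponseError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from .gmv import fdr_adjust

logger = logging.getLogger("imgomix")


@dataclass
class PLSResult:
    n_components: int
    genes: list
    parcel_ids: tuple
    weights: np.ndarray            # (genes, components)
    scores: np.ndarray             # (parcels, components)
    variance_explained: np.ndarray  # per-component R^2 increment of y
    pls1_scores: ParcelMap = None
    gene_table: pd.DataFrame | None = None

    @property
    def pls1_weights(self) -> pd.Series:
        return pd.Series(self.weights[:, 0], index=self.genes, name="w")


@dataclass
class SpinTestResult:
    statistic: str
    observed: float
    permuted: np.ndarray
    n_spins: int
    p_spin: float = field(init=False)

    def __post_init__(self):
        exceed = int(np.sum(self.permuted >= self.observed))
        self.p_spin = (1.0 + exceed) / (1.0 + self.n_spins)


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    n_const = int((sd == 0).sum())
    if n_const:
        logger.info("zeroing %d constant expression columns", n_const)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _standardize_y(y: np.ndarray) -> np.ndarray:
    sd = y.std(ddof=0)
    if sd == 0:
        raise DegenerateResponseError("response map is constant")
    return (y - y.mean()) / sd


def _pls1_weight(Xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """First PLS weight vector for a univariate response: X'y normalised."""
    w = Xs.T @ ys
    n = np.linalg.norm(w)
    if n == 0:
        raise DegenerateResponseError("X'y is zero; no covariance to model")
    return w / n


def _r_squared_on_scores(ys: np.ndarray, scores: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(
        np.column_stack([np.ones(len(ys)), scores]), ys, rcond=None)
    resid = ys - np.column_stack([np.ones(len(ys)), scores]) @ coef
    return 1.0 - (resid @ resid) / (ys @ ys)


def fit_pls(X: ExpressionMatrix, y: ParcelMap, n_components: int = 15) -> PLSResult:
    """PLS regression of the standardised t-map on column-standardised
    expression. ``variance_explained[c]`` is the R^2 increment of the
    response when component c+1 joins the score regression; the PLS1 sign
    is fixed so corr(pls1_scores, y) >= 0."""
    Xv = X.values_for(y.parcel_ids)
    n_parcels = Xv.shape[0]
    if n_components < 1 or n_components > n_parcels - 1:
        raise InvalidArgumentError(
            f"n_components must be in [1, {n_parcels - 1}], got {n_components}")
    Xs = _standardize_columns(Xv)
    ys = _standardize_y(y.values)

    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(Xs, ys)
    W = model.x_weights_.copy()
    T = model.x_scores_.copy()

    if np.corrcoef(T[:, 0], ys)[0, 1] < 0:
        W[:, 0] *= -1.0
        T[:, 0] *= -1.0

    cum = np.array([_r_squared_on_scores(ys, T[:, : c + 1])
                    for c in range(n_components)])
    varexp = np.diff(np.concatenate([[0.0], cum]))

    return PLSResult(
        n_components=n_components, genes=list(X.genes),
        parcel_ids=tuple(y.parcel_ids), weights=W, scores=T,
        variance_explained=varexp,
        pls1_scores=ParcelMap(y.parcel_ids, T[:, 0], name="pls1_score"))


def pls1_variance_explained(Xs: np.ndarray, ys: np.ndarray) -> float:
    """R^2 of the (standardised) response on the first PLS score; equals the
    squared Pearson correlation between the PLS1 score map and y."""
    t = Xs @ _pls1_weight(Xs, ys)
    r = np.corrcoef(t, ys)[0, 1]
    return float(r * r)


def spatial_correlation(a, b):
    """Pearson r and two-sided p between two parcel maps."""
    av = np.asarray(a.values if isinstance(a, ParcelMap) else a, float)
    bv = np.asarray(b.values if isinstance(b, ParcelMap) else b, float)
    if av.shape != bv.shape or av.size < 3:
        raise InvalidArgumentError("maps must have equal length >= 3")
    if av.std(ddof=0) == 0 or bv.std(ddof=0) == 0:
        raise UndefinedCorrelationError("zero-variance map")
    r, p = stats.pearsonr(av, bv)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# spin permutation

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation: QR of a Gaussian 3x3 with sign fix, det forced +1."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1.0
    return q


def spin_assignment(centroids: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Index of the nearest *original* centroid for each rotated centroid.

    Parcel i's permuted value is ``y[assignment[i]]``; the map is
    many-to-one in general. The identity rotation returns 0..n-1.
    """
    rotated = centroids @ rotation.T
    return np.argmax(rotated @ centroids.T, axis=1)


def spin_permutation_test(statistic_fn, y: ParcelMap, centroids: np.ndarray,
                          n_spins: int = 1000, seed=0,
                          statistic_name: str = "statistic") -> SpinTestResult:
    """Generic spin test: ``statistic_fn(y_values)`` is recomputed on each
    rotated reassignment of the map; p is the add-one upper-tail estimate."""
    centroids = np.asarray(centroids, float)
    if not np.allclose(np.linalg.norm(centroids, axis=1), 1.0, atol=1e-6):
        raise InvalidArgumentError("centroids must be unit-norm")
    if n_spins < 100:
        raise InvalidArgumentError("n_spins must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = float(statistic_fn(y.values))
    permuted = np.empty(n_spins)
    for s in range(n_spins):
        idx = spin_assignment(centroids, random_rotation(rng))
        permuted[s] = statistic_fn(y.values[idx])
    return SpinTestResult(statistic_name, observed, permuted, n_spins)


def spin_test_pls(X: ExpressionMatrix, y: ParcelMap, centroids, n_spins: int = 1000,
                  seed=0, statistic: str = "varexp") -> SpinTestResult:
    """Spin test of the PLS1 association between expression and the t-map.

    ``statistic`` is 'varexp' (variance explained by PLS1; the quantity the
    reported Pspin attaches to) or 'correlation' (Pearson r between the
    PLS1 score map and the t-map).
    """
    Xs = _standardize_columns(X.values_for(y.parcel_ids))

    if statistic == "varexp":
        def fn(yv):
            return pls1_variance_explained(Xs, _standardize_y(yv))
    elif statistic == "correlation":
        def fn(yv):
            ys = _standardize_y(yv)
            t = Xs @ _pls1_weight(Xs, ys)
            return np.corrcoef(t, ys)[0, 1]
    else:
        raise InvalidArgumentError(f"unknown spin statistic {statistic!r}")
    return spin_permutation_test(fn, y, centroids, n_spins, seed,
                                 statistic_name=f"pls1_{statistic}")


# ---------------------------------------------------------------------------
# bootstrap gene Z

def bootstrap_gene_z(X: ExpressionMatrix, y: ParcelMap, n_boot: int = 1000,
                     seed=0, z_threshold: float = 3.0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Bootstrap-normalised PLS1 gene weights.

    Parcels are resampled with replacement; PLS1 is refit on each
    resample; each bootstrap weight vector is sign-aligned to the original
    (flipped when its correlation with the original is negative). Z is the
    original weight over the bootstrap SD, p the two-sided normal tail, q
    BH-adjusted; ``sign_class`` applies the |Z| > z_threshold & q < alpha
    partition into 'PLS1+' / 'PLS1-' / 'none'.

    Weights are kept on the covariance scale (X'y / n; the PLS1 direction
    up to a positive factor) rather than unit-normalised per fit: the
    vector norm of a resampled fit is systematically inflated by duplicated
    parcels (E[multiplicity^2] = 2 - 1/n), and dividing by it would shrink
    the bootstrap SD by ~sqrt(2), mis-calibrating Z for null genes.
    """
    if n_boot < 200:
        raise InvalidArgumentError("n_boot must be >= 200")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xs = _standardize_columns(X.values_for(y.parcel_ids))
    ys = _standardize_y(y.values)
    n = len(ys)
    w0 = Xs.T @ ys / n  # covariance-scale PLS1 weight

    Wb = np.empty((n_boot, len(w0)))
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        yb = ys[idx]
        if yb.std(ddof=0) == 0:
            redraws += 1
            continue
        acc = np.zeros(n)
        np.add.at(acc, idx, yb)
        wb = Xs.T @ acc / n
        if wb @ w0 < 0:
            wb = -wb
        Wb[b] = wb
        b += 1
    if redraws:
        logger.info("redrew %d degenerate bootstrap resamples", redraws)

    se = Wb.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, w0 / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = fdr_adjust(np.nan_to_num(p, nan=1.0))
    table = pd.DataFrame(
        {"weight": w0, "se": se, "z": z, "p": p, "q": q},
        index=pd.Index(X.genes, name="gene"))
    table["sign_class"] = np.select(
        [(table["z"] > z_threshold) & (table["q"] < alpha),
         (table["z"] < -z_threshold) & (table["q"] < alpha)],
        ["PLS1+", "PLS1-"], default="none")
    return table


def select_pls_genes(gene_table: pd.DataFrame, z_threshold: float = 3.0,
                     alpha: float = 0.05):
    """(PLS1+, PLS1-) gene lists, each sorted by |Z| descending."""
    pos = gene_table.loc[(gene_table["z"] > z_threshold) & (gene_table["q"] < alpha)]
    neg = gene_table.loc[(gene_table["z"] < -z_threshold) & (gene_table["q"] < alpha)]
    order = lambda df: list(df.reindex(df["z"].abs().sort_values(ascending=False).index).index)
    return order(pos), order(neg)
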