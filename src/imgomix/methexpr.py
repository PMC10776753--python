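"""Methylation-expression coupling at the gene level.

For a GMV-changed region, the top-weight DMP genes give two paired
vectors across genes: mean methylation beta (patient average over each
gene's top DMPs) and that gene's regional expression. Their Spearman
correlation is tested against a permutation null built by shuffling the
gene pairing (5,000 permutations by default), with a one-way cumulative
p in the direction of the observed sign — the reporting convention used
with this design; note that choosing the tail from the observed sign is
anti-conservative under the null, so fixed tails are also supported.

Separately, the mean expression maps of the top-DMP genes, split by PLS
weight sign, are correlated with the GMV t-map across parcels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, MethylationSet, ParcelMap
from .errors import InvalidArgumentError, UndefinedCorrelationError
from .pls import spatial_correlation

logger = logging.getLogger("imgomix")


@dataclass
class MethExprResult:
    region: str
    genes: list
    gene_betas: pd.Series
    gene_expression: pd.Series
    method: str
    rho: float
    p: float
    n_permutations: int
    p_perm: float


def gene_level_methylation(top_dmps: pd.DataFrame, meth: MethylationSet,
                           subjects) -> pd.Series:
    """Per-gene mean beta: average over the gene's top DMPs of the
    subject-mean beta. Genes with no surviving DMP are dropped (logged)."""
    missing = [c for c in top_dmps["cpg_id"] if c not in meth.beta.columns]
    if missing:
        raise InvalidArgumentError(f"top DMPs missing from beta matrix: {missing[:3]}")
    beta = meth.beta.loc[list(subjects)]
    out, dropped = {}, 0
    for gene, grp in top_dmps.groupby("gene"):
        if not gene:
            dropped += 1
            continue
        cpgs = sorted(set(grp["cpg_id"]))
        out[gene] = float(beta[cpgs].mean(axis=0).mean())
    if dropped:
        logger.info("dropped %d unannotated top-DMP entries", dropped)
    return pd.Series(out, dtype=float).sort_index()


def meth_expr_correlation(gene_betas: pd.Series, regional_expression: pd.Series,
                          method: str = "spearman"):
    """Correlation across genes between methylation status and regional
    expression; average-rank ties for Spearman."""
    common = gene_betas.index.intersection(regional_expression.index)
    if len(common) < 3:
        raise InvalidArgumentError("need >= 3 paired genes")
    x = gene_betas.loc[common].to_numpy(float)
    y = regional_expression.loc[common].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("constant vector")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return float(rho), float(p)


def permutation_test_correlation(gene_betas, regional_expression,
                                 n_perm: int = 5000, tail: str = "auto",
                                 seed=0, method: str = "spearman") -> float:
    """Permutation p for the gene-level correlation.

    The gene pairing is permuted uniformly; ``tail`` is 'left', 'right',
    'two', or 'auto' (one-way cumulative probability in the direction of
    the observed sign). Add-one estimator throughout.
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be >= 100")
    x = np.asarray(gene_betas, float)
    y = np.asarray(regional_expression, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)

    def corr(a, b):
        return np.corrcoef(a, b)[0, 1]

    obs = corr(x, y)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = corr(x, rng.permutation(y))

    if tail == "auto":
        tail = "right" if obs >= 0 else "left"
    if tail == "right":
        p = (1 + np.sum(perm >= obs)) / (1 + n_perm)
    elif tail == "left":
        p = (1 + np.sum(perm <= obs)) / (1 + n_perm)
    elif tail == "two":
        p = (1 + np.sum(np.abs(perm) >= abs(obs))) / (1 + n_perm)
    else:
        raise InvalidArgumentError(f"unknown tail {tail!r}")
    return float(p)


def analyze_region(region: str, top_dmps: pd.DataFrame, meth: MethylationSet,
                   expression: ExpressionMatrix, subjects, n_perm: int = 5000,
                   method: str = "spearman", tail: str = "auto",
                   seed=0) -> MethExprResult | None:
    """Full gene-level coupling test for one region; None when fewer than
    three top-DMP genes have expression data (logged)."""
    sub = top_dmps.loc[top_dmps["region"] == region]
    betas = gene_level_methylation(sub, meth, subjects)
    genes = [g for g in betas.index if g in expression.data.columns]
    if len(genes) < 3:
        logger.info("region %s: only %d genes with expression; skipping",
                    region, len(genes))
        return None
    expr = expression.data.loc[region, genes] if region in expression.data.index \
        else None
    if expr is None:
        raise InvalidArgumentError(f"region {region!r} missing from expression")
    betas = betas.loc[genes]
    rho, p = meth_expr_correlation(betas, expr, method)
    p_perm = permutation_test_correlation(betas.to_numpy(), expr.to_numpy(),
                                          n_perm, tail, seed, method)
    return MethExprResult(region, genes, betas, expr, method, rho, p,
                          n_perm, p_perm)


def expression_map_vs_tmap(genes_by_class: dict, expression: ExpressionMatrix,
                           tmap: ParcelMap) -> pd.DataFrame:
    """Correlate each class's mean expression map with the t-map.

    ``genes_by_class`` maps a label (e.g. 'PLS+') to a gene list; empty
    classes are skipped with a log entry. A pooled gene x parcel
    long-format correlation is included under label 'pooled'.
    """
    rows = []
    pooled_x, pooled_y = [], []
    for label, genes in genes_by_class.items():
        genes = [g for g in genes if g in expression.data.columns]
        if not genes:
            logger.info("class %s empty; skipped", label)
            continue
        maps = expression.data.loc[list(tmap.parcel_ids), genes]
        mean_map = maps.mean(axis=1).to_numpy()
        r, p = spatial_correlation(mean_map, tmap.values)
        rows.append({"class": label, "n_genes": len(genes), "r": r, "p": p})
        pooled_x.append(maps.to_numpy().ravel(order="F"))
        pooled_y.append(np.tile(tmap.values, len(genes)))
    if pooled_x:
        r, p = spatial_correlation(np.concatenate(pooled_x), np.concatenate(pooled_y))
        rows.append({"class": "pooled", "n_genes": sum(r_["n_genes"] for r_ in rows),
                     "r": r, "p": p})
    return pd.DataFrame(rows, columns=["class", "n_genes", "r", "p"])
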