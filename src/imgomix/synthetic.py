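"""Planted-truth synthetic multi-omics study generator.

Generates a complete synthetic study — spherical parcellation, spatially
autocorrelated regional gene expression, a two-group GMV cohort with
covariates and clinical scores, a subject x CpG methylation set with a
manifest-style annotation, and GMT pathways — with known planted effects:

* a group GMV deficit at a chosen set of parcels,
* a subset of genes whose expression maps are spatially coupled to the
  deficit pattern,
* promoter DMPs planted in those coupled genes,
* a subject-level latent factor tying methylation at the true DMPs to
  GMV at the deficit parcels (the principal-component-regression signal),
* pathways enriched for the true-DMP genes.

The ``truth`` record of the resulting :class:`SyntheticStudy` is the
acceptance surface: every downstream stage is judged by how well it
recovers these planted entities.

All randomness flows from ``SynthConfig.seed`` through
:class:`numpy.random.SeedSequence` substreams, so identical configs give
byte-identical studies on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import (
    CohortTable,
    ExpressionMatrix,
    MethylationSet,
    ParcelMap,
    Parcellation,
)
from .errors import InvalidArgumentError, NumericalFailureError

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SynthConfig:
    """Study-design knobs for the synthetic generator.

    Defaults are the reduced desk scale the test-suite runs at: 60+60
    subjects, 180 parcels, 2,000 genes, 20,000 CpGs. ``paper_scale()``
    returns the full-size configuration (10,027 genes, 269+416 subjects).
    """

    n_parcels: int = 180
    n_genes: int = 2000
    n_subjects_mdd: int = 60
    n_subjects_hc: int = 60
    n_cpgs: int = 20000
    n_pathways: int = 50
    effect_parcels: list | None = None  # parcel indices; None -> contiguous cluster
    n_effect_parcels: int = 15
    gmv_effect_size: float = 0.8  # Cohen's d of the planted deficit
    n_coupled_genes: int = 100
    coupling_r: float = 0.6  # spatial correlation of coupled genes with the deficit map
    n_true_dmps: int = 50
    dmp_delta_beta: float = 0.05  # |group difference| on the beta scale
    smoothness_kappa: float = 0.5  # exponential-kernel length scale (radians)
    pcr_signal_r: float = 0.6  # latent-to-GMV correlation at effect parcels
    clinical_signal_r: float = 0.6  # latent-to-HAMD correlation in patients
    n_enriched_pathways: int = 5
    pathway_fold: float = 10.0
    pathway_size: int = 40
    gmv_noise_sd: float = 0.05
    meth_logit_noise_sd: float = 0.12
    meth_latent_loading: float = 0.10
    seed: int = 0

    def __post_init__(self):
        counts = dict(
            n_parcels=self.n_parcels, n_genes=self.n_genes,
            n_subjects_mdd=self.n_subjects_mdd, n_subjects_hc=self.n_subjects_hc,
            n_cpgs=self.n_cpgs, n_pathways=self.n_pathways,
            n_true_dmps=self.n_true_dmps, n_coupled_genes=self.n_coupled_genes,
        )
        for name, v in counts.items():
            if int(v) <= 0:
                raise InvalidArgumentError(f"{name} must be positive, got {v}")
        if not np.isfinite(self.gmv_effect_size) or not np.isfinite(self.dmp_delta_beta):
            raise InvalidArgumentError("effect sizes must be finite")
        if not 0 <= abs(self.coupling_r) < 1:
            raise InvalidArgumentError("coupling_r must satisfy |r| < 1")
        if not abs(self.pcr_signal_r) < 1:
            raise InvalidArgumentError("pcr_signal_r must satisfy |r| < 1")
        if self.n_coupled_genes > self.n_genes:
            raise InvalidArgumentError("n_coupled_genes cannot exceed n_genes")
        if self.n_true_dmps > self.n_cpgs:
            raise InvalidArgumentError("n_true_dmps cannot exceed n_cpgs")
        if self.smoothness_kappa <= 0:
            raise InvalidArgumentError("smoothness_kappa must be > 0")
        if self.effect_parcels is not None:
            ep = [int(i) for i in self.effect_parcels]
            if any(i < 0 or i >= self.n_parcels for i in ep):
                raise InvalidArgumentError("effect_parcels out of range")
            self.effect_parcels = ep

    @classmethod
    def paper_scale(cls, **overrides) -> "SynthConfig":
        """Full-cohort scale (269 MDD / 416 HC, 10,027 genes)."""
        base = dict(n_parcels=180, n_genes=10027, n_subjects_mdd=269,
                    n_subjects_hc=416, n_cpgs=20000)
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticStudy:
    parcellation: Parcellation
    expression: ExpressionMatrix
    cohort: CohortTable
    methylation: MethylationSet
    pathways: dict
    truth: dict
    config: SynthConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# spatial building blocks

def generate_parcellation(n_parcels: int, seed: int) -> Parcellation:
    """Well-separated unit-sphere centroids (rotated Fibonacci lattice).

    The lattice gives deterministic, pairwise-distinct, evenly spaced
    points; the seed only sets a global random rotation so different
    seeds give different (but equally regular) parcellations.
    """
    if n_parcels < 4:
        raise InvalidArgumentError("n_parcels must be >= 4")
    i = np.arange(n_parcels)
    z = 1.0 - 2.0 * (i + 0.5) / n_parcels
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = _GOLDEN_ANGLE * i
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    pts = pts @ rot.T
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    ids = tuple(f"P{k:03d}" for k in range(n_parcels))
    return Parcellation(ids, pts)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation in SO(3): QR of a Gaussian matrix, sign-fixed."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1.0
    return q


def exponential_kernel_cholesky(centroids: np.ndarray, kappa: float,
                                jitter: float = 1e-10) -> np.ndarray:
    """Cholesky factor of exp(-d/kappa) on geodesic distance, with jitter."""
    if kappa <= 0:
        raise InvalidArgumentError("kappa must be > 0")
    d = np.arccos(np.clip(centroids @ centroids.T, -1.0, 1.0))
    K = np.exp(-d / kappa)
    for eps in (jitter, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(K + eps * np.eye(len(K)))
        except np.linalg.LinAlgError:
            continue
    raise NumericalFailureError("covariance not positive definite after jitter")


def generate_smooth_map(centroids, kappa: float, seed, size: int | None = None,
                        chol: np.ndarray | None = None):
    """Zero-mean, unit-variance Gaussian-process draw(s) on the sphere.

    Covariance is exp(-d/kappa) on geodesic distance; each draw is
    standardised across parcels. ``size=None`` returns a single (n,)
    vector, otherwise an (n, size) matrix of independent draws.
    ``chol`` lets callers reuse the Cholesky factor across many draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if chol is None:
        chol = exponential_kernel_cholesky(np.asarray(centroids, float), kappa)
    k = 1 if size is None else int(size)
    draws = chol @ rng.standard_normal((chol.shape[0], k))
    draws = draws - draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    draws = draws / sd
    return draws[:, 0] if size is None else draws


def generate_expression(centroids, n_genes: int, truth_map, n_coupled: int,
                        coupling_r: float, seed, kappa: float = 0.5,
                        chol: np.ndarray | None = None) -> ExpressionMatrix:
    """Smooth per-gene expression maps, the first ``n_coupled`` of which are
    linearly mixed with ``truth_map`` so their expected spatial Pearson
    correlation with it is ``coupling_r`` (alternating sign to populate
    both tails of the downstream PLS axis)."""
    if abs(coupling_r) >= 1:
        raise InvalidArgumentError("|coupling_r| must be < 1")
    if n_coupled > n_genes:
        raise InvalidArgumentError("n_coupled cannot exceed n_genes")
    centroids = np.asarray(centroids, float)
    tm = np.asarray(truth_map.values if isinstance(truth_map, ParcelMap) else truth_map,
                    dtype=float)
    tm = (tm - tm.mean()) / tm.std(ddof=0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if chol is None:
        chol = exponential_kernel_cholesky(centroids, kappa)
    base = generate_smooth_map(centroids, kappa, rng, size=n_genes, chol=chol)
    signs = np.where(np.arange(n_coupled) % 2 == 0, 1.0, -1.0)
    mix = np.sqrt(1.0 - coupling_r ** 2)
    base[:, :n_coupled] = (signs * coupling_r) * tm[:, None] + mix * base[:, :n_coupled]
    genes = [f"G{j:05d}" for j in range(n_genes)]
    ids = (truth_map.parcel_ids if isinstance(truth_map, ParcelMap)
           else [f"P{k:03d}" for k in range(len(tm))])
    df = pd.DataFrame(5.0 + base, index=list(ids), columns=genes)
    return ExpressionMatrix(df, provenance={"source": "synthetic",
                                            "coupling_r": coupling_r,
                                            "n_coupled": n_coupled})


def default_effect_parcels(parcellation: Parcellation, n_effect: int, seed) -> list:
    """A contiguous cluster: a seed parcel plus its nearest neighbours."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anchor = int(rng.integers(parcellation.n_parcels))
    d = parcellation.geodesic_distances()[anchor]
    return sorted(int(i) for i in np.argsort(d)[:n_effect])


def effect_pattern_map(parcellation: Parcellation, effect_parcels) -> ParcelMap:
    """Standardised deficit pattern: negative at effect parcels (cases lower)."""
    ind = np.zeros(parcellation.n_parcels)
    ind[list(effect_parcels)] = 1.0
    v = -(ind - ind.mean()) / ind.std(ddof=0)
    return ParcelMap(parcellation.parcel_ids, v, name="effect_pattern")


# ---------------------------------------------------------------------------
# cohort

def generate_cohort(parcellation: Parcellation, effect_parcels, gmv_effect_size: float,
                    n_mdd: int, n_hc: int, seed, *, noise_sd: float = 0.05,
                    subject_latent: np.ndarray | None = None,
                    pcr_signal_r: float = 0.0,
                    clinical_signal_r: float = 0.0) -> CohortTable:
    """Two-group cohort with covariates, clinical scores and regional GMV.

    GMV is baseline + linear covariate contributions (age, gender, TIV) +
    Gaussian noise; cases get a deficit of ``gmv_effect_size`` times the
    noise SD at ``effect_parcels``. If ``subject_latent`` is given, every
    subject's GMV at the effect parcels also carries a loading on that
    latent factor, scaled analytically so the within-sample correlation
    between regional GMV and the latent is ``pcr_signal_r`` in
    expectation (this is the planted DMP-to-GMV association). HAMD in
    patients depends on the same latent at ``clinical_signal_r``; HAMA is
    independent of everything (a built-in negative control).
    """
    if not np.isfinite(gmv_effect_size):
        raise InvalidArgumentError("gmv_effect_size must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_mdd + n_hc
    npar = parcellation.n_parcels
    subject_ids = [f"S{k:04d}" for k in range(n)]
    group = np.array(["MDD"] * n_mdd + ["HC"] * n_hc)

    age = rng.uniform(18, 60, n).round(1)
    gender = rng.integers(0, 2, n)
    education = np.clip(rng.normal(12, 3, n), 6, 22).round(1)
    medication = np.where(group == "MDD", rng.random(n) < 0.5, False).astype(int)
    tiv = rng.normal(1400, 120, n).round(1)

    baseline = rng.uniform(0.35, 0.65, npar)
    gmv = (baseline[None, :]
           - 0.001 * (age - 40.0)[:, None]
           + 5e-5 * (tiv - 1400.0)[:, None]
           + 0.01 * gender[:, None]
           + rng.normal(0.0, noise_sd, (n, npar)))

    eff = list(effect_parcels)
    is_case = group == "MDD"

    # latent factor first: it contributes to the within-group variance, so
    # the deficit (a standardized difference) must be scaled to the
    # covariate-adjusted residual SD including the latent contribution
    resid_sd = np.full(len(eff), noise_sd)
    if subject_latent is not None and abs(pcr_signal_r) > 0:
        u = np.asarray(subject_latent, float)
        lam = pcr_signal_r / np.sqrt(1.0 - pcr_signal_r ** 2)
        s = gmv[:, eff].std(axis=0, ddof=0)
        gmv[:, eff] += lam * s[None, :] * u[:, None]
        resid_sd = np.sqrt(noise_sd ** 2 + (lam * s) ** 2)

    # medication exists only in patients, so it is collinear with group and
    # inflates the adjusted group-contrast SE; calibrate the deficit on the
    # adjusted-contrast scale so gmv_effect_size is the standardized effect
    # the covariate-adjusted test actually sees
    D = np.column_stack([np.ones(n), age, gender, education, medication, tiv])
    g = is_case.astype(float)
    coef, *_ = np.linalg.lstsq(D, g, rcond=None)
    r2_g = 1.0 - ((g - D @ coef) ** 2).sum() / ((g - g.mean()) ** 2).sum()
    inflate = 1.0 / np.sqrt(max(1e-6, 1.0 - r2_g))
    gmv[np.ix_(is_case, eff)] -= gmv_effect_size * inflate * resid_sd[None, :]
    gmv = np.maximum(gmv, 1e-3)

    # clinical scores: HAMD coupled to the latent in patients, HAMA a null
    u = (np.asarray(subject_latent, float) if subject_latent is not None
         else rng.standard_normal(n))
    c = clinical_signal_r
    hamd_core = c * u + np.sqrt(max(0.0, 1.0 - c * c)) * rng.standard_normal(n)
    hamd = np.where(is_case,
                    np.clip(np.round(22 + 5 * hamd_core), 8, 52),
                    np.clip(np.round(rng.normal(2, 1.5, n)), 0, 7))
    hama = np.where(is_case,
                    np.clip(np.round(rng.normal(16, 5, n)), 4, 45),
                    np.clip(np.round(rng.normal(2, 1.5, n)), 0, 7))

    subjects = pd.DataFrame(
        {"group": group, "age": age, "gender": gender, "education": education,
         "medication": medication, "tiv": tiv, "hamd": hamd, "hama": hama},
        index=pd.Index(subject_ids, name="subject_id"))
    gmv_df = pd.DataFrame(gmv, index=subjects.index, columns=list(parcellation.parcel_ids))
    return CohortTable(subjects, gmv_df)


# ---------------------------------------------------------------------------
# methylation

def generate_methylation(cohort: CohortTable, gene_universe, coupled_genes,
                         n_cpgs: int, n_true_dmps: int, dmp_delta_beta: float,
                         seed, *, subject_latent: np.ndarray | None = None,
                         logit_noise_sd: float = 0.12,
                         latent_loading: float = 0.10,
                         truth_out: dict | None = None) -> MethylationSet:
    """Subject x CpG beta values simulated on the logit scale.

    True DMPs are annotated to distinct genes drawn from ``coupled_genes``
    with ``promoter_flag`` True, receive a case-control mean shift of
    ``dmp_delta_beta`` on the beta scale (sign random per CpG, mapped to a
    local logit shift), and load on ``subject_latent`` so that their mean
    composite tracks the latent tied to GMV in :func:`generate_cohort`.
    """
    if n_true_dmps > n_cpgs:
        raise InvalidArgumentError("n_true_dmps cannot exceed n_cpgs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = len(cohort.subjects)
    is_case = cohort.group_indicator.astype(bool)

    cpg_ids = [f"cg{k:07d}" for k in range(n_cpgs)]
    true_idx = np.sort(rng.choice(n_cpgs, size=n_true_dmps, replace=False))
    is_true = np.zeros(n_cpgs, bool)
    is_true[true_idx] = True

    coupled_genes = list(coupled_genes)
    gene_universe = list(gene_universe)
    if n_true_dmps > len(coupled_genes):
        raise InvalidArgumentError("need at least one coupled gene per true DMP")
    dmp_genes = list(rng.choice(coupled_genes, size=n_true_dmps, replace=False))
    genes = np.array(rng.choice(gene_universe, size=n_cpgs), dtype=object)
    genes[rng.random(n_cpgs) < 0.03] = ""  # unannotated CpGs
    genes[true_idx] = dmp_genes
    promoter = rng.random(n_cpgs) < 0.3
    promoter[true_idx] = True

    # mid-range baselines for true DMPs so the beta-scale shift is representable
    m = rng.normal(0.0, 1.5, n_cpgs)
    m[true_idx] = rng.normal(0.0, 0.6, n_true_dmps)

    sign = rng.choice([-1.0, 1.0], size=n_cpgs)
    p0 = expit(m)
    p1 = p0 + sign * dmp_delta_beta
    bad = is_true & ((p1 <= 0.005) | (p1 >= 0.995))
    if bad.any():
        raise InvalidArgumentError(
            "dmp_delta_beta pushes group means outside (0, 1) "
            f"for {int(bad.sum())} CpGs")

    L = m[None, :] + rng.normal(0.0, logit_noise_sd, (n_sub, n_cpgs))
    shift = np.where(is_true, logit(np.clip(p1, 0.005, 0.995)) - m, 0.0)
    L[is_case] += shift[None, :]
    if subject_latent is not None:
        u = np.asarray(subject_latent, float)
        L[:, true_idx] += latent_loading * u[:, None]

    beta = expit(L)
    if truth_out is not None:
        truth_out["true_dmps"] = [cpg_ids[k] for k in true_idx]
        truth_out["true_dmp_genes"] = sorted(set(dmp_genes))
    beta_df = pd.DataFrame(beta, index=cohort.subjects.index, columns=cpg_ids)
    anno = pd.DataFrame(
        {"gene": genes,
         "promoter_flag": promoter,
         "chrom": [f"chr{c}" for c in rng.integers(1, 23, n_cpgs)],
         "pos": rng.integers(10_000, 100_000_000, n_cpgs)},
        index=pd.Index(cpg_ids, name="cpg_id"))
    return MethylationSet(beta_df, anno)


# ---------------------------------------------------------------------------
# pathways

def generate_pathways(genes, n_pathways: int, enriched_set, seed, *,
                      n_enriched: int = 5, fold: float = 10.0,
                      size: int = 40):
    """Named gene sets; ``n_enriched`` of them are enriched for
    ``enriched_set`` members at the given fold over the uniform baseline.

    Returns ``(pathways, enriched_names)`` where pathways maps name ->
    member list. ``fold <= 1`` makes every pathway a uniform draw (null).
    """
    genes = list(genes)
    if not genes:
        raise InvalidArgumentError("gene universe is empty")
    enriched_set = [g for g in enriched_set if g in set(genes)]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    others = sorted(set(genes) - set(enriched_set))
    pathways = {}
    enriched_names = []
    for i in range(n_pathways):
        name = f"PW{i:03d}"
        if fold > 1 and i < n_enriched and enriched_set:
            k_set = int(min(len(enriched_set),
                            max(1, round(fold * size * len(enriched_set) / len(genes)))))
            members = list(rng.choice(enriched_set, size=k_set, replace=False))
            members += list(rng.choice(others, size=size - k_set, replace=False))
            enriched_names.append(name)
        else:
            members = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
        pathways[name] = sorted(members)
    return pathways, enriched_names


# ---------------------------------------------------------------------------
# whole study

def generate_study(config: SynthConfig) -> SyntheticStudy:
    """Generate the full synthetic study described by ``config``."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(7)
    rng_par, rng_eff, rng_expr, rng_coh, rng_meth, rng_path, rng_lat = (
        np.random.default_rng(s) for s in seeds)

    parcellation = generate_parcellation(config.n_parcels,
                                         int(rng_par.integers(2 ** 31)))
    if config.effect_parcels is not None:
        effect = list(config.effect_parcels)
    else:
        effect = default_effect_parcels(parcellation, config.n_effect_parcels, rng_eff)
    pattern = effect_pattern_map(parcellation, effect)

    chol = exponential_kernel_cholesky(parcellation.centroids, config.smoothness_kappa)
    expression = generate_expression(
        parcellation.centroids, config.n_genes, pattern,
        config.n_coupled_genes, config.coupling_r, rng_expr,
        kappa=config.smoothness_kappa, chol=chol)

    n_sub = config.n_subjects_mdd + config.n_subjects_hc
    latent = rng_lat.standard_normal(n_sub)
    # orthogonalise the latent to the group contrast: the PCR plant and the
    # group-deficit plant stay separate by construction (no accidental
    # confounding of either the GMV or the DMP group tests)
    for sl in (slice(0, config.n_subjects_mdd), slice(config.n_subjects_mdd, n_sub)):
        latent[sl] -= latent[sl].mean()
        latent[sl] /= latent[sl].std(ddof=0)

    cohort = generate_cohort(
        parcellation, effect, config.gmv_effect_size,
        config.n_subjects_mdd, config.n_subjects_hc, rng_coh,
        noise_sd=config.gmv_noise_sd, subject_latent=latent,
        pcr_signal_r=config.pcr_signal_r,
        clinical_signal_r=config.clinical_signal_r)

    coupled = expression.genes[: config.n_coupled_genes]
    coupled_signs = {g: (1 if j % 2 == 0 else -1) for j, g in enumerate(coupled)}
    meth_truth: dict = {}
    methylation = generate_methylation(
        cohort, expression.genes, coupled, config.n_cpgs,
        config.n_true_dmps, config.dmp_delta_beta, rng_meth,
        subject_latent=latent if abs(config.pcr_signal_r) > 0 else None,
        logit_noise_sd=config.meth_logit_noise_sd,
        latent_loading=config.meth_latent_loading,
        truth_out=meth_truth)
    true_dmps = meth_truth["true_dmps"]

    pathways, enriched_names = generate_pathways(
        expression.genes, config.n_pathways,
        meth_truth["true_dmp_genes"],
        rng_path, n_enriched=config.n_enriched_pathways,
        fold=config.pathway_fold, size=config.pathway_size)

    truth = {
        "effect_parcel_indices": [int(i) for i in effect],
        "effect_parcels": [parcellation.parcel_ids[i] for i in effect],
        "coupled_genes": list(coupled),
        "coupled_gene_signs": coupled_signs,
        "true_dmps": list(true_dmps),
        "true_dmp_genes": list(meth_truth["true_dmp_genes"]),
        "enriched_pathways": list(enriched_names),
        "subject_latent": {s: float(v) for s, v in zip(cohort.subjects.index, latent)},
        "gmv_effect_size": config.gmv_effect_size,
        "coupling_r": config.coupling_r,
        "pcr_signal_r": config.pcr_signal_r,
        "dmp_delta_beta": config.dmp_delta_beta,
    }
    return SyntheticStudy(parcellation, expression, cohort, methylation,
                          pathways, truth, config)


def study_truth_frame(study: SyntheticStudy) -> pd.DataFrame:
    """Convenience one-row summary of planted effect sizes."""
    t = study.truth
    return pd.DataFrame([{
        "n_effect_parcels": len(t["effect_parcels"]),
        "n_coupled_genes": len(t["coupled_genes"]),
        "n_true_dmps": len(t["true_dmps"]),
        "n_enriched_pathways": len(t["enriched_pathways"]),
        "gmv_effect_size": t["gmv_effect_size"],
        "coupling_r": t["coupling_r"],
        "pcr_signal_r": t["pcr_signal_r"],
    }])
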