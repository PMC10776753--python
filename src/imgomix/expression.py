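"""Donor-level expression preparation: sample tables -> parcels x genes.

A simplified, fully configurable version of the community-standard
microarray-atlas preparation: probe intensity filtering, probe -> gene
collapse, nearest-centroid sample assignment with a distance cap,
within-donor normalisation (scaled robust sigmoid or z-score), and
cross-donor averaging. A ready-made parcels x genes TSV is an equally
valid entry point for every downstream stage; this module exists so the
pipeline can start from donor tables when they are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, Parcellation
from .errors import InvalidArgumentError, SchemaMismatchError

logger = logging.getLogger("imgomix")


@dataclass
class DonorSampleTable:
    """One donor's samples: coordinates, probe intensities and annotation.

    ``intensities`` is probes x samples; ``pass_flags`` is a same-shaped
    boolean frame (probe detected above background in that sample);
    ``probe_annotation`` maps probe_id -> gene symbol.
    """

    donor_id: str
    coordinates: np.ndarray            # (n_samples, 3)
    intensities: pd.DataFrame          # probes x samples
    probe_annotation: pd.Series        # probe_id -> gene
    pass_flags: pd.DataFrame = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        if not np.all(np.isfinite(self.coordinates)):
            raise InvalidArgumentError("sample coordinates must be finite")
        if self.coordinates.shape[0] != self.intensities.shape[1]:
            raise SchemaMismatchError("coordinates/samples count mismatch")
        missing = set(self.intensities.index) - set(self.probe_annotation.index)
        if missing:
            raise SchemaMismatchError(
                f"{len(missing)} probes lack annotation, e.g. {sorted(missing)[:3]}")
        if self.pass_flags is None:
            self.pass_flags = pd.DataFrame(
                True, index=self.intensities.index, columns=self.intensities.columns)


def filter_probes(table: DonorSampleTable, intensity_flag_threshold: float = 0.5
                  ) -> DonorSampleTable:
    """Keep probes flagged present in at least the given fraction of samples."""
    if not 0 <= intensity_flag_threshold <= 1:
        raise InvalidArgumentError("threshold must be in [0, 1]")
    frac = table.pass_flags.mean(axis=1)
    keep = frac.index[frac.to_numpy() >= intensity_flag_threshold]
    return DonorSampleTable(
        table.donor_id, table.coordinates,
        table.intensities.loc[keep],
        table.probe_annotation,
        table.pass_flags.loc[keep])


def collapse_probes_to_genes(table: DonorSampleTable, method: str = "max_mean"
                             ) -> pd.DataFrame:
    """genes x samples: one representative probe per gene.

    The representative maximises the probe mean ('max_mean') or variance
    ('max_variance') across samples; ties break on lexicographic probe id.
    Genes left with zero probes after filtering are dropped with a log line.
    """
    if method not in ("max_mean", "max_variance"):
        raise InvalidArgumentError(f"unknown collapse method {method!r}")
    stat = (table.intensities.mean(axis=1) if method == "max_mean"
            else table.intensities.var(axis=1, ddof=0))
    genes = table.probe_annotation.loc[table.intensities.index]
    rows = {}
    for gene, probes in genes.groupby(genes).groups.items():
        probes = sorted(probes)  # lexicographic tie-break
        vals = stat.loc[probes]
        best = vals.index[np.argmax(vals.to_numpy())]
        # argmax returns the first maximum over the sorted probe list
        rows[gene] = table.intensities.loc[best]
    n_dropped = len(set(table.probe_annotation)) - len(rows)
    if n_dropped > 0:
        logger.info("dropped %d genes with no surviving probes", n_dropped)
    return pd.DataFrame(rows).T.sort_index()


def assign_samples_to_parcels(coordinates, parcellation: Parcellation,
                              max_distance: float = 0.25) -> np.ndarray:
    """Nearest-centroid (Euclidean) parcel index per sample, or -1 when the
    nearest centroid is farther than ``max_distance``; ties break to the
    lower parcel index."""
    coords = np.asarray(coordinates, float)
    d = np.linalg.norm(coords[:, None, :] - parcellation.centroids[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    dist = d[np.arange(len(coords)), nearest]
    return np.where(dist <= max_distance, nearest, -1)


def normalize_within_donor(genes_by_samples: pd.DataFrame,
                           method: str = "scaled_robust_sigmoid") -> pd.DataFrame:
    """Per-gene normalisation across one donor's samples.

    'scaled_robust_sigmoid': x -> 1/(1+exp(-(x-median)/(IQR/1.35))) followed
    by min-max to [0, 1]; constant genes map to 0.5. 'zscore': mean 0, SD 1;
    constant genes map to 0.
    """
    X = genes_by_samples.to_numpy(float)
    if X.shape[1] < 2:
        raise InvalidArgumentError("donor must have at least 2 samples")
    if method == "zscore":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        out = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1, sd), 0.0)
    elif method == "scaled_robust_sigmoid":
        med = np.median(X, axis=1, keepdims=True)
        iqr = (np.percentile(X, 75, axis=1) - np.percentile(X, 25, axis=1))[:, None]
        scale = iqr / 1.35
        with np.errstate(over="ignore"):
            sig = np.where(scale > 0, 1.0 / (1.0 + np.exp(-(X - med) / np.where(scale == 0, 1, scale))), 0.5)
        lo = sig.min(axis=1, keepdims=True)
        hi = sig.max(axis=1, keepdims=True)
        rng = hi - lo
        out = np.where(rng > 0, (sig - lo) / np.where(rng == 0, 1, rng), 0.5)
    else:
        raise InvalidArgumentError(f"unknown normalisation {method!r}")
    return pd.DataFrame(out, index=genes_by_samples.index,
                        columns=genes_by_samples.columns)


def donor_parcel_matrix(norm: pd.DataFrame, assignment: np.ndarray,
                        parcellation: Parcellation) -> pd.DataFrame:
    """parcels x genes for one donor: mean over the samples assigned to each
    parcel; parcels with no samples are NaN."""
    out = np.full((parcellation.n_parcels, norm.shape[0]), np.nan)
    for p in range(parcellation.n_parcels):
        cols = np.nonzero(assignment == p)[0]
        if cols.size:
            out[p] = norm.iloc[:, cols].mean(axis=1).to_numpy()
    return pd.DataFrame(out, index=list(parcellation.parcel_ids),
                        columns=list(norm.index))


def aggregate_across_donors(per_donor: list) -> pd.DataFrame:
    """Elementwise nan-mean of the per-donor parcels x genes matrices."""
    first = per_donor[0]
    for m in per_donor[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise SchemaMismatchError("donor matrices must share parcels and genes")
    stack = np.stack([m.to_numpy(float) for m in per_donor])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return pd.DataFrame(mean, index=first.index, columns=first.columns)


def prepare_expression(donors: list, parcellation: Parcellation, *,
                       intensity_flag_threshold: float = 0.5,
                       collapse_method: str = "max_mean",
                       max_distance: float = 0.25,
                       normalization: str = "scaled_robust_sigmoid",
                       parcel_subset=None) -> ExpressionMatrix:
    """Full preparation chain over a list of :class:`DonorSampleTable`.

    Donor order does not affect the result (each donor is processed
    independently and the aggregation is a mean). Parcels never covered
    by any donor are dropped with a log entry; ``parcel_subset`` (id list)
    restricts the atlas, e.g. to one hemisphere.
    """
    per_donor = []
    for donor in sorted(donors, key=lambda d: d.donor_id):
        filtered = filter_probes(donor, intensity_flag_threshold)
        genes = collapse_probes_to_genes(filtered, collapse_method)
        assignment = assign_samples_to_parcels(donor.coordinates, parcellation,
                                               max_distance)
        if (assignment >= 0).sum() == 0:
            raise SchemaMismatchError(f"donor {donor.donor_id}: no samples assigned")
        norm = normalize_within_donor(genes, normalization)
        per_donor.append(donor_parcel_matrix(norm, assignment, parcellation))
    agg = aggregate_across_donors(per_donor)
    covered = ~agg.isna().all(axis=1)
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.info("dropping %d parcels with no donor coverage", n_uncovered)
    agg = agg.loc[covered]
    empty_genes = agg.columns[agg.isna().all(axis=0)]
    agg = agg.drop(columns=empty_genes)
    if parcel_subset is not None:
        agg = agg.loc[[p for p in parcel_subset if p in agg.index]]
    provenance = {
        "steps": ["filter_probes", "collapse_probes_to_genes",
                  "assign_samples_to_parcels", "normalize_within_donor",
                  "aggregate_across_donors"],
        "intensity_flag_threshold": intensity_flag_threshold,
        "collapse_method": collapse_method,
        "max_distance": max_distance,
        "normalization": normalization,
        "n_donors": len(donors),
        "n_genes": int(agg.shape[1]),
        "n_parcels": int(agg.shape[0]),
    }
    return ExpressionMatrix(agg, provenance)


def load_donor_tables(donors_dir) -> list:
    """Read donor tables from ``donors_dir``: one subdirectory per donor
    holding ``coordinates.csv`` (sample_id,x,y,z), ``intensities.csv``
    (probes x samples), ``annotation.csv`` (probe_id,gene) and optionally
    ``flags.csv`` (0/1, same shape as intensities)."""
    from pathlib import Path

    import pandas as pd

    donors = []
    root = Path(donors_dir)
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        coords = pd.read_csv(sub / "coordinates.csv", index_col=0)
        intens = pd.read_csv(sub / "intensities.csv", index_col=0)
        anno = pd.read_csv(sub / "annotation.csv", index_col=0)["gene"]
        flags = None
        if (sub / "flags.csv").exists():
            flags = pd.read_csv(sub / "flags.csv", index_col=0).astype(bool)
        donors.append(DonorSampleTable(
            donor_id=sub.name, coordinates=coords[["x", "y", "z"]].to_numpy(),
            intensities=intens, probe_annotation=anno, pass_flags=flags))
    if not donors:
        raise InvalidArgumentError(f"no donor subdirectories in {root}")
    return donors


def write_donor_tables(donors: list, donors_dir) -> None:
    """Inverse of :func:`load_donor_tables` (used by examples and tests)."""
    from pathlib import Path

    import pandas as pd

    root = Path(donors_dir)
    for d in donors:
        sub = root / d.donor_id
        sub.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(d.coordinates, columns=["x", "y", "z"],
                     index=pd.Index(d.intensities.columns, name="sample_id")
                     ).to_csv(sub / "coordinates.csv", float_format="%.12g")
        d.intensities.rename_axis("probe_id").to_csv(
            sub / "intensities.csv", float_format="%.12g")
        d.probe_annotation.rename("gene").rename_axis("probe_id").to_frame(
            ).to_csv(sub / "annotation.csv")
        d.pass_flags.astype(int).rename_axis("probe_id").to_csv(
            sub / "flags.csv")


def make_synthetic_donor_tables(truth: ExpressionMatrix, parcellation: Parcellation,
                                n_donors: int = 3, probes_per_gene: int = 2,
                                samples_per_donor: int = 200,
                                noise_sd: float = 0.1, seed=0) -> list:
    """Synthetic donor sample tables consistent with a known truth matrix.

    Test support for the preparation chain: samples sit at jittered parcel
    centroids, probe intensities are the parcel's truth value plus a probe
    offset and noise, and a small fraction of pass flags is cleared.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tvals = truth.data.to_numpy(float)
    donors = []
    for d in range(n_donors):
        sample_parcels = rng.integers(0, parcellation.n_parcels, samples_per_donor)
        coords = parcellation.centroids[sample_parcels]
        coords = coords + rng.normal(0, 0.02, coords.shape)
        coords /= np.linalg.norm(coords, axis=1, keepdims=True)
        probe_ids, gene_map, rows = [], {}, []
        for j, gene in enumerate(truth.genes):
            for k in range(probes_per_gene):
                pid = f"probe_{gene}_{k}"
                probe_ids.append(pid)
                gene_map[pid] = gene
                offset = rng.normal(0, 0.05)
                rows.append(tvals[sample_parcels, j] + offset
                            + rng.normal(0, noise_sd, samples_per_donor))
        intens = pd.DataFrame(np.array(rows), index=probe_ids,
                              columns=[f"D{d}_s{i}" for i in range(samples_per_donor)])
        flags = pd.DataFrame(rng.random(intens.shape) > 0.05,
                             index=intens.index, columns=intens.columns)
        donors.append(DonorSampleTable(
            donor_id=f"D{d}", coordinates=coords, intensities=intens,
            probe_annotation=pd.Series(gene_map), pass_flags=flags))
    return donors
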