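"""Core in-memory containers shared by all pipeline stages.

Everything tabular is a labelled :class:`pandas.DataFrame`; the thin
dataclass wrappers below exist to carry alignment invariants (parcel
order, subject order, annotation coverage) and light validation, not to
hide pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaMismatchError

GROUP_CASE = "MDD"
GROUP_CONTROL = "HC"

#: Covariates used by the regional gray-matter model.
GMV_COVARIATES = ("age", "gender", "education", "medication", "tiv")
#: Covariates used by the per-CpG methylation model (no TIV).
CPG_COVARIATES = ("age", "gender", "education", "medication")


@dataclass(frozen=True)
class Parcellation:
    """Ordered cortical parcels with unit-sphere centroid coordinates."""

    parcel_ids: tuple
    centroids: np.ndarray  # (n, 3), unit norm rows

    def __post_init__(self):
        c = np.asarray(self.centroids, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise InvalidArgumentError("centroids must be an (n, 3) array")
        if len(self.parcel_ids) != c.shape[0]:
            raise InvalidArgumentError("parcel_ids and centroids length mismatch")
        norms = np.linalg.norm(c, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise InvalidArgumentError("centroids must lie on the unit sphere")
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "parcel_ids", tuple(self.parcel_ids))

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def geodesic_distances(self) -> np.ndarray:
        """Pairwise great-circle distances (radians) between centroids."""
        dots = np.clip(self.centroids @ self.centroids.T, -1.0, 1.0)
        return np.arccos(dots)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.centroids, index=list(self.parcel_ids), columns=["x", "y", "z"]
        ).rename_axis("parcel_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        return cls(tuple(df.index), df[["x", "y", "z"]].to_numpy(float))


@dataclass
class ParcelMap:
    """A scalar value per parcel (t-statistic, PLS score, ...), in parcel order."""

    parcel_ids: tuple
    values: np.ndarray
    name: str = "value"

    def __post_init__(self):
        self.parcel_ids = tuple(self.parcel_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.parcel_ids),):
            raise InvalidArgumentError("values must be 1-D, one per parcel")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.parcel_ids), name=self.name)

    def aligned_to(self, parcel_ids) -> "ParcelMap":
        """Reorder onto ``parcel_ids``; raises if any parcel is missing."""
        s = self.to_series()
        missing = [p for p in parcel_ids if p not in s.index]
        if missing:
            raise SchemaMismatchError(f"map is missing parcels: {missing[:5]}")
        return ParcelMap(tuple(parcel_ids), s.loc[list(parcel_ids)].to_numpy(), self.name)


@dataclass
class ExpressionMatrix:
    """Regional expression: parcels (rows) x genes (columns).

    ``provenance`` records the preparation steps and their parameters so a
    prepared matrix can be audited and the preparation replayed.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise SchemaMismatchError("duplicate gene symbols in expression matrix")
        if self.data.index.duplicated().any():
            raise SchemaMismatchError("duplicate parcel ids in expression matrix")

    @property
    def genes(self):
        return list(self.data.columns)

    @property
    def parcel_ids(self):
        return tuple(self.data.index)

    def values_for(self, parcel_ids) -> np.ndarray:
        missing = [p for p in parcel_ids if p not in self.data.index]
        if missing:
            raise SchemaMismatchError(f"expression missing parcels: {missing[:5]}")
        return self.data.loc[list(parcel_ids)].to_numpy(float)


@dataclass
class CohortTable:
    """Per-subject phenotypes plus the regional GMV matrix.

    ``subjects`` is indexed by subject id and carries group, covariates and
    clinical scores; ``gmv`` is subjects x parcels, strictly positive volume
    density, row-aligned to ``subjects``.
    """

    subjects: pd.DataFrame
    gmv: pd.DataFrame

    def __post_init__(self):
        required = {"group", "age", "gender", "education", "medication", "tiv"}
        missing = required - set(self.subjects.columns)
        if missing:
            raise SchemaMismatchError(f"cohort table missing columns: {sorted(missing)}")
        if not self.subjects.index.equals(self.gmv.index):
            raise SchemaMismatchError("subjects and gmv indices are not aligned")
        bad = set(self.subjects["group"]) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise InvalidArgumentError(f"unknown group labels: {sorted(bad)}")
        if (self.gmv.to_numpy(float) <= 0).any():
            raise InvalidArgumentError("GMV values must be strictly positive")

    @property
    def parcel_ids(self):
        return tuple(self.gmv.columns)

    @property
    def group_indicator(self) -> np.ndarray:
        """1 for cases (MDD), 0 for controls."""
        return (self.subjects["group"] == GROUP_CASE).to_numpy(int)

    def patients(self) -> "CohortTable":
        mask = self.subjects["group"] == GROUP_CASE
        return CohortTable(self.subjects.loc[mask].copy(), self.gmv.loc[mask].copy())


@dataclass
class MethylationSet:
    """Subject x CpG beta values with a manifest-style CpG annotation.

    The annotation frame is indexed by cpg_id and carries ``gene``,
    ``promoter_flag`` (bool), ``chrom`` and ``pos``.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self):
        vals = self.beta.to_numpy(float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise InvalidArgumentError("beta values must lie in [0, 1]")
        missing = set(self.beta.columns) - set(self.annotation.index)
        if missing:
            raise SchemaMismatchError(
                f"annotation does not cover {len(missing)} CpGs, e.g. {sorted(missing)[:3]}"
            )
        for col in ("gene", "promoter_flag", "chrom", "pos"):
            if col not in self.annotation.columns:
                raise SchemaMismatchError(f"annotation missing column {col!r}")

    @property
    def cpg_ids(self):
        return list(self.beta.columns)

    def aligned_to_cohort(self, cohort: CohortTable) -> "MethylationSet":
        missing = set(cohort.subjects.index) - set(self.beta.index)
        if missing:
            raise SchemaMismatchError(f"beta matrix missing subjects: {sorted(missing)[:3]}")
        return MethylationSet(self.beta.loc[cohort.subjects.index], self.annotation)
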