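"""Text-first I/O: labelled matrices (CSV/TSV), GMT gene sets, JSON, and
whole-study round trips. Numeric output keeps 12 significant digits so a
write/read cycle is lossless at analysis precision and byte-reproducible
for fixed inputs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CohortTable, ExpressionMatrix, MethylationSet, Parcellation
from .errors import FormatError

FLOAT_FMT = "%.12g"


def write_matrix(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT)


def read_matrix(path, sep: str = ",", index_col: int = 0) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    labels = header[index_col + 1:]
    seen = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"{path}: duplicate column label {lab!r}")
        seen.add(lab)
    try:
        df = pd.read_csv(path, sep=sep, index_col=index_col)
    except pd.errors.ParserError as e:  # ragged rows etc.
        raise FormatError(f"{path}: {e}") from e
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row label {dup!r}")
    return df


def write_gmt(pathways: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name in pathways:
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *map(str, pathways[name])]) + "\n")


def read_gmt(path) -> dict:
    """GMT convention: name, description, then members; trailing tabs and
    empty member fields are ignored."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: GMT needs name and description")
            name = parts[0]
            if name in out:
                raise FormatError(f"{path}:{ln}: duplicate set name {name!r}")
            out[name] = [m for m in parts[2:] if m.strip()]
    return out


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# whole-study round trip

def write_study(study, outdir) -> None:
    """Write every component of a synthetic study as plain text."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(study.parcellation.to_frame(), out / "centroids.csv")
    cohort_df = pd.concat([study.cohort.subjects, study.cohort.gmv], axis=1)
    write_matrix(cohort_df, out / "cohort.csv")
    write_matrix(study.expression.data.rename_axis("parcel_id"),
                 out / "expression.tsv", sep="\t")
    write_matrix(study.methylation.beta.rename_axis("subject_id"),
                 out / "beta.tsv", sep="\t")
    write_matrix(study.methylation.annotation, out / "annotation.csv")
    write_gmt(study.pathways, out / "pathways.gmt")
    write_json(study.truth, out / "truth.json")


def read_study(indir):
    """Inverse of :func:`write_study`; returns a SyntheticStudy."""
    from .synthetic import SyntheticStudy

    ind = Path(indir)
    parc = Parcellation.from_frame(read_matrix(ind / "centroids.csv"))
    cohort_df = read_matrix(ind / "cohort.csv")
    pheno_cols = ["group", "age", "gender", "education", "medication",
                  "tiv", "hamd", "hama"]
    subjects = cohort_df[pheno_cols]
    gmv = cohort_df[[c for c in cohort_df.columns if c in set(parc.parcel_ids)]]
    cohort = CohortTable(subjects, gmv)
    expr = ExpressionMatrix(read_matrix(ind / "expression.tsv", sep="\t"))
    anno = read_matrix(ind / "annotation.csv")
    anno["promoter_flag"] = anno["promoter_flag"].astype(bool)
    anno["gene"] = anno["gene"].fillna("")
    beta = read_matrix(ind / "beta.tsv", sep="\t")
    meth = MethylationSet(beta, anno)
    pathways = read_gmt(ind / "pathways.gmt")
    truth = read_json(ind / "truth.json") if (ind / "truth.json").exists() else {}
    return SyntheticStudy(parc, expr, cohort, meth, pathways, truth)
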