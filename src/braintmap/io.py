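"""Readers and writers for the pipeline's tabular formats.

Formats (all UTF-8 with a header row):

* phenotypes — CSV with columns subject_id, diagnosis, age, sex, education
* imaging    — CSV, first column subject_id, remaining columns ROI labels
* expression — TSV, first column gene symbol, remaining columns ROI labels;
  empty cells mean missing
* gene set   — plain text, one symbol per line
* results    — CSV with the fixed column order
  gene, contrast, r, n_used, p, p_adjusted, significant
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    PHENOTYPE_COLUMNS,
    RESULT_COLUMNS,
    STAGES,
    ExpressionMatrix,
    GeneSet,
    ImagingMatrix,
    PhenotypeTable,
)
from .errors import InputError

logger = logging.getLogger("braintmap")

#: Accepted spellings for the binary sex code (male=1, female=0).
_SEX_CODES = {
    "1": 1, "m": 1, "male": 1, "1.0": 1,
    "0": 0, "f": 0, "female": 0, "0.0": 0,
}

#: Fixed float format for all writers so that write -> read -> write is
#: byte-stable (17 significant digits round-trips any float64).
FLOAT_FORMAT = "%.17g"


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Load and validate a phenotype CSV.

    Rows with missing or unparseable age/sex/education are dropped (the
    count is logged); an unknown diagnosis label is a hard error naming the
    offending row, because it usually indicates the wrong file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, dtype={"subject_id": str, "diagnosis": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise InputError(f"phenotype file {path} is empty") from None
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InputError(f"{path}: missing phenotype columns {missing_cols}")
    if df.empty:
        raise InputError(f"phenotype file {path} has a header but no rows")

    bad_dx = ~df["diagnosis"].isin(STAGES)
    if bad_dx.any():
        row = int(df.index[bad_dx][0])
        raise InputError(
            f"{path}: unknown diagnosis {df.loc[row, 'diagnosis']!r} "
            f"in data row {row + 1} (subject_id="
            f"{df.loc[row, 'subject_id']!r}); allowed: {STAGES}"
        )

    sex = (
        df["sex"].astype(str).str.strip().str.lower().map(_SEX_CODES)
    )
    age = pd.to_numeric(df["age"], errors="coerce")
    edu = pd.to_numeric(df["education"], errors="coerce")
    usable = sex.notna() & age.notna() & edu.notna() & (age > 0) & (edu >= 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "read_phenotypes: dropped %d row(s) with missing/unparseable "
            "covariates from %s", n_dropped, path,
        )
    clean = pd.DataFrame(
        {
            "subject_id": df.loc[usable, "subject_id"],
            "diagnosis": df.loc[usable, "diagnosis"],
            "age": age[usable].astype(float),
            "sex": sex[usable].astype(int),
            "education": edu[usable].astype(float),
        }
    )
    return PhenotypeTable(clean)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_imaging(path: str | Path) -> ImagingMatrix:
    """Load a subjects x ROIs imaging-trait CSV (first column subject_id)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise InputError(f"imaging file {path} is empty") from None
    if df.shape[1] == 0:
        raise InputError(f"{path}: imaging matrix has no ROI columns")
    df.index = df.index.astype(str)
    return ImagingMatrix(df.astype(float))


def write_imaging(matrix: ImagingMatrix, path: str | Path) -> None:
    matrix.frame.to_csv(
        path, index=True, index_label="subject_id", float_format=FLOAT_FORMAT
    )


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Load a genes x ROIs expression TSV; empty cells are missing.

    Genes with fewer than 3 non-missing ROI values cannot enter any
    correlation and are excluded at load with a logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise InputError(f"expression file {path} is empty") from None
    if df.shape[1] == 0:
        raise InputError(f"{path}: expression matrix has no ROI columns")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate gene symbol(s): {dupes[:5]}")
    df.index = df.index.astype(str)
    df = df.astype(float)
    n_obs = df.notna().sum(axis=1)
    too_sparse = n_obs < ExpressionMatrix.MIN_ROIS
    if too_sparse.any():
        logger.warning(
            "read_expression: excluded %d gene(s) with < %d non-missing ROI "
            "values from %s", int(too_sparse.sum()), ExpressionMatrix.MIN_ROIS,
            path,
        )
        df = df.loc[~too_sparse]
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.frame.to_csv(
        path, sep="\t", index=True, index_label="gene", float_format=FLOAT_FORMAT
    )


def read_gene_set(path: str | Path) -> GeneSet:
    """Load a one-symbol-per-line annotation list; an empty file yields an
    empty set (every downstream hit is then reported as novel)."""
    text = Path(path).read_text(encoding="utf-8")
    symbols = [line.strip() for line in text.splitlines()]
    gene_set = GeneSet(symbols)
    if not gene_set:
        logger.warning("read_gene_set: %s contains no gene symbols", path)
    return gene_set


def write_gene_set(genes: GeneSet, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(sorted(genes)) + ("\n" if genes else ""), encoding="utf-8"
    )


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a stage-2 results table with the fixed column order."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"results table lacks columns {missing}")
    out = table.loc[:, list(RESULT_COLUMNS)].copy()
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: results file lacks columns {missing}")
    return df


def write_effect_map(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(
        path, index=True, index_label="roi_label", float_format=FLOAT_FORMAT
    )


def read_effect_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="roi_label", float_precision="round_trip")


def filter_hemisphere(roi_labels: list[str], prefix: str = "L_") -> list[str]:
    """Restrict an atlas label list to one hemisphere by prefix, preserving
    order. Labels must carry an ``L_`` or ``R_`` hemisphere prefix."""
    offenders = [
        lab for lab in roi_labels if not (lab.startswith("L_") or lab.startswith("R_"))
    ]
    if offenders:
        raise InputError(
            f"ROI label(s) without a hemisphere prefix ('L_'/'R_'): "
            f"{offenders[:10]}"
        )
    return [lab for lab in roi_labels if lab.startswith(prefix)]
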