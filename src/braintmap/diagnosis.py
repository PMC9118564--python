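"""Stage 1 — mapping diagnostic effects onto regional imaging traits.

For each diagnostic contrast (control group vs a pooled, stage-contiguous
case group) and each ROI, an ordinary least squares regression

    trait_roi ~ intercept + diagnosis + age + sex + education

is fitted, where diagnosis is the 0/1 case indicator. The per-ROI two-sided
p value of the diagnosis coefficient, rendered as -log10(p), forms the
imaging-diagnosis map consumed by stage 2.

The per-ROI fits share one design matrix per contrast, so all ROIs are
fitted in a single pseudoinverse multiply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CASE_STAGES,
    DiagnosisContrast,
    EffectMap,
    ImagingMatrix,
    P_FLOOR,
    PhenotypeTable,
    neglog10,
)
from .errors import InputError, StatisticalError

logger = logging.getLogger("braintmap")

DESIGN_COLUMNS = ("intercept", "diagnosis", "age", "sex", "education")


def build_contrasts(
    available_stages: tuple[str, ...] = CASE_STAGES,
) -> list[DiagnosisContrast]:
    """Enumerate every control-vs-case contrast with a contiguous case pool.

    Over the full EMCI < LMCI < AD progression this yields the six
    comparisons CN vs EMCI, CN vs LMCI, CN vs AD, CN vs EMCI+LMCI,
    CN vs LMCI+AD and CN vs EMCI+LMCI+AD; the discontiguous EMCI+AD pool
    (skipping LMCI) is never produced.
    """
    stages = tuple(available_stages)
    if not stages:
        raise InputError("available_stages must not be empty")
    order = [CASE_STAGES.index(s) for s in stages]
    if order != sorted(order):
        raise InputError(f"stages {stages} are not in progression order")
    out = []
    for i in range(len(stages)):
        for j in range(i, len(stages)):
            out.append(DiagnosisContrast(cases=stages[i : j + 1]))
    return out


def assemble_design(
    pheno: PhenotypeTable, contrast: DiagnosisContrast
) -> tuple[pd.DataFrame, list[str]]:
    """Build the regression design for one contrast.

    Subjects outside the control group and the pooled case groups are
    excluded. Returns (design, subject_ids) with design columns
    intercept, diagnosis (1 = case), age, sex, education, row-aligned with
    subject_ids.
    """
    df = pheno.frame
    keep = df["diagnosis"].isin((contrast.control,) + contrast.cases)
    sub = df.loc[keep]
    n_cases = int(sub["diagnosis"].isin(contrast.cases).sum())
    n_controls = len(sub) - n_cases
    if n_cases == 0:
        raise StatisticalError(f"{contrast.name}: no case subjects in cohort")
    if n_controls == 0:
        raise StatisticalError(f"{contrast.name}: no control subjects in cohort")
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "diagnosis": sub["diagnosis"].isin(contrast.cases).astype(float),
            "age": sub["age"].astype(float),
            "sex": sub["sex"].astype(float),
            "education": sub["education"].astype(float),
        },
        index=sub.index,
    )
    if len(design) < design.shape[1] + 2:
        raise StatisticalError(
            f"{contrast.name}: only {len(design)} usable subjects for "
            f"{design.shape[1]} regressors"
        )
    return design.reset_index(drop=True), sub["subject_id"].tolist()


def _check_rank(X: np.ndarray, columns) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name each column that is a linear combination of the others
    collinear = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        fitted, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ fitted
        scale = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(resid) < 1e-8 * scale:
            collinear.append(columns[j])
    raise StatisticalError(
        f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
        f"collinear columns: {collinear or 'undetermined'}"
    )


def _fit_all(X: np.ndarray, Y: np.ndarray, coef_index: int = 1):
    """OLS of every column of Y on the shared design X.

    Returns (beta, se, t, p) for the coefficient at coef_index, each of
    length Y.shape[1]. p is the two-sided t tail with n - p degrees of
    freedom, floored at P_FLOOR.
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y  # p x m
    resid = Y - X @ coef
    dof = n - p
    rss = (resid**2).sum(axis=0)
    # an RSS at rounding-error scale relative to the response's total sum of
    # squares is a perfect fit: force the zero-residual branch
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    rss = np.where(rss <= 1e-24 * np.maximum(tss, np.finfo(float).tiny), 0.0, rss)
    sigma2 = rss / dof
    beta = coef[coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(xtx_inv[coef_index, coef_index] * sigma2)
        t = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        # perfect fit: zero residual variance -> infinite t, p at the floor
        t[(se == 0) & (beta != 0)] = np.sign(beta[(se == 0) & (beta != 0)]) * np.inf
    pval = 2.0 * stats.t.sf(np.abs(t), dof)
    pval = np.maximum(pval, P_FLOOR)
    return beta, se, t, pval


def fit_roi_regression(
    design: pd.DataFrame, trait: np.ndarray | pd.Series
) -> dict[str, float]:
    """OLS fit of one ROI trait; returns the diagnosis-coefficient
    statistics {beta, se, t, p}."""
    X = design.to_numpy(dtype=float)
    y = np.asarray(trait, dtype=float)
    if y.shape != (X.shape[0],):
        raise InputError(
            f"trait length {y.shape} does not match design rows {X.shape[0]}"
        )
    if not np.isfinite(y).all():
        raise InputError("trait vector contains non-finite values")
    _check_rank(X, list(design.columns))
    coef_index = list(design.columns).index("diagnosis")
    beta, se, t, p = _fit_all(X, y[:, None], coef_index)
    return {"beta": float(beta[0]), "se": float(se[0]), "t": float(t[0]), "p": float(p[0])}


def effect_map(
    pheno: PhenotypeTable,
    imaging: ImagingMatrix,
    contrast: DiagnosisContrast,
    roi_subset: list[str] | None = None,
) -> EffectMap:
    """Fit the per-ROI regressions for one contrast and assemble the
    imaging-diagnosis map (records sorted by ROI label)."""
    model = DiagnosisEffectModel(pheno, imaging, contrast, roi_subset)
    return model.fit()


def significant_rois(
    effmap: EffectMap, alpha: float = 0.05, correction: str = "none"
) -> list[str]:
    """ROIs passing the chosen significance criterion (see
    :meth:`EffectMap.significant_rois`)."""
    return effmap.significant_rois(alpha, correction)


@dataclass
class DiagnosisEffectModel:
    """Stage-1 model: per-ROI covariate-adjusted diagnosis regressions.

    Parameters
    ----------
    pheno : PhenotypeTable
        Subject diagnoses and covariates.
    imaging : ImagingMatrix
        Subjects x ROIs trait values; rows are matched to ``pheno`` by
        subject_id.
    contrast : DiagnosisContrast
        Which control-vs-case comparison to estimate.
    roi_subset : list of str, optional
        ROIs to analyze (e.g. the left hemisphere); defaults to every ROI
        in ``imaging``.

    ``fit()`` returns an :class:`EffectMap` results object.
    """

    pheno: PhenotypeTable
    imaging: ImagingMatrix
    contrast: DiagnosisContrast
    roi_subset: list[str] | None = None

    def __post_init__(self) -> None:
        rois = self.roi_subset
        if rois is not None:
            unknown = set(rois) - set(self.imaging.roi_labels)
            if unknown:
                raise InputError(
                    f"roi_subset contains labels absent from the imaging "
                    f"matrix: {sorted(unknown)[:10]}"
                )
        missing = set(self.pheno.subject_ids) - set(self.imaging.subject_ids)
        if missing:
            raise InputError(
                f"{len(missing)} phenotype subject(s) missing from the "
                f"imaging matrix, e.g. {sorted(missing)[:5]}"
            )

    def fit(self) -> EffectMap:
        design, subject_ids = assemble_design(self.pheno, self.contrast)
        rois = self.roi_subset or self.imaging.roi_labels
        Y = self.imaging.frame.loc[subject_ids, rois].to_numpy(dtype=float)
        X = design.to_numpy(dtype=float)
        try:
            _check_rank(X, list(design.columns))
        except StatisticalError as err:
            raise StatisticalError(f"{self.contrast.name}: {err}") from None
        coef_index = list(design.columns).index("diagnosis")
        beta, se, t, p = _fit_all(X, Y, coef_index)
        table = pd.DataFrame(
            {
                "beta": beta,
                "se": se,
                "t": t,
                "p": p,
                "neglog10p": neglog10(p),
            },
            index=pd.Index(rois, name="roi_label"),
        )
        logger.info(
            "effect_map %s: %d subjects, %d ROIs",
            self.contrast.name, len(subject_ids), len(rois),
        )
        return EffectMap(self.contrast, table, n_subjects=len(subject_ids))
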