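"""Stage 2 — spatial correlation of gene expression maps with
imaging-diagnosis maps.

Each gene's expression values across ROIs are Pearson-correlated with the
-log10(p) vector of each contrast's effect map, over the ROIs where both are
observed (pairwise-complete deletion). The two-sided p value comes from the
t transform t = r * sqrt(n-2) / sqrt(1-r^2). Family-wise error is controlled
by Bonferroni over the *pooled* family of every (gene, contrast) test
actually performed — with no exclusions this is n_contrasts x n_genes — and
genes significant in every contrast form the cross-contrast intersection,
which an annotation gene set splits into confirmatory and novel findings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    EffectMap,
    ExpressionMatrix,
    GeneCorrelationResults,
    GeneSet,
    P_FLOOR,
)
from .errors import InputError, StatisticalError

logger = logging.getLogger("braintmap")

MIN_PAIRS = 3  # a Pearson p value needs at least 3 pairwise-complete points


def pearson_with_p(x, y) -> dict:
    """Pearson r with a two-sided t-transform p value, pairwise complete.

    Positions missing (NaN) in either vector are dropped. Returns a dict
    {r, n_used, p, usable}; fewer than 3 complete pairs or a zero-variance
    input yields usable=False (r and p are NaN), because r is then
    undefined rather than zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < MIN_PAIRS:
        return {"r": np.nan, "n_used": n, "p": np.nan, "usable": False}
    xs, ys = x[keep], y[keep]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    sxx = xc @ xc
    syy = yc @ yc
    if sxx == 0 or syy == 0:
        return {"r": np.nan, "n_used": n, "p": np.nan, "usable": False}
    r = float(np.clip((xc @ yc) / np.sqrt(sxx * syy), -1.0, 1.0))
    p = _p_from_r(np.array([r]), np.array([n]))[0]
    return {"r": r, "n_used": n, "p": float(p), "usable": True}


def _p_from_r(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t transform; |r| = 1 maps to the p floor."""
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof) / np.sqrt(1.0 - r**2)
        t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return np.maximum(p, P_FLOOR)


def correlate_genes(
    expr: ExpressionMatrix,
    effmap: EffectMap,
    target: str = "neglog10p",
) -> pd.DataFrame:
    """Correlate every gene's expression map with one effect map.

    target="neglog10p" (default) correlates against the unsigned -log10(p)
    map; target="signed" uses sign(beta) * -log10(p), a direction-aware
    variant. Genes whose pairwise-complete overlap with the map is < 3 ROIs,
    or whose used values are constant, are excluded (counted in the
    ``usable`` column as False).

    Returns a per-gene DataFrame with columns gene, contrast, r, n_used, p,
    usable (unadjusted — feed the pooled table to
    :func:`bonferroni_family`).
    """
    if target not in ("neglog10p", "signed"):
        raise InputError(f"unknown correlation target {target!r}")
    common = [lab for lab in expr.roi_labels if lab in set(effmap.roi_labels)]
    if len(common) < MIN_PAIRS:
        raise InputError(
            f"expression and effect map share only {len(common)} ROI "
            f"label(s); need at least {MIN_PAIRS}"
        )
    y = effmap.table.loc[common, "neglog10p"].to_numpy(dtype=float)
    if target == "signed":
        y = np.sign(effmap.table.loc[common, "beta"].to_numpy(dtype=float)) * y

    E = expr.frame.loc[:, common].to_numpy(dtype=float)
    obs = np.isfinite(E)
    n_used = obs.sum(axis=1)

    # pairwise-complete Pearson for all genes at once, via masked sums
    Ez = np.where(obs, E, 0.0)
    sx = Ez.sum(axis=1)
    sy = obs @ y
    sxy = Ez @ y
    sxx = (Ez**2).sum(axis=1)
    syy = obs @ (y**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n_used * sxy - sx * sy
        varx = n_used * sxx - sx**2
        vary = n_used * syy - sy**2
        r = cov / np.sqrt(varx * vary)
    # relative guard: exact-constant vectors leave varx at rounding-error scale
    usable = (
        (n_used >= MIN_PAIRS)
        & (varx > 1e-10 * n_used * np.maximum(sxx, 1e-30))
        & (vary > 1e-10 * n_used * np.maximum(syy, 1e-30))
    )
    r = np.where(usable, np.clip(r, -1.0, 1.0), np.nan)
    p = np.where(usable, _p_from_r(np.where(usable, r, 0.0), n_used), np.nan)

    out = pd.DataFrame(
        {
            "gene": expr.gene_symbols,
            "contrast": effmap.contrast.name,
            "r": r,
            "n_used": n_used,
            "p": p,
            "usable": usable,
        }
    )
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info(
            "correlate_genes %s: excluded %d unusable gene(s)",
            effmap.contrast.name, n_excluded,
        )
    return out


def bonferroni_family(
    results: pd.DataFrame, alpha: float = 0.05, per_contrast: bool = False
) -> tuple[pd.DataFrame, int]:
    """Bonferroni-adjust the pooled (gene, contrast) test family.

    family_size counts only tests actually performed (usable rows). With
    per_contrast=True the denominator is instead the per-contrast test
    count, a documented variant. Returns (adjusted table, family_size);
    the adjusted table keeps only usable rows and gains columns p_adjusted
    = min(1, p * family_size) and significant = (p_adjusted < alpha).
    """
    if not 0 < alpha < 1:
        raise StatisticalError(f"alpha must be in (0, 1), got {alpha}")
    if results.empty:
        raise StatisticalError("no correlation results to adjust")
    usable = results[results["usable"]].copy()
    if usable.empty:
        raise StatisticalError("no usable (gene, contrast) tests in the family")
    if per_contrast:
        sizes = usable.groupby("contrast")["p"].transform("size")
        usable["p_adjusted"] = np.minimum(1.0, usable["p"] * sizes)
        family_size = int(len(usable))
    else:
        family_size = int(len(usable))
        usable["p_adjusted"] = np.minimum(1.0, usable["p"] * family_size)
    usable["significant"] = usable["p_adjusted"] < alpha
    logger.info(
        "bonferroni_family: family_size=%d alpha=%g mode=%s",
        family_size, alpha, "per_contrast" if per_contrast else "pooled",
    )
    return usable, family_size


def intersect_across_contrasts(adjusted: pd.DataFrame) -> list[str]:
    """Genes significant in every contrast present, alphabetical."""
    if adjusted.empty:
        return []
    contrasts = adjusted["contrast"].unique()
    sets = [
        set(adjusted.loc[(adjusted["contrast"] == c) & adjusted["significant"], "gene"])
        for c in contrasts
    ]
    return sorted(set.intersection(*sets)) if sets else []


def partition_by_annotation(
    genes: list[str], known: GeneSet
) -> tuple[list[str], list[str]]:
    """Split genes into (known_hits, novel_hits) by annotation membership;
    both alphabetical. Membership is case-insensitive (symbols normalized
    to upper case)."""
    known_hits = sorted(g for g in genes if g in known)
    novel_hits = sorted(g for g in genes if g not in known)
    return known_hits, novel_hits


@dataclass
class SpatialCorrelationModel:
    """Stage-2 model: gene expression maps vs imaging-diagnosis maps.

    Parameters
    ----------
    expression : ExpressionMatrix
        Genes x ROIs normalized expression.
    effect_maps : list of EffectMap
        One stage-1 results object per contrast.
    target : {"neglog10p", "signed"}
        Which rendering of the effect map to correlate against.

    ``fit(alpha, per_contrast)`` returns :class:`GeneCorrelationResults`.
    """

    expression: ExpressionMatrix
    effect_maps: list[EffectMap]
    target: str = "neglog10p"

    def __post_init__(self) -> None:
        if not self.effect_maps:
            raise InputError("need at least one effect map")
        names = [m.contrast.name for m in self.effect_maps]
        if len(set(names)) != len(names):
            raise InputError(f"duplicate contrasts in effect_maps: {names}")

    def fit(
        self, alpha: float = 0.05, per_contrast: bool = False
    ) -> GeneCorrelationResults:
        per_map = [
            correlate_genes(self.expression, m, self.target)
            for m in self.effect_maps
        ]
        pooled = pd.concat(per_map, ignore_index=True)
        n_excluded = int((~pooled["usable"]).sum())
        adjusted, family_size = bonferroni_family(pooled, alpha, per_contrast)
        table = adjusted.loc[
            :, ["gene", "contrast", "r", "n_used", "p", "p_adjusted", "significant"]
        ].reset_index(drop=True)
        return GeneCorrelationResults(
            table=table,
            family_size=family_size,
            alpha=alpha,
            n_excluded=n_excluded,
            family_mode="per_contrast" if per_contrast else "pooled",
        )
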