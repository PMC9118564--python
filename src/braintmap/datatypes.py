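"""Domain containers for the two-stage brain transcriptome mapping pipeline.

All containers are thin, validated wrappers around pandas objects:

* :class:`PhenotypeTable` — per-subject diagnosis plus age/sex/education.
* :class:`ImagingMatrix` — subjects x ROIs regional trait values (SUVR role).
* :class:`ExpressionMatrix` — genes x ROIs normalized expression maps
  (missing entries are NaN).
* :class:`DiagnosisContrast` — one control-vs-pooled-cases comparison.
* :class:`EffectMap` — stage-1 results: per-ROI diagnosis coefficient,
  t statistic, p value and -log10(p) for one contrast.
* :class:`GeneCorrelationResults` — stage-2 results across genes x contrasts
  with family-wise adjusted significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, StatisticalError

#: Clinical progression used throughout: cognitively normal, early MCI,
#: late MCI, Alzheimer's disease.
STAGES = ("CN", "EMCI", "LMCI", "AD")

#: Case stages in progression order (CN is always the control).
CASE_STAGES = ("EMCI", "LMCI", "AD")

#: p values are floored here before taking -log10 so perfect fits stay finite.
P_FLOOR = 1e-300

PHENOTYPE_COLUMNS = ("subject_id", "diagnosis", "age", "sex", "education")


def neglog10(p: np.ndarray | float) -> np.ndarray | float:
    """-log10(p) with the numerical floor applied."""
    return -np.log10(np.maximum(p, P_FLOOR))


@dataclass(frozen=True)
class DiagnosisContrast:
    """A control-vs-case comparison pooling contiguous disease stages.

    Cases must be contiguous in the EMCI < LMCI < AD progression: pooling
    EMCI with AD while skipping LMCI would mix non-adjacent disease stages
    and is rejected.
    """

    cases: tuple[str, ...]
    control: str = "CN"

    def __post_init__(self) -> None:
        if not self.cases:
            raise InputError("a contrast needs at least one case stage")
        unknown = [c for c in self.cases if c not in CASE_STAGES]
        if unknown:
            raise InputError(f"unknown case stage(s): {unknown}")
        if self.control in self.cases:
            raise InputError(f"control {self.control!r} cannot also be a case")
        idx = [CASE_STAGES.index(c) for c in self.cases]
        if idx != sorted(idx) or idx != list(range(idx[0], idx[-1] + 1)):
            raise InputError(
                f"case stages {self.cases} are not contiguous in the "
                f"progression {' < '.join(CASE_STAGES)}"
            )

    @property
    def name(self) -> str:
        return f"{self.control}_vs_" + "+".join(self.cases)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


@dataclass
class PhenotypeTable:
    """Validated per-subject phenotype table.

    ``frame`` columns: subject_id (unique str), diagnosis (one of
    :data:`STAGES`), age (years), sex (1 = male, 0 = female),
    education (years). Rows with missing covariates are rejected at load.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise InputError(f"phenotype table lacks columns {missing_cols}")
        if df.empty:
            raise InputError("phenotype table is empty")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise InputError(f"duplicate subject_id(s): {dupes[:5]}")
        bad = ~df["diagnosis"].isin(STAGES)
        if bad.any():
            row = df.index[bad][0]
            raise InputError(
                f"unknown diagnosis {df.loc[row, 'diagnosis']!r} in row {row}; "
                f"allowed: {STAGES}"
            )
        if df[list(PHENOTYPE_COLUMNS)].isna().any().any():
            raise InputError("phenotype table contains missing values after load")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].tolist()

    def group_counts(self) -> dict[str, int]:
        counts = self.frame["diagnosis"].value_counts()
        return {s: int(counts.get(s, 0)) for s in STAGES}


@dataclass
class ImagingMatrix:
    """Subjects x ROIs continuous regional trait values (e.g. AV45 SUVR)."""

    frame: pd.DataFrame  # index: subject_id, columns: roi_label

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise InputError("duplicate subject_id rows in imaging matrix")
        if self.frame.columns.duplicated().any():
            raise InputError("duplicate ROI labels in imaging matrix")
        values = self.frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise InputError("imaging matrix contains non-finite values")
        self.frame.index.name = "subject_id"
        self.frame.columns.name = None

    @property
    def subject_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def roi_labels(self) -> list[str]:
        return self.frame.columns.tolist()


@dataclass
class ExpressionMatrix:
    """Genes x ROIs normalized expression; NaN marks a missing (gene, ROI)."""

    frame: pd.DataFrame  # index: gene_symbol, columns: roi_label

    #: genes dropped at load for having < MIN_ROIS non-missing values
    MIN_ROIS = 3

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise InputError(f"duplicate gene symbol(s): {dupes[:5]}")
        if self.frame.columns.duplicated().any():
            raise InputError("duplicate ROI labels in expression matrix")
        if self.frame.shape[1] == 0:
            raise InputError("expression matrix has no ROI columns")
        self.frame.index.name = "gene"
        self.frame.columns.name = None

    @property
    def gene_symbols(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def roi_labels(self) -> list[str]:
        return self.frame.columns.tolist()

    def n_observed(self) -> pd.Series:
        """Number of non-missing ROI values per gene."""
        return self.frame.notna().sum(axis=1)


class GeneSet(frozenset):
    """A disease-gene annotation set; symbols are upper-cased on construction
    because annotation databases and expression atlases disagree on case."""

    def __new__(cls, symbols: Iterable[str] = ()):  # noqa: D102
        cleaned = {s.strip().upper() for s in symbols if s and s.strip()}
        return super().__new__(cls, cleaned)

    def __contains__(self, symbol: object) -> bool:
        if isinstance(symbol, str):
            symbol = symbol.strip().upper()
        return super().__contains__(symbol)


EFFECT_MAP_COLUMNS = ("beta", "se", "t", "p", "neglog10p")


@dataclass
class EffectMap:
    """Stage-1 results object: the imaging-diagnosis map for one contrast.

    ``table`` is indexed by roi_label (sorted) with columns beta, se, t, p,
    neglog10p, where beta/t/p refer to the binary diagnosis coefficient of
    the covariate-adjusted per-ROI regression.
    """

    contrast: DiagnosisContrast
    table: pd.DataFrame
    n_subjects: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in EFFECT_MAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"effect map lacks columns {missing}")
        self.table = self.table.sort_index()
        p = self.table["p"].to_numpy()
        if ((p <= 0) | (p > 1)).any():
            raise InputError("effect map p values must lie in (0, 1]")

    @property
    def roi_labels(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def neglog10p(self) -> pd.Series:
        return self.table["neglog10p"]

    def significant_rois(
        self, alpha: float = 0.05, correction: str = "none"
    ) -> list[str]:
        """ROI labels passing the significance criterion.

        correction="bonferroni" divides alpha by the number of ROIs in the
        map; "none" thresholds the raw p values.
        """
        if not 0 < alpha < 1:
            raise StatisticalError(f"alpha must be in (0, 1), got {alpha}")
        if correction not in ("none", "bonferroni"):
            raise InputError(f"unknown correction {correction!r}")
        threshold = alpha / len(self.table) if correction == "bonferroni" else alpha
        return self.table.index[self.table["p"] < threshold].tolist()

    def summary(self, top_k: int = 10) -> str:
        """Human-readable summary: contrast, subjects, and top ROIs by
        -log10(p)."""
        top = self.table.nlargest(top_k, "neglog10p")
        lines = [
            f"Imaging-diagnosis map: {self.contrast.name}",
            f"  subjects: {self.n_subjects}, ROIs: {len(self.table)}",
            f"  ROIs with p < 0.05 (raw): {len(self.significant_rois())}",
            f"  top {len(top)} ROIs by -log10(p):",
        ]
        for roi, row in top.iterrows():
            lines.append(
                f"    {roi:<16} beta={row.beta:+.4f}  t={row.t:+.2f}  "
                f"-log10(p)={row.neglog10p:.2f}"
            )
        return "\n".join(lines)


RESULT_COLUMNS = ("gene", "contrast", "r", "n_used", "p", "p_adjusted", "significant")


@dataclass
class GeneCorrelationResults:
    """Stage-2 results: spatial gene-map correlations across all contrasts.

    ``table`` has one row per usable (gene, contrast) test with columns
    gene, contrast, r, n_used, p, p_adjusted, significant. ``family_size``
    is the Bonferroni denominator actually used (tests performed, after
    unusable-gene exclusion).
    """

    table: pd.DataFrame
    family_size: int
    alpha: float
    n_excluded: int = 0
    family_mode: str = "pooled"

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"results table lacks columns {missing}")

    @property
    def contrasts(self) -> list[str]:
        return sorted(self.table["contrast"].unique())

    def significant_genes(self, contrast: str) -> set[str]:
        t = self.table
        mask = (t["contrast"] == contrast) & t["significant"]
        return set(t.loc[mask, "gene"])

    def intersection(self) -> list[str]:
        """Genes significant in every contrast present, alphabetical."""
        sets = [self.significant_genes(c) for c in self.contrasts]
        if not sets:
            return []
        common = set.intersection(*sets)
        return sorted(common)

    def partition(self, known: GeneSet) -> tuple[list[str], list[str]]:
        """Split the all-contrast intersection into annotation-known
        (confirmatory) and novel genes, both alphabetical."""
        genes = self.intersection()
        known_hits = sorted(g for g in genes if g in known)
        novel_hits = sorted(g for g in genes if g not in known)
        return known_hits, novel_hits

    def summary(self) -> str:
        lines = [
            "Spatial gene-map correlation results",
            f"  family size (Bonferroni denominator, {self.family_mode}): "
            f"{self.family_size}",
            f"  alpha: {self.alpha}",
            f"  unusable (gene, contrast) tests excluded: {self.n_excluded}",
            "  significant genes per contrast:",
        ]
        for c in self.contrasts:
            lines.append(f"    {c:<24} {len(self.significant_genes(c))}")
        inter = self.intersection()
        lines.append(f"  genes significant in all contrasts: {len(inter)}")
        if inter:
            lines.append("    " + ", ".join(inter))
        return "\n".join(lines)
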