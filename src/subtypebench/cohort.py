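"""Domain model for multi-dataset neoadjuvant-chemotherapy response cohorts.

A cohort couples a gene-level log2 expression matrix (genes x samples) with a
per-sample clinical table (receptor status, age, grade, TNM stage, binary
pathological-complete-response endpoint, and dataset of origin).  Clinical
subtypes are derived from ER and HER2 immunohistochemistry status:

    HER2+            her2 positive (any ER), refined into HER2+/ER- and HER2+/ER+
    Luminal          her2 negative, er positive
    Triple Negative  her2 negative, er negative

pCR ("pathological complete response") means no residual invasive cancer in
the breast and axillary lymph nodes after neoadjuvant therapy; it is the
binary endpoint every predictor in this package targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import numpy as np
import pandas as pd

RESPONSE_LEVELS = ("pCR", "no_pCR")
STATUS_LEVELS = ("positive", "negative")

#: clinical features used by clinical-modality predictors, in canonical order
CLINICAL_FEATURES = ("er", "pr", "her2", "age", "grade", "tnm_stage")

#: measurement kind of each clinical feature (drives encoding/discretization)
CLINICAL_KINDS = {
    "er": "binary",
    "pr": "binary",
    "her2": "binary",
    "age": "continuous",
    "grade": "ordinal",
    "tnm_stage": "ordinal",
}

CLINICAL_COLUMNS = ("dataset_id",) + CLINICAL_FEATURES + ("response",)


class CohortError(ValueError):
    """Raised when input tables violate the cohort contract."""


class Subtype(str, Enum):
    """Clinical breast-cancer subtype labels (coarse plus HER2+ refinements)."""

    HER2_POS = "HER2_POS"
    LUMINAL = "LUMINAL"
    TN = "TN"
    HER2_POS_ER_NEG = "HER2_POS_ER_NEG"
    HER2_POS_ER_POS = "HER2_POS_ER_POS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


COARSE_SUBTYPES = (Subtype.HER2_POS, Subtype.LUMINAL, Subtype.TN)
REFINED_CELLS = (
    Subtype.HER2_POS_ER_NEG,
    Subtype.HER2_POS_ER_POS,
    Subtype.LUMINAL,
    Subtype.TN,
)


@dataclass(frozen=True)
class SubtypeLabel:
    """Coarse subtype plus, for HER2+ samples, the ER-based refinement."""

    coarse: Subtype
    refinement: Optional[Subtype] = None


@dataclass(frozen=True)
class Sample:
    sample_id: str
    er: str
    pr: Optional[str]
    her2: str
    age: Optional[float]
    grade: Optional[int]
    tnm_stage: Optional[int]
    response: str
    dataset_id: str


def assign_subtype(er: str, her2: str, sample_id: str = "<sample>") -> SubtypeLabel:
    """Map ER/HER2 status to a subtype label.

    HER2 positivity dominates: Luminal and Triple Negative require HER2-.
    HER2+ samples additionally carry the ER-based refinement.

    Raises
    ------
    CohortError
        If either status is missing or not in {positive, negative}.
    """
    for name, value in (("er", er), ("her2", her2)):
        if value not in STATUS_LEVELS:
            raise CohortError(
                f"sample {sample_id!r}: {name} status {value!r} is missing or "
                f"not one of {STATUS_LEVELS}"
            )
    if her2 == "positive":
        refinement = (
            Subtype.HER2_POS_ER_NEG if er == "negative" else Subtype.HER2_POS_ER_POS
        )
        return SubtypeLabel(Subtype.HER2_POS, refinement)
    if er == "positive":
        return SubtypeLabel(Subtype.LUMINAL)
    return SubtypeLabel(Subtype.TN)


def subtype_matches(label: SubtypeLabel, subtype: Subtype) -> bool:
    """Whether a sample's label falls inside ``subtype`` (coarse or refined)."""
    return label.coarse == subtype or label.refinement == subtype


@dataclass
class Cohort:
    """Aligned expression matrix and clinical table for one set of samples.

    ``expression`` is genes x samples (log2 intensities); its column order is
    the clinical table's row order.  All expression values must be finite;
    er/her2/response must be non-missing for every sample.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        expr, clin = self.expression, self.clinical
        if list(expr.columns) != list(clin.index):
            only_expr = set(expr.columns) - set(clin.index)
            only_clin = set(clin.index) - set(expr.columns)
            raise CohortError(
                "expression columns and clinical rows disagree: "
                f"expression-only={sorted(map(str, only_expr))}, "
                f"clinical-only={sorted(map(str, only_clin))}, "
                "or ordering differs"
            )
        if expr.columns.duplicated().any():
            dupes = expr.columns[expr.columns.duplicated()].tolist()
            raise CohortError(f"duplicate sample ids: {dupes}")
        if expr.index.duplicated().any():
            dupes = expr.index[expr.index.duplicated()].tolist()
            raise CohortError(f"duplicate gene ids: {dupes}")
        values = expr.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CohortError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            bad = expr.columns[np.where(~np.isfinite(values))[1]].unique().tolist()
            raise CohortError(f"non-finite expression values in samples {bad}")
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
        if missing_cols:
            raise CohortError(f"clinical table missing columns {missing_cols}")
        for col, levels in (
            ("er", STATUS_LEVELS),
            ("her2", STATUS_LEVELS),
            ("response", RESPONSE_LEVELS),
        ):
            bad = clin.index[~clin[col].isin(levels)].tolist()
            if bad:
                raise CohortError(
                    f"column {col!r} missing or invalid for samples {bad}"
                )
        bad_pr = clin.index[clin["pr"].notna() & ~clin["pr"].isin(STATUS_LEVELS)]
        if len(bad_pr):
            raise CohortError(f"invalid pr status for samples {bad_pr.tolist()}")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    def samples(self) -> list[Sample]:
        out = []
        for sid, row in self.clinical.iterrows():
            out.append(
                Sample(
                    sample_id=str(sid),
                    er=row["er"],
                    pr=row["pr"] if pd.notna(row["pr"]) else None,
                    her2=row["her2"],
                    age=float(row["age"]) if pd.notna(row["age"]) else None,
                    grade=int(row["grade"]) if pd.notna(row["grade"]) else None,
                    tnm_stage=int(row["tnm_stage"])
                    if pd.notna(row["tnm_stage"])
                    else None,
                    response=row["response"],
                    dataset_id=str(row["dataset_id"]),
                )
            )
        return out

    def subtype_labels(self) -> pd.Series:
        """Per-sample :class:`SubtypeLabel`, index-aligned with the clinical table."""
        return self.clinical.apply(
            lambda r: assign_subtype(r["er"], r["her2"], str(r.name)), axis=1
        )

    def subset(self, sample_ids: Iterable[str]) -> "Cohort":
        ids = list(sample_ids)
        return Cohort(self.expression[ids], self.clinical.loc[ids])

    def responses(self) -> pd.Series:
        """Binary endpoint: 1 = pCR, 0 = no pCR."""
        return (self.clinical["response"] == "pCR").astype(int)


def concat_cohorts(cohorts: Iterable[Cohort]) -> Cohort:
    """Pool several (harmonized) cohorts into one; gene sets must agree."""
    cohorts = list(cohorts)
    genes = cohorts[0].gene_ids
    for c in cohorts[1:]:
        if c.gene_ids != genes:
            raise CohortError("cohorts have different gene sets/orders; harmonize first")
    expr = pd.concat([c.expression for c in cohorts], axis=1)
    clin = pd.concat([c.clinical for c in cohorts], axis=0)
    return Cohort(expr, clin)


# -- I/O ---------------------------------------------------------------------


def read_cohort(expression_path, clinical_path) -> Cohort:
    """Read a cohort from the two TSV files.

    Expression TSV: first column gene_id, remaining columns sample ids, log2
    values.  Clinical TSV: sample_id, dataset_id, er, pr, her2, age, grade,
    tnm_stage, response; empty cell = missing.  Samples present in only one
    file are rejected with their ids named.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    try:
        expr = expr.astype(float)
    except ValueError as exc:
        raise CohortError(f"non-numeric expression value: {exc}") from exc
    clin = pd.read_csv(clinical_path, sep="\t", index_col="sample_id", dtype=str)
    clin.index = clin.index.astype(str)
    clin.index.name = "sample_id"
    for col in ("age",):
        if col in clin:
            clin[col] = pd.to_numeric(clin[col], errors="raise")
    for col in ("grade", "tnm_stage"):
        if col in clin:
            clin[col] = pd.to_numeric(clin[col], errors="raise").astype("Float64")
    clin = clin.reindex(columns=list(CLINICAL_COLUMNS))
    if set(expr.columns) != set(clin.index):
        raise CohortError(
            "sample ids differ between files: "
            f"expression-only={sorted(set(expr.columns) - set(clin.index))}, "
            f"clinical-only={sorted(set(clin.index) - set(expr.columns))}"
        )
    clin = clin.loc[expr.columns]
    return Cohort(expr, clin)


def write_cohort(cohort: Cohort, expression_path, clinical_path) -> None:
    expr = cohort.expression.copy()
    expr.index.name = "gene_id"
    expr.to_csv(expression_path, sep="\t", float_format="%.6f")
    clin = cohort.clinical.copy()
    clin.index.name = "sample_id"
    for col in ("grade", "tnm_stage"):  # canonical integer form on disk
        clin[col] = pd.to_numeric(clin[col], errors="coerce").round().astype("Int64")
    clin.to_csv(clinical_path, sep="\t")


# -- composition tables ------------------------------------------------------


def percentage(count: int, total: int) -> int:
    """Integer percentage with half-up rounding, as printed in clinical tables."""
    return int(math.floor(100.0 * count / total + 0.5))


def composition_percentages(n_pcr: int, n_no_pcr: int) -> tuple:
    """(pCR%, no-pCR%) for one stratum row; blank strings for an empty row."""
    total = n_pcr + n_no_pcr
    if total == 0:
        return ("", "")
    return (percentage(n_pcr, total), percentage(n_no_pcr, total))


def subtype_composition(cohort: Cohort) -> pd.DataFrame:
    """Counts and integer percentages of pCR / no-pCR per subtype stratum.

    Rows: the three coarse subtypes, the two HER2+ refinements, and "All".
    Percentages are within-row and rounded half-up; an empty stratum gets
    zero counts and blank percentages.
    """
    labels = cohort.subtype_labels()
    y = cohort.responses()
    rows = []
    strata = list(COARSE_SUBTYPES) + [Subtype.HER2_POS_ER_NEG, Subtype.HER2_POS_ER_POS]
    for st in strata:
        mask = labels.apply(lambda l, st=st: subtype_matches(l, st))
        n_pcr = int(((y == 1) & mask).sum())
        n_no = int(((y == 0) & mask).sum())
        rows.append((st.value, n_pcr, n_no))
    rows.append(("All", int(y.sum()), int((y == 0).sum())))
    table = pd.DataFrame(rows, columns=["stratum", "pCR", "no_pCR"]).set_index("stratum")
    pct = table.apply(
        lambda r: composition_percentages(r["pCR"], r["no_pCR"]), axis=1
    )
    table["pCR_pct"] = [p[0] for p in pct]
    table["no_pCR_pct"] = [p[1] for p in pct]
    return table


# -- clinical feature matrix -------------------------------------------------


def clinical_table(cohort: Cohort) -> tuple[pd.DataFrame, dict]:
    """Complete-case numeric clinical feature matrix (samples x 6 features).

    Encoding: er/pr/her2 as 0/1 (positive = 1), grade and TNM stage as ordered
    integers, age continuous.  Samples missing any of the six features are
    dropped (complete-case policy: the clinical modality analyses a subset of
    the expression cohort).  Returns (matrix, kinds).
    """
    clin = cohort.clinical
    X = pd.DataFrame(index=clin.index)
    for col in ("er", "pr", "her2"):
        X[col] = clin[col].map({"positive": 1.0, "negative": 0.0})
    X["age"] = pd.to_numeric(clin["age"], errors="coerce")
    X["grade"] = pd.to_numeric(clin["grade"], errors="coerce")
    X["tnm_stage"] = pd.to_numeric(clin["tnm_stage"], errors="coerce")
    X = X.dropna(axis=0, how="any").astype(float)
    return X, dict(CLINICAL_KINDS)
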