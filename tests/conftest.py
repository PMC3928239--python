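"""Shared fixture builders: tiny deterministic cohorts assembled in memory."""

import numpy as np
import pandas as pd
import pytest

from subtypebench.cohort import Cohort


def build_clinical(rows):
    """Clinical table from tuples of
    (sample_id, dataset, er, pr, her2, age, grade, stage, response)."""
    frame = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "dataset_id", "er", "pr", "her2",
            "age", "grade", "tnm_stage", "response",
        ],
    ).set_index("sample_id")
    return frame


def build_cohort(rows, n_genes=3, seed=0, expression=None):
    clin = build_clinical(rows)
    if expression is None:
        rng = np.random.default_rng(seed)
        expression = pd.DataFrame(
            rng.normal(size=(n_genes, len(clin))),
            index=[f"G{i}" for i in range(n_genes)],
            columns=clin.index,
        )
    return Cohort(expression, clin)


@pytest.fixture
def tiny_cohort():
    rows = [
        ("S1", "D1", "negative", "negative", "positive", 45.0, 2, 2, "pCR"),
        ("S2", "D1", "positive", "positive", "negative", 52.0, 3, 1, "no_pCR"),
        ("S3", "D1", "negative", "negative", "negative", 61.0, 1, 3, "pCR"),
        ("S4", "D1", "positive", "positive", "negative", 38.0, 2, 2, "no_pCR"),
    ]
    return build_cohort(rows, n_genes=3)


def balanced_rows(n_per_cell, cells=None, dataset="D1", start=0):
    """n_per_cell samples in each (refined subtype, response) cell."""
    if cells is None:
        cells = [
            ("negative", "positive", "pCR"), ("negative", "positive", "no_pCR"),
            ("positive", "negative", "pCR"), ("positive", "negative", "no_pCR"),
            ("negative", "negative", "pCR"), ("negative", "negative", "no_pCR"),
        ]
    rows = []
    i = start
    for er, her2, resp in cells:
        for _ in range(n_per_cell):
            rows.append((f"{dataset}_S{i:03d}", dataset, er, er, her2,
                         40.0 + (i % 20), 1 + (i % 3), 1 + (i % 3), resp))
            i += 1
    return rows
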