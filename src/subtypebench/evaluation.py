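"""AUC estimation and specific-vs-generic comparison statistics.

The AUC uses the Mann-Whitney formulation: the probability that a random
responder scores above a random non-responder, counting tied score pairs as
half-concordant.  A predictor whose score is constant on a validation set
therefore attains exactly 0.5 -- the collapse a generic predictor suffers
when every feature it selected is constant within the validated subgroup.

Per (subtype x modality) the best subtype-specific and best generic predictor
configurations (by mean AUC over outer repetitions) are compared with a
two-sided t-test (Welch by default) and Bonferroni correction over the
declared comparison family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied) / (n_pos * n_neg).

    Computed from average ranks, which implements the half-credit tie
    convention exactly.  Raises if either class is absent.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one response class is absent")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ComparisonOutcome:
    subtype: str
    modality: str
    specific_config: str
    specific_mean_auc: float
    generic_config: str
    generic_mean_auc: float
    n_specific: int
    n_generic: int
    t_statistic: float
    p_raw: float
    p_adjusted: float
    family_size: int
    significant: bool
    testable: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def compare(
    specific_aucs,
    generic_aucs,
    family_size: int = 1,
    paired: bool = False,
    subtype: str = "",
    modality: str = "",
    specific_config: str = "",
    generic_config: str = "",
    alpha: float = 0.05,
) -> ComparisonOutcome:
    """Two-sided t-test (Welch unless ``paired``) on two AUC distributions.

    Missing cells must already be excluded.  Bonferroni: adjusted p =
    min(1, family_size * raw p).  Fewer than 2 values on either side flags
    the outcome untestable (p = NaN, not significant).
    """
    a = np.asarray(specific_aucs, dtype=float)
    b = np.asarray(generic_aucs, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    base = dict(
        subtype=subtype,
        modality=modality,
        specific_config=specific_config,
        generic_config=generic_config,
        specific_mean_auc=float(a.mean()) if len(a) else float("nan"),
        generic_mean_auc=float(b.mean()) if len(b) else float("nan"),
        n_specific=len(a),
        n_generic=len(b),
        family_size=int(family_size),
    )
    if len(a) < 2 or len(b) < 2 or (paired and len(a) != len(b)):
        return ComparisonOutcome(
            **base, t_statistic=float("nan"), p_raw=float("nan"),
            p_adjusted=float("nan"), significant=False, testable=False,
        )
    if paired:
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance on both sides and equal means
        p = 1.0
        t = 0.0
    p_adj = min(1.0, family_size * p)
    return ComparisonOutcome(
        **base, t_statistic=t, p_raw=p, p_adjusted=p_adj,
        significant=bool(p_adj < alpha),
    )


def config_name(row) -> str:
    ranker = row["ranker"] if isinstance(row["ranker"], str) else "embedded"
    return f"{row['classifier']}-{ranker}"


def best_predictor(
    auc_table: pd.DataFrame, subtype: str, scope: str, modality: str
) -> tuple[str, float]:
    """(config name, mean AUC) of the best configuration for one cell.

    Mean is over repetitions with non-missing AUC.  Ties break to the
    configuration with fewer selected features (mean over repetitions), then
    lexicographic config name.
    """
    cell = auc_table[
        (auc_table["subtype"] == subtype)
        & (auc_table["scope"] == scope)
        & (auc_table["modality"] == modality)
        & auc_table["auc"].notna()
    ]
    if cell.empty:
        raise ValueError(f"no AUC values for {subtype}/{scope}/{modality}")
    grouped = (
        cell.assign(config=cell.apply(config_name, axis=1))
        .groupby("config")
        .agg(mean_auc=("auc", "mean"), mean_n=("n_features_selected", "mean"))
        .reset_index()
    )
    grouped = grouped.sort_values(
        ["mean_auc", "mean_n", "config"], ascending=[False, True, True],
        kind="mergesort",
    )
    top = grouped.iloc[0]
    return str(top["config"]), float(top["mean_auc"])


def _config_aucs(
    auc_table: pd.DataFrame, subtype: str, scope: str, modality: str, config: str
) -> np.ndarray:
    cell = auc_table[
        (auc_table["subtype"] == subtype)
        & (auc_table["scope"] == scope)
        & (auc_table["modality"] == modality)
    ]
    cell = cell[cell.apply(config_name, axis=1) == config]
    return cell["auc"].to_numpy(dtype=float)


def compare_table(
    auc_table: pd.DataFrame,
    family_size: Optional[int] = None,
    paired: bool = False,
    alpha: float = 0.05,
) -> list[ComparisonOutcome]:
    """Best-specific vs best-generic comparison per (subtype, modality).

    Family size defaults to the number of comparisons actually performed.
    """
    cells = (
        auc_table[["subtype", "modality"]]
        .drop_duplicates()
        .sort_values(["modality", "subtype"])
        .itertuples(index=False)
    )
    cells = [(c.subtype, c.modality) for c in cells]
    m = family_size if family_size is not None else len(cells)
    outcomes = []
    for subtype, modality in cells:
        best_s, mean_s = best_predictor(auc_table, subtype, "specific", modality)
        best_g, mean_g = best_predictor(auc_table, subtype, "generic", modality)
        a = _config_aucs(auc_table, subtype, "specific", modality, best_s)
        b = _config_aucs(auc_table, subtype, "generic", modality, best_g)
        if paired:
            keep = ~np.isnan(a) & ~np.isnan(b)
            a, b = a[keep], b[keep]
        outcomes.append(
            compare(
                a, b, family_size=m, paired=paired, subtype=subtype,
                modality=modality, specific_config=best_s,
                generic_config=best_g, alpha=alpha,
            )
        )
    return outcomes


def boxplot_data(auc_table: pd.DataFrame) -> pd.DataFrame:
    """Per-box AUC values for external plotting: one row per repetition of the
    best config in each (subtype, modality, scope) cell."""
    rows = []
    cells = auc_table[["subtype", "modality", "scope"]].drop_duplicates()
    for _, cell in cells.iterrows():
        config, _ = best_predictor(
            auc_table, cell["subtype"], cell["scope"], cell["modality"]
        )
        vals = auc_table[
            (auc_table["subtype"] == cell["subtype"])
            & (auc_table["scope"] == cell["scope"])
            & (auc_table["modality"] == cell["modality"])
        ]
        vals = vals[vals.apply(config_name, axis=1) == config]
        for _, r in vals.iterrows():
            rows.append(
                dict(
                    subtype=cell["subtype"], modality=cell["modality"],
                    scope=cell["scope"], config=config,
                    repetition=r["repetition"], auc=r["auc"],
                )
            )
    return pd.DataFrame(rows)


def report(
    auc_table: pd.DataFrame,
    outcomes: list[ComparisonOutcome],
    out_dir,
) -> dict:
    """Write the comparison report: best-config grid, full AUC grid, boxplot
    data, and a JSON summary.  Deterministic for a fixed AUC table."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    best_rows = []
    for o in outcomes:
        best_rows.append(
            dict(
                subtype=o.subtype, modality=o.modality,
                specific=o.specific_config, specific_mean_auc=round(o.specific_mean_auc, 6),
                generic=o.generic_config, generic_mean_auc=round(o.generic_mean_auc, 6),
                p_adjusted=o.p_adjusted, significant=o.significant,
            )
        )
    best_grid = pd.DataFrame(best_rows).sort_values(["modality", "subtype"])
    best_grid.to_csv(out / "best_predictors.tsv", sep="\t", index=False)

    full = (
        auc_table.assign(config=auc_table.apply(config_name, axis=1))
        .groupby(["modality", "subtype", "scope", "config"])["auc"]
        .mean()
        .reset_index()
        .sort_values(["modality", "subtype", "scope", "config"])
    )
    full.to_csv(out / "auc_grid.tsv", sep="\t", index=False, float_format="%.6f")

    boxes = boxplot_data(auc_table).sort_values(
        ["modality", "subtype", "scope", "repetition"]
    )
    boxes.to_csv(out / "boxplot_data.tsv", sep="\t", index=False, float_format="%.6f")

    summary = {
        "outcomes": [o.to_dict() for o in outcomes],
        "family_size": outcomes[0].family_size if outcomes else 0,
        "n_rows": int(len(auc_table)),
        "n_missing_cells": int(auc_table["auc"].isna().sum()),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
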