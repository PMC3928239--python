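"""Double-loop cross-validation engine.

Outer loop: the cohort is split 2/3 train / 1/3 validation, stratified on
(refined subtype x response) so both subtype mix and response rate are
preserved on each side; the split is redrawn for each of R repetitions
(default 15).  Inner loop: on the training portion alone, a stratified 3-fold
cross-validation picks the feature count (from a grid) that maximizes the
mean fold AUC for each (ranker, classifier) combination.

Two training scopes are evaluated against the *same* validation samples of a
subtype: the subtype-specific scope trains only on that subtype's training
samples, the generic scope trains on all training samples.  Sharing the
outer split between scopes means an AUC difference cannot be an artefact of
different test sets.

A per-phase audit callback can observe every sample id touched, which the
test suite uses to assert that no validation sample leaks into ranking,
inner-loop selection, or fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from .cohort import (
    CLINICAL_KINDS,
    Cohort,
    Subtype,
    assign_subtype,
    clinical_table,
    subtype_matches,
)
from .evaluation import auc
from .ranking import CLINICAL_RANKERS, EXPRESSION_RANKERS, rank_features

DEFAULT_GRID_EXPRESSION = (1, 2, 5, 10, 20, 30, 50, 100)
DEFAULT_GRID_CLINICAL = (1, 2, 3, 4, 5, 6)
MODALITIES = ("expression", "clinical")

AuditFn = Callable[..., None]


@dataclass(frozen=True)
class PredictorConfig:
    """One (modality, ranker, classifier) combination.

    The decision tree carries its own embedded feature selection and has
    ranker ``"embedded"``; all other classifiers pair with each of the
    modality's three rankers, giving 3 x 5 + 1 = 16 configurations per
    modality.
    """

    modality: str
    ranker: str
    classifier: str

    @property
    def name(self) -> str:
        return f"{self.classifier}-{self.ranker}"


def enumerate_configs(modality: str) -> list[PredictorConfig]:
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    rankers = EXPRESSION_RANKERS if modality == "expression" else CLINICAL_RANKERS
    configs = [
        PredictorConfig(modality, r, c)
        for r in rankers
        for c in ("NB", "NM", "3NN", "LREG", "SVM")
    ]
    configs.append(PredictorConfig(modality, "embedded", "TREE"))
    return configs


@dataclass(frozen=True)
class EvaluationScope:
    """Training scope (a subtype, or None = generic) and validation subtype."""

    train_subtype: Optional[Subtype]
    validation_subtype: Subtype

    @property
    def scope_name(self) -> str:
        return "generic" if self.train_subtype is None else "specific"


def default_scopes(subtypes: Sequence[Subtype]) -> list[EvaluationScope]:
    """Specific and generic training scope per subtype, validated identically."""
    scopes = []
    for st in subtypes:
        scopes.append(EvaluationScope(st, st))
        scopes.append(EvaluationScope(None, st))
    return scopes


@dataclass
class SplitPlan:
    repetition: int
    train_ids: list
    validation_ids: list
    strata: dict  # sample_id -> stratum key
    seed: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _strata_keys(clinical: pd.DataFrame, min_stratum: int = 3) -> pd.Series:
    """(refined subtype, response) stratum per sample; cells smaller than
    ``min_stratum`` are merged into their subtype's other response cell."""

    def key(row):
        label = assign_subtype(row["er"], row["her2"], str(row.name))
        cell = label.refinement or label.coarse
        return f"{cell.value}|{row['response']}"

    keys = clinical.apply(key, axis=1)
    counts = keys.value_counts()
    merged = keys.copy()
    for stratum, n in counts.items():
        if n < min_stratum:
            # fold the undersized cell into its subtype's other response cell:
            # both become a single subtype-level stratum
            subtype = stratum.split("|")[0]
            merged[keys.str.startswith(subtype + "|")] = subtype
    return merged


def make_split(
    clinical: pd.DataFrame,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    min_stratum: int = 3,
    repetition: int = 0,
) -> SplitPlan:
    """Stratified 2/3-1/3 split: per stratum, round-half-up(fraction * n)
    samples go to training (seeded shuffle within stratum), the rest to
    validation."""
    strata = _strata_keys(clinical, min_stratum=min_stratum)
    counts = strata.value_counts()
    too_small = [s for s, n in counts.items() if n < 2]
    if too_small:
        raise ValueError(
            f"strata with fewer than 2 samples even after merging: {too_small}"
        )
    rng = np.random.default_rng(seed)
    train: list = []
    validation: list = []
    for stratum in sorted(counts.index):
        members = sorted(strata.index[strata == stratum].astype(str))
        order = rng.permutation(len(members))
        n_train = _round_half_up(fraction * len(members))
        n_train = min(max(n_train, 1), len(members) - 1)  # both sides non-empty
        for i, idx in enumerate(order):
            (train if i < n_train else validation).append(members[idx])
    pos = {sid: i for i, sid in enumerate(clinical.index.astype(str))}
    train.sort(key=pos.__getitem__)
    validation.sort(key=pos.__getitem__)
    return SplitPlan(
        repetition=repetition,
        train_ids=train,
        validation_ids=validation,
        strata=strata.to_dict(),
        seed=seed,
    )


def inner_optimal_n(
    X: pd.DataFrame,
    y: pd.Series,
    config: PredictorConfig,
    grid: Sequence[int],
    kinds: Optional[dict] = None,
    n_folds: int = 3,
    seed: int = 0,
    _fold_cache: Optional[dict] = None,
) -> int:
    """Feature count maximizing mean stratified-k-fold AUC on the training set.

    The ranker is fit on each fold's training part only.  Mean AUCs are
    rounded to 1e-12 before the argmax; ties go to the smallest n.  A fold
    draw that leaves a side single-class is redrawn with a new seed (up to 10
    attempts).
    """
    if config.ranker == "embedded":
        raise ValueError("the tree's embedded selection has no feature-count grid")
    if not len(grid):
        raise ValueError("empty feature-count grid")
    grid = sorted({min(int(n), X.shape[1]) for n in grid})
    if len(grid) == 1:
        return grid[0]
    folds, fold_rankings = _inner_folds(X, y, kinds, config.ranker, n_folds, seed, _fold_cache)
    mean_aucs = []
    for n in grid:
        fold_aucs = []
        for (tr_idx, te_idx), ranking in zip(folds, fold_rankings):
            feats = ranking.top(n)
            model = clf.fit(config.classifier, X.iloc[tr_idx][feats], y.iloc[tr_idx], kinds)
            scores = model.score(X.iloc[te_idx][feats])
            fold_aucs.append(auc(scores, y.iloc[te_idx]))
        mean_aucs.append(round(float(np.mean(fold_aucs)), 12))
    best = int(np.argmax(mean_aucs))  # argmax takes the first = smallest n on ties
    return grid[best]


def _inner_folds(X, y, kinds, ranker, n_folds, seed, cache):
    """Stratified folds plus the per-fold-train ranking, with optional caching
    keyed on (ranker,) so multiple classifiers reuse the fold rankings."""
    key = ("folds", n_folds, seed)
    if cache is not None and key in cache:
        folds = cache[key]
    else:
        folds = _draw_folds(y, n_folds, seed)
        if cache is not None:
            cache[key] = folds
    rkey = ("rank", ranker, n_folds, seed)
    if cache is not None and rkey in cache:
        return folds, cache[rkey]
    rankings = [rank_features(ranker, X.iloc[tr], y.iloc[tr], kinds) for tr, _ in folds]
    if cache is not None:
        cache[rkey] = rankings
    return folds, rankings


def _draw_folds(y, n_folds, seed):
    yv = np.asarray(y).astype(int)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) + attempt)
        folds = list(skf.split(np.zeros(len(yv)), yv))
        if all(
            len(np.unique(yv[tr])) == 2 and len(np.unique(yv[te])) == 2
            for tr, te in folds
        ):
            return folds
    raise ValueError("could not draw inner folds with both classes on both sides")


def _modality_data(cohort: Cohort, modality: str):
    """(feature matrix samples x features, kinds, clinical subset) per modality."""
    if modality == "expression":
        X = cohort.expression.T.copy()
        X.index = X.index.astype(str)
        return X, None, cohort.clinical
    if modality == "clinical":
        X, kinds = clinical_table(cohort)
        return X, kinds, cohort.clinical.loc[X.index]
    raise ValueError(f"unknown modality {modality!r}")


def run_double_loop(
    cohort: Cohort,
    configs: Sequence[PredictorConfig],
    scopes: Sequence[EvaluationScope],
    n_repetitions: int = 15,
    grid: Optional[Sequence[int]] = None,
    seed: int = 0,
    min_stratum: int = 3,
    fraction: float = 2.0 / 3.0,
    audit: Optional[AuditFn] = None,
) -> pd.DataFrame:
    """Run the full benchmark; returns the AUC table.

    One stratified outer split is drawn per repetition and shared by every
    scope and configuration.  Per (scope, config): features are ranked on the
    scope's training samples, the feature count is chosen by the inner 3-fold
    loop on those same samples, the classifier is refit on all of them, and
    the validation samples of the scope's subtype are scored.  Failed cells
    are recorded with a reason, never dropped silently.
    """
    rows = []
    modalities = sorted({c.modality for c in configs})
    for modality in modalities:
        X_all, kinds, clinical = _modality_data(cohort, modality)
        mod_configs = [c for c in configs if c.modality == modality]
        mod_grid = grid if grid is not None else (
            DEFAULT_GRID_EXPRESSION if modality == "expression" else DEFAULT_GRID_CLINICAL
        )
        labels = clinical.apply(
            lambda r: assign_subtype(r["er"], r["her2"], str(r.name)), axis=1
        )
        y_all = (clinical["response"] == "pCR").astype(int)
        for rep in range(1, n_repetitions + 1):
            rep_seed = int(seed) + rep
            split = make_split(
                clinical, fraction=fraction, seed=rep_seed,
                min_stratum=min_stratum, repetition=rep,
            )
            for scope in scopes:
                if scope.train_subtype is None:
                    train_ids = list(split.train_ids)
                else:
                    train_ids = [
                        s for s in split.train_ids
                        if subtype_matches(labels[s], scope.train_subtype)
                    ]
                val_ids = [
                    s for s in split.validation_ids
                    if subtype_matches(labels[s], scope.validation_subtype)
                ]
                scope_cache: dict = {}
                for config in mod_configs:
                    row = dict(
                        repetition=rep, modality=modality,
                        scope=scope.scope_name,
                        subtype=scope.validation_subtype.value,
                        ranker=config.ranker, classifier=config.classifier,
                        n_features_selected=np.nan, auc=np.nan, note="",
                    )
                    try:
                        row.update(
                            _run_cell(
                                X_all, y_all, kinds, config, mod_grid,
                                train_ids, val_ids, rep_seed, scope_cache, audit,
                                scope, rep,
                            )
                        )
                    except Exception as exc:  # record, never drop
                        row["note"] = f"{type(exc).__name__}: {exc}"
                    rows.append(row)
    return pd.DataFrame(rows)


def _run_cell(
    X_all, y_all, kinds, config, grid, train_ids, val_ids, rep_seed,
    scope_cache, audit, scope, rep,
):
    if len(val_ids) == 0:
        raise ValueError("no validation samples for this subtype")
    X_tr, y_tr = X_all.loc[train_ids], y_all.loc[train_ids]
    if y_tr.nunique() < 2:
        raise ValueError("training set single-class")
    if y_all.loc[val_ids].nunique() < 2:
        raise ValueError("validation set single-class; AUC undefined")
    if audit:
        audit(rep=rep, scope=scope, config=config, phase="rank", ids=list(train_ids))
    if config.ranker == "embedded":
        feats = list(X_tr.columns.astype(str))
        n_sel = len(feats)
    else:
        rkey = ("outer_rank", config.ranker)
        if rkey in scope_cache:
            ranking = scope_cache[rkey]
        else:
            ranking = rank_features(config.ranker, X_tr, y_tr, kinds)
            scope_cache[rkey] = ranking
        if audit:
            audit(rep=rep, scope=scope, config=config, phase="inner_cv", ids=list(train_ids))
        n_sel = inner_optimal_n(
            X_tr, y_tr, config, grid, kinds=kinds, seed=rep_seed,
            _fold_cache=scope_cache,
        )
        feats = ranking.top(n_sel)
    if audit:
        audit(rep=rep, scope=scope, config=config, phase="fit", ids=list(train_ids))
    model = clf.fit(config.classifier, X_tr[feats], y_tr, kinds)
    if audit:
        audit(rep=rep, scope=scope, config=config, phase="score", ids=list(val_ids))
    scores = model.score(X_all.loc[val_ids, feats])
    return dict(
        n_features_selected=n_sel,
        auc=auc(scores, y_all.loc[val_ids]),
        note="",
    )


def write_auc_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_auc_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {
        "repetition", "modality", "scope", "subtype",
        "ranker", "classifier", "n_features_selected", "auc",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"AUC table missing columns {sorted(missing)}")
    if "note" not in table.columns:
        table["note"] = ""
    table["note"] = table["note"].fillna("")
    return table
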