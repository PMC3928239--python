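"""Feature scoring and ranking.

Expression-modality rankers (continuous features):

* ``rank_wmw``       -- two-sided Wilcoxon-Mann-Whitney rank-sum p-value per
                        feature (exact null for small, tie-free classes; normal
                        approximation with tie correction otherwise).
* ``filter_correlated`` -- greedy removal of features whose absolute Pearson
                        correlation with a higher-ranked kept feature exceeds
                        a threshold (default 0.75); with ``rank_wmw`` this is
                        the "WMW-uncorrelated" ranker.
* ``rank_bwr``       -- ratio of between-group to within-group sum of squares.

Clinical-modality rankers (mostly categorical features):

* ``rank_infogain``  -- mutual information of feature and class, natural-log
                        entropies; continuous features are discretized first.
* ``rank_cfs``       -- correlation-based feature selection: forward best-first
                        subset search on the merit
                        ``k * r_cf / sqrt(k + k(k-1) * r_ff)`` with symmetrical
                        uncertainty as the correlation measure.
* ``rank_relief``    -- deterministic ReliefF sweep over all instances with
                        k nearest hits/misses under a normalized Manhattan
                        distance.

Every ranker is deterministic; ties break to the lexicographically smallest
feature id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BINS = 3  # equal-frequency bins for discretizing continuous clinical features


@dataclass
class RankedFeatures:
    """An ordered feature list with per-feature scores.

    ``ascending`` records the score direction (True: smaller = more
    discriminative, as for p-values).  ``ordinal`` marks rankings whose order
    is authoritative by construction (subset-search inclusion order) rather
    than derived from the score column.
    """

    method: str
    table: pd.DataFrame  # columns: feature_id, score; ordered best-first
    ascending: bool = False
    ordinal: bool = False

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table["feature_id"])

    def top(self, n: int) -> list[str]:
        return self.feature_ids[: int(n)]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out["method"] = self.method
        out.to_csv(path, sep="\t", index=False)


def _ordered(
    method: str,
    feature_ids: Sequence[str],
    scores: Sequence[float],
    ascending: bool,
) -> RankedFeatures:
    table = pd.DataFrame({"feature_id": list(feature_ids), "score": list(scores)})
    table = table.sort_values(
        ["score", "feature_id"], ascending=[ascending, True], kind="mergesort"
    ).reset_index(drop=True)
    return RankedFeatures(method=method, table=table, ascending=ascending)


def _check_classes(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y).astype(int)
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("labels must be binary 0/1")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be non-empty")
    return y == 1, y == 0


# -- expression rankers ------------------------------------------------------


def rank_wmw(X: pd.DataFrame, y) -> RankedFeatures:
    """Rank features by two-sided rank-sum test p-value (ascending).

    Exact null distribution when both classes have at most 10 samples and the
    feature is tie-free; otherwise the normal approximation with tie and
    continuity correction.
    """
    pos, neg = _check_classes(np.asarray(y))
    A = X.iloc[np.where(pos)[0]]
    B = X.iloc[np.where(neg)[0]]
    n_small = pos.sum() <= 10 and neg.sum() <= 10
    pvals = np.empty(X.shape[1])
    if n_small:
        for j, col in enumerate(X.columns):
            a, b = A[col].to_numpy(), B[col].to_numpy()
            if np.all(a == a[0]) and np.all(b == a[0]):
                pvals[j] = 1.0
                continue
            has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            method = "asymptotic" if has_ties else "exact"
            pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    else:
        res = stats.mannwhitneyu(
            A.to_numpy(), B.to_numpy(), alternative="two-sided",
            method="asymptotic", axis=0,
        )
        pvals = np.asarray(res.pvalue)
        constant = (X.nunique(axis=0) == 1).to_numpy()
        pvals = np.where(constant, 1.0, pvals)
    pvals = np.minimum(pvals, 1.0)
    return _ordered("wmw", X.columns.astype(str), pvals, ascending=True)


def filter_correlated(
    X: pd.DataFrame, ranking: RankedFeatures, r_max: float = 0.75
) -> RankedFeatures:
    """Greedy scan in rank order; drop a feature iff its absolute Pearson
    correlation with any already-kept (higher-ranked) feature exceeds ``r_max``.

    Constant features have undefined Pearson correlation; they are treated as
    uncorrelated (correlation 0) and kept.  The top-ranked feature is never
    removed.
    """
    missing = set(ranking.feature_ids) - set(X.columns.astype(str))
    if missing:
        raise KeyError(f"ranking covers features absent from X: {sorted(missing)}")
    values = {f: X[f].to_numpy(dtype=float) for f in ranking.feature_ids}
    kept: list[str] = []
    rows = []
    for _, row in ranking.table.iterrows():
        f = row["feature_id"]
        v = values[f]
        ok = True
        for g in kept:
            w = values[g]
            if v.std() == 0 or w.std() == 0:
                continue
            r = np.corrcoef(v, w)[0, 1]
            if abs(r) > r_max:
                ok = False
                break
        if ok:
            kept.append(f)
            rows.append(row)
    table = pd.DataFrame(rows).reset_index(drop=True)
    return RankedFeatures(
        method=ranking.method + "_uncor", table=table, ascending=ranking.ascending
    )


def rank_wmw_uncor(X: pd.DataFrame, y, r_max: float = 0.75) -> RankedFeatures:
    return filter_correlated(X, rank_wmw(X, y), r_max=r_max)


def bwr_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Between- to within-group sum-of-squares ratio per feature (column).

    score_j = sum_k n_k (mean_kj - mean_j)^2 / sum_k sum_{i in k} (x_ij - mean_kj)^2.
    A zero within-group sum of squares with non-zero between yields +inf;
    0/0 (a constant feature) yields 0.
    """
    pos, neg = _check_classes(y)
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("BWR requires at least 2 samples per class")
    grand = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for mask in (pos, neg):
        mk = X[mask].mean(axis=0)
        between += mask.sum() * (mk - grand) ** 2
        within += ((X[mask] - mk) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = between / within
    score = np.where((within == 0) & (between == 0), 0.0, score)
    score = np.where((within == 0) & (between > 0), np.inf, score)
    return score


def rank_bwr(X: pd.DataFrame, y) -> RankedFeatures:
    """Rank by the between/within sum-of-squares ratio, descending."""
    scores = bwr_scores(X.to_numpy(dtype=float), np.asarray(y))
    return _ordered("bwr", X.columns.astype(str), scores, ascending=False)


# -- discretization ----------------------------------------------------------


def discretize(
    values, n_bins: int = DEFAULT_BINS, edges: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency binning; returns (integer codes, inner bin edges).

    Edges come from the given data (the training data when ``edges`` is later
    reused on new samples).  Fewer distinct values than bins collapse to
    distinct-value bins; a constant vector is a single bin.
    """
    v = np.asarray(values, dtype=float)
    if edges is None:
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        qs = np.quantile(v, [i / n_bins for i in range(1, n_bins)])
        edges = np.unique(qs)
        # drop edges outside the data interior (constant vector -> no edges)
        edges = edges[(edges > v.min()) & (edges <= v.max())]
    codes = np.searchsorted(edges, v, side="left")
    return codes.astype(int), edges


# -- entropy machinery (natural log) -----------------------------------------


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _joint_entropy(a: np.ndarray, b: np.ndarray) -> float:
    pair = a.astype(np.int64) * (b.max() + 1) + b.astype(np.int64)
    return _entropy(pair)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    return _entropy(a) + _entropy(b) - _joint_entropy(a, b)


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """2 I(a;b) / (H(a)+H(b)); 0 when either variable is constant."""
    ha, hb = _entropy(a), _entropy(b)
    if ha == 0 or hb == 0:
        return 0.0
    return float(np.clip(2.0 * mutual_information(a, b) / (ha + hb), 0.0, 1.0))


def _discretized_matrix(
    X: pd.DataFrame, kinds: Optional[Mapping[str, str]], n_bins: int
) -> dict[str, np.ndarray]:
    """Integer-coded feature columns; continuous ones equal-frequency binned."""
    out = {}
    for col in X.columns:
        kind = (kinds or {}).get(col, "categorical")
        v = X[col].to_numpy()
        if kind == "continuous":
            codes, _ = discretize(v, n_bins=n_bins)
        else:
            _, codes = np.unique(v, return_inverse=True)
        out[str(col)] = codes.astype(int)
    return out


def rank_infogain(
    X: pd.DataFrame, y, kinds: Optional[Mapping[str, str]] = None,
    n_bins: int = DEFAULT_BINS,
) -> RankedFeatures:
    """Rank by information gain H(y) - H(y | feature), descending (nats)."""
    _check_classes(np.asarray(y))
    ycodes = np.asarray(y).astype(int)
    cols = _discretized_matrix(X, kinds, n_bins)
    hy = _entropy(ycodes)
    scores = [
        hy - (_joint_entropy(codes, ycodes) - _entropy(codes))
        for codes in cols.values()
    ]
    return _ordered("infogain", list(cols), scores, ascending=False)


def cfs_merit(su_cf: Sequence[float], su_ff: Mapping[tuple, float], subset: Sequence[int]) -> float:
    """CFS merit of a feature subset: k r_cf / sqrt(k + k(k-1) r_ff)."""
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = float(np.mean([su_cf[i] for i in subset]))
    if k == 1:
        return r_cf
    pairs = [(i, j) for a, i in enumerate(subset) for j in subset[a + 1:]]
    r_ff = float(np.mean([su_ff[tuple(sorted(p))] for p in pairs]))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def rank_cfs(
    X: pd.DataFrame, y, kinds: Optional[Mapping[str, str]] = None,
    n_bins: int = DEFAULT_BINS, max_stale: int = 5,
) -> RankedFeatures:
    """Correlation-based feature selection, forward best-first.

    Features enter in the order the subset search adds them (up to
    ``max_stale`` consecutive non-improving expansions are tolerated before
    the search stops; the best subset seen defines the selected prefix).
    Features never selected are appended ranked by their individual
    class symmetrical uncertainty.  Scores are informational (merit at entry
    for selected features, class-SU for appended ones); the order itself is
    authoritative (``ordinal=True``).
    """
    _check_classes(np.asarray(y))
    ycodes = np.asarray(y).astype(int)
    cols = _discretized_matrix(X, kinds, n_bins)
    names = sorted(cols)  # lexicographic tie-break baked into scan order
    su_cf = [symmetrical_uncertainty(cols[f], ycodes) for f in names]
    su_ff: dict[tuple, float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            su_ff[(i, j)] = symmetrical_uncertainty(cols[names[i]], cols[names[j]])

    selected: list[int] = []
    entry_merit: list[float] = []
    best_merit, best_len = 0.0, 0
    stale = 0
    while len(selected) < len(names) and stale < max_stale:
        candidates = [i for i in range(len(names)) if i not in selected]
        merits = [(cfs_merit(su_cf, su_ff, selected + [i]), -1, names[i], i) for i in candidates]
        merits.sort(key=lambda t: (-t[0], t[2]))
        merit, _, _, idx = merits[0]
        selected.append(idx)
        entry_merit.append(merit)
        if merit > best_merit + 1e-12:
            best_merit, best_len = merit, len(selected)
            stale = 0
        else:
            stale += 1
    chosen = selected[:best_len]
    chosen_merits = entry_merit[:best_len]
    rest = [i for i in range(len(names)) if i not in chosen]
    rest.sort(key=lambda i: (-su_cf[i], names[i]))
    table = pd.DataFrame(
        {
            "feature_id": [names[i] for i in chosen] + [names[i] for i in rest],
            "score": chosen_merits + [su_cf[i] for i in rest],
        }
    )
    return RankedFeatures(method="cfs", table=table, ascending=False, ordinal=True)


# -- ReliefF ------------------------------------------------------------------


def relief_weights(
    X: pd.DataFrame, y, kinds: Optional[Mapping[str, str]] = None,
    k_neighbors: int = 3,
) -> pd.Series:
    """Deterministic ReliefF weights (all-instance sweep).

    Per-feature difference: 0/1 for categorical features, |a-b|/range for
    continuous and ordinal ones (range over the data; a constant feature
    contributes 0).  Distance = mean of per-feature differences (normalized
    Manhattan).  For every instance the k nearest same-class hits and k
    nearest other-class misses update
    ``w_f += mean(miss diffs) - mean(hit diffs)``; weights are averaged over
    instances.  Neighbor distance ties break by sample position.
    """
    y = np.asarray(y).astype(int)
    pos, neg = _check_classes(y)
    if pos.sum() <= k_neighbors or neg.sum() <= k_neighbors:
        raise ValueError(
            f"each class needs > k_neighbors={k_neighbors} samples "
            f"(have {int(pos.sum())} / {int(neg.sum())}); use a smaller k"
        )
    n, p = X.shape
    diffs = np.zeros((n, n, p))
    for j, col in enumerate(X.columns):
        kind = (kinds or {}).get(col, "continuous")
        v = X[col].to_numpy(dtype=float)
        if kind in ("categorical", "binary"):
            d = (v[:, None] != v[None, :]).astype(float)
        else:
            rng_ = v.max() - v.min()
            d = np.abs(v[:, None] - v[None, :]) / rng_ if rng_ > 0 else np.zeros((n, n))
        diffs[:, :, j] = d
    dist = diffs.mean(axis=2)
    weights = np.zeros(p)
    for i in range(n):
        same = np.where((y == y[i]) & (np.arange(n) != i))[0]
        other = np.where(y != y[i])[0]
        hits = same[np.argsort(dist[i, same], kind="stable")[:k_neighbors]]
        misses = other[np.argsort(dist[i, other], kind="stable")[:k_neighbors]]
        weights += diffs[i, misses].mean(axis=0) - diffs[i, hits].mean(axis=0)
    return pd.Series(weights / n, index=X.columns.astype(str))


def rank_relief(
    X: pd.DataFrame, y, kinds: Optional[Mapping[str, str]] = None,
    k_neighbors: int = 3,
) -> RankedFeatures:
    """Rank by ReliefF weight, descending."""
    w = relief_weights(X, y, kinds=kinds, k_neighbors=k_neighbors)
    return _ordered("relief", w.index, w.to_numpy(), ascending=False)


# -- dispatcher ---------------------------------------------------------------

EXPRESSION_RANKERS = ("wmw", "wmw_uncor", "bwr")
CLINICAL_RANKERS = ("infogain", "cfs", "relief")


def rank_features(
    ranker: str, X: pd.DataFrame, y,
    kinds: Optional[Mapping[str, str]] = None,
) -> RankedFeatures:
    if ranker == "wmw":
        return rank_wmw(X, y)
    if ranker == "wmw_uncor":
        return rank_wmw_uncor(X, y)
    if ranker == "bwr":
        return rank_bwr(X, y)
    if ranker == "infogain":
        return rank_infogain(X, y, kinds=kinds)
    if ranker == "cfs":
        return rank_cfs(X, y, kinds=kinds)
    if ranker == "relief":
        return rank_relief(X, y, kinds=kinds)
    raise ValueError(f"unknown ranker {ranker!r}")
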