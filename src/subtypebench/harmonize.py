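"""Cross-dataset harmonization.

Datasets profiled at different institutes carry additive batch effects.  The
strategy used here centers each probe/gene of each dataset so that its median
matches the median in a designated reference dataset.  Because the datasets
differ in subtype composition and response rate, the medians are computed on
*composition-balanced subsets*: the largest subset of each dataset whose
(subtype x response) cell counts are proportional to a common target
composition.  Probe-level matrices are collapsed to gene level by keeping, per
gene, the probe with the highest standard deviation across all pooled samples.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, assign_subtype


def composition_cells(clinical: pd.DataFrame) -> pd.Series:
    """Per-sample (refined subtype, response) cell key, e.g. 'TN|pCR'."""

    def key(row):
        label = assign_subtype(row["er"], row["her2"], str(row.name))
        cell = label.refinement or label.coarse
        return f"{cell.value}|{row['response']}"

    return clinical.apply(key, axis=1)


def composition_target(cohort: Cohort) -> dict:
    """A cohort's own (subtype x response) composition as target proportions."""
    cells = composition_cells(cohort.clinical)
    counts = cells.value_counts()
    return (counts / counts.sum()).to_dict()


def joint_composition_target(cohorts: Mapping[str, Cohort], reference_id: str) -> dict:
    """Reference composition restricted to cells present in every dataset,
    renormalized.  A cell no dataset can serve cannot be matched on, so it is
    excluded from the balancing target rather than making centering
    infeasible."""
    target = composition_target(cohorts[reference_id])
    for c in cohorts.values():
        present = set(composition_cells(c.clinical))
        target = {cell: p for cell, p in target.items() if cell in present}
    if not target:
        raise CohortError("no (subtype, response) cell is shared by all datasets")
    total = sum(target.values())
    return {cell: p / total for cell, p in target.items()}


def balanced_subset(
    cohort: Cohort, target: Mapping[str, float], seed: int = 0
) -> list[str]:
    """Largest sample subset whose cell counts are proportional to ``target``.

    For each non-empty target cell the available count caps the overall scale:
    with ``s = min_c available_c / p_c`` the subset takes ``floor(s * p_c)``
    samples per cell, drawn uniformly (seeded) within the cell.  A target cell
    with no available samples is infeasible and raises.
    """
    total_p = sum(target.values())
    if not np.isclose(total_p, 1.0, atol=1e-9):
        raise ValueError(f"target proportions sum to {total_p}, not 1")
    cells = composition_cells(cohort.clinical)
    available = cells.value_counts().to_dict()
    scale = np.inf
    for cell, p in target.items():
        if p <= 0:
            continue
        n_avail = available.get(cell, 0)
        if n_avail == 0:
            raise CohortError(f"balanced subset infeasible: no samples in cell {cell!r}")
        scale = min(scale, n_avail / p)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for cell in sorted(target):
        p = target[cell]
        if p <= 0:
            continue
        take = int(np.floor(scale * p + 1e-9))
        members = sorted(cells.index[cells == cell].astype(str))
        take = min(take, len(members))
        picked = rng.choice(len(members), size=take, replace=False)
        chosen.extend(members[i] for i in sorted(picked))
    if not chosen:
        raise CohortError("balanced subset is empty")
    # preserve cohort sample order
    order = {sid: i for i, sid in enumerate(cohort.sample_ids)}
    return sorted(chosen, key=order.__getitem__)


def median_center(
    cohorts: Mapping[str, Cohort],
    reference_id: str,
    target: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> dict[str, Cohort]:
    """Center every non-reference cohort's per-gene medians onto the reference.

    Medians are computed on balanced subsets drawn against ``target`` (default:
    the reference cohort's own composition).  For each gene g and dataset d the
    shift ``median_d(g) - median_ref(g)`` is subtracted from all of d's samples;
    the reference cohort is returned unchanged.  Idempotent given the same seed.
    """
    if reference_id not in cohorts:
        raise KeyError(f"reference dataset {reference_id!r} not among cohorts")
    ref = cohorts[reference_id]
    genes = ref.gene_ids
    for did, c in cohorts.items():
        if c.gene_ids != genes:
            raise CohortError(
                f"dataset {did!r} has a different gene set/order than the reference"
            )
    if target is None:
        target = joint_composition_target(cohorts, reference_id)
    ref_subset = balanced_subset(ref, target, seed=seed)
    ref_median = ref.expression[ref_subset].median(axis=1)
    out: dict[str, Cohort] = {}
    for did, c in sorted(cohorts.items()):
        if did == reference_id:
            out[did] = c
            continue
        subset = balanced_subset(c, target, seed=seed)
        shift = c.expression[subset].median(axis=1) - ref_median
        centered = c.expression.sub(shift, axis=0)
        out[did] = Cohort(centered, c.clinical)
    return out


def collapse_probes(matrix: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probes x samples matrix to one row per gene.

    Per gene the probe with the largest standard deviation (ddof=1) across all
    (pooled) samples is kept; ties break to the lexicographically smallest
    probe id.  Every probe in the matrix must be mapped; probes hitting
    multiple genes should already have been removed from the map upstream.
    """
    unmapped = [p for p in matrix.index if p not in probe_map]
    if unmapped:
        raise KeyError(f"unmapped probes: {sorted(map(str, unmapped))[:10]}")
    sds = matrix.std(axis=1, ddof=1)
    best: dict[str, str] = {}
    for probe in sorted(matrix.index.astype(str)):
        gene = probe_map[probe]
        if gene not in best:
            best[gene] = probe
        else:
            incumbent = best[gene]
            if sds[probe] > sds[incumbent]:
                best[gene] = probe
    genes = sorted(best)
    out = matrix.loc[[best[g] for g in genes]].copy()
    out.index = pd.Index(genes, name=matrix.index.name or "gene_id")
    return out


def read_probe_map(path) -> dict[str, str]:
    """Read a probe_id -> gene_id TSV; duplicate probe rows are an error."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table["probe_id"].duplicated().any():
        dupes = table["probe_id"][table["probe_id"].duplicated()].tolist()
        raise ValueError(f"probe ids mapped twice: {dupes}")
    return dict(zip(table["probe_id"], table["gene_id"]))
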