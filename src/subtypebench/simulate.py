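"""Synthetic multi-dataset breast-cancer cohort generator.

Emulates the statistical structure the benchmark assumes: several datasets
(institutes) profiled on a shared gene set, each with additive per-gene batch
shifts; a subtype composition and per-subtype pCR rate patterned on a pooled
neoadjuvant T-FAC/T-FEC cohort; response-informative genes with shared and
subtype-private effects; ER-like and HER2-like marker gene modules; and
clinical covariates (age, grade, TNM stage) whose response association can be
confined to chosen subtypes.

Default composition and response rates follow the pooled-cohort stratification
counts (HER2+/ER-: 45 samples at 56% pCR, HER2+/ER+: 37 at 16%, Luminal: 199
at 7%, TN: 113 at 37%, out of 394 over three datasets).

Everything is a pure function of (config, seed): the same ``ScenarioConfig``
always yields byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, REFINED_CELLS, Subtype

#: refined-cell proportions of the pooled reference cohort (counts /394)
DEFAULT_PROPORTIONS = {
    "HER2_POS_ER_NEG": 45 / 394,
    "HER2_POS_ER_POS": 37 / 394,
    "LUMINAL": 199 / 394,
    "TN": 113 / 394,
}
#: per-cell pathological-complete-response rates (counts ratio, not the
#: rounded printed percentage)
DEFAULT_PCR_RATES = {
    "HER2_POS_ER_NEG": 25 / 45,
    "HER2_POS_ER_POS": 6 / 37,
    "LUMINAL": 14 / 199,
    "TN": 42 / 113,
}

_CELL_ER = {
    "HER2_POS_ER_NEG": "negative",
    "HER2_POS_ER_POS": "positive",
    "LUMINAL": "positive",
    "TN": "negative",
}
_CELL_HER2 = {
    "HER2_POS_ER_NEG": "positive",
    "HER2_POS_ER_POS": "positive",
    "LUMINAL": "negative",
    "TN": "negative",
}
_CELL_COARSE = {
    "HER2_POS_ER_NEG": "HER2_POS",
    "HER2_POS_ER_POS": "HER2_POS",
    "LUMINAL": "LUMINAL",
    "TN": "TN",
}


@dataclass
class ScenarioConfig:
    """Full description of one synthetic study.

    ``clinical_assoc`` maps covariate name (age/grade/tnm_stage) to either a
    scalar log-odds coefficient (applied in every subtype) or a mapping of
    coarse-subtype / refined-cell name to coefficient.  Covariates are
    standardized before entering the response logit, so coefficients are
    log-odds per SD-like unit.
    """

    n_samples: Sequence[int] = (132, 131, 131)
    dataset_ids: Sequence[str] = ("D1", "D2", "D3")
    cell_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    pcr_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PCR_RATES))
    n_genes: int = 500
    n_shared_signal: int = 0
    shared_effect: float = 1.0
    n_private_signal: int = 0
    private_effect: float = 1.0
    private_subtype: str = "TN"
    n_marker_genes: int = 20
    er_marker_shift: float = 1.5
    her2_marker_shift: float = 1.5
    clinical_assoc: Mapping[str, object] = field(default_factory=dict)
    pr_flip_prob: float = 0.1
    batch_sd: float = 0.3
    noise_sd: float = 1.0
    clinical_missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        props = dict(self.cell_proportions)
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("cell proportions must sum to 1")
        if any(p < 0 for p in props.values()):
            raise ValueError("cell proportions must be non-negative")
        for cell, r in self.pcr_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"pCR rate for {cell} outside [0,1]")
        if len(self.n_samples) != len(self.dataset_ids):
            raise ValueError("n_samples and dataset_ids lengths differ")
        if any(n <= 0 for n in self.n_samples):
            raise ValueError("each dataset needs at least one sample")
        n_special = (
            self.n_shared_signal + self.n_private_signal + 2 * self.n_marker_genes
        )
        if n_special > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_special} structured genes"
            )

    def gene_roles(self) -> dict:
        """Index ranges of the structured gene blocks (shared / private /
        ER-module / HER2-module); everything after them is pure noise."""
        i = 0
        roles = {}
        roles["shared"] = list(range(i, i + self.n_shared_signal)); i += self.n_shared_signal
        roles["private"] = list(range(i, i + self.n_private_signal)); i += self.n_private_signal
        roles["er_module"] = list(range(i, i + self.n_marker_genes)); i += self.n_marker_genes
        roles["her2_module"] = list(range(i, i + self.n_marker_genes)); i += self.n_marker_genes
        roles["noise"] = list(range(i, self.n_genes))
        return roles


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _assoc_coef(assoc: Mapping[str, object], feature: str, cell: str) -> float:
    entry = assoc.get(feature)
    if entry is None:
        return 0.0
    if isinstance(entry, (int, float)):
        return float(entry)
    # mapping: accept coarse subtype or refined cell keys
    if cell in entry:
        return float(entry[cell])
    coarse = _CELL_COARSE[cell]
    return float(entry.get(coarse, 0.0))


def generate(config: ScenarioConfig) -> list[Cohort]:
    """Generate one cohort per dataset; deterministic in config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(int(config.seed))
    cells = [c for c in DEFAULT_PROPORTIONS if config.cell_proportions.get(c, 0) > 0]
    probs = np.array([config.cell_proportions[c] for c in cells])
    probs = probs / probs.sum()
    roles = config.gene_roles()
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    cohorts = []
    counter = 0
    for did, n in zip(config.dataset_ids, config.n_samples):
        batch = rng.normal(0.0, config.batch_sd, size=config.n_genes)
        sample_ids = [f"{did}_S{counter + i:04d}" for i in range(n)]
        counter += n
        cell_idx = rng.choice(len(cells), size=n, p=probs)
        cell_names = [cells[i] for i in cell_idx]
        er = np.array([_CELL_ER[c] for c in cell_names])
        her2 = np.array([_CELL_HER2[c] for c in cell_names])
        flip = rng.random(n) < config.pr_flip_prob
        pr = np.where(
            flip,
            np.where(er == "positive", "negative", "positive"),
            er,
        )
        age = rng.normal(50.0, 10.0, size=n).clip(25.0, 90.0)
        grade = rng.choice([1, 2, 3], size=n, p=[0.2, 0.5, 0.3])
        stage = rng.choice([1, 2, 3], size=n, p=[0.3, 0.5, 0.2])
        z = {
            "age": (age - 50.0) / 10.0,
            "grade": grade - 2.0,
            "tnm_stage": stage - 2.0,
        }
        eta = np.array([_logit(config.pcr_rates[c]) for c in cell_names])
        for feat, zv in z.items():
            coefs = np.array(
                [_assoc_coef(config.clinical_assoc, feat, c) for c in cell_names]
            )
            eta = eta + coefs * zv
        response = np.where(
            rng.random(n) < 1.0 / (1.0 + np.exp(-eta)), "pCR", "no_pCR"
        )
        expr = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
        expr += batch[:, None]
        is_pcr = response == "pCR"
        if roles["shared"]:
            expr[np.ix_(roles["shared"], np.where(is_pcr)[0])] += config.shared_effect
        if roles["private"]:
            in_target = np.array(
                [
                    _CELL_COARSE[c] == config.private_subtype
                    or c == config.private_subtype
                    for c in cell_names
                ]
            )
            hit = np.where(is_pcr & in_target)[0]
            if len(hit):
                expr[np.ix_(roles["private"], hit)] += config.private_effect
        if roles["er_module"]:
            pos = np.where(er == "positive")[0]
            if len(pos):
                expr[np.ix_(roles["er_module"], pos)] += config.er_marker_shift
        if roles["her2_module"]:
            pos = np.where(her2 == "positive")[0]
            if len(pos):
                expr[np.ix_(roles["her2_module"], pos)] += config.her2_marker_shift
        clin = pd.DataFrame(
            {
                "dataset_id": did,
                "er": er,
                "pr": pr,
                "her2": her2,
                "age": np.round(age, 1),
                "grade": grade.astype(float),
                "tnm_stage": stage.astype(float),
                "response": response,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        if config.clinical_missing_rate > 0:
            for col in ("age", "grade", "tnm_stage"):
                miss = rng.random(n) < config.clinical_missing_rate
                clin.loc[miss, col] = np.nan
        expr_df = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
        cohorts.append(Cohort(expr_df, clin))
    return cohorts


PRESET_NAMES = (
    "null",
    "shared_signal",
    "subtype_private_signal",
    "confounded_marker",
    "rare_minority",
)


def preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Named scenarios reproducing the benchmark's headline phenomena.

    * ``null``: no response signal anywhere, no batch shifts — every predictor
      should hover at AUC 0.5.
    * ``shared_signal``: genes shifted in responders of every subtype.
    * ``subtype_private_signal``: genes shifted in responders of TN only.
    * ``confounded_marker``: no response-informative genes; the ER-like
      clinical marker separates subtypes with very different pCR rates, so it
      is strongly predictive pooled yet constant (hence useless) inside each
      subtype; age/grade/stage carry response signal inside the HER2+
      subgroups only.  A generic predictor that selects the pooled-dominant
      receptor features collapses to AUC 0.5 in HER2+/ER-.
    * ``rare_minority``: shared-signal genes only, with the Luminal subtype's
      7% pCR rate making responders rare; a subtype-specific Luminal
      predictor sees too few positive training samples.
    """
    if name == "null":
        return ScenarioConfig(
            seed=seed, n_genes=200, n_marker_genes=0,
            er_marker_shift=0.0, her2_marker_shift=0.0, batch_sd=0.0,
        )
    if name == "shared_signal":
        return ScenarioConfig(seed=seed, n_shared_signal=10, shared_effect=1.0)
    if name == "subtype_private_signal":
        return ScenarioConfig(
            seed=seed, n_private_signal=10, private_effect=1.0, private_subtype="TN",
        )
    if name == "confounded_marker":
        return ScenarioConfig(
            seed=seed,
            n_genes=100,
            clinical_assoc={
                "age": {"HER2_POS": 1.2},
                "grade": {"HER2_POS": 1.0},
                "tnm_stage": {"HER2_POS": 0.8},
            },
        )
    if name == "rare_minority":
        return ScenarioConfig(seed=seed, n_genes=1000, n_shared_signal=10, shared_effect=1.0)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def config_to_dict(config: ScenarioConfig) -> dict:
    d = asdict(config)
    d["n_samples"] = list(d["n_samples"])
    d["dataset_ids"] = list(d["dataset_ids"])
    return d


def config_from_dict(d: Mapping) -> ScenarioConfig:
    d = dict(d)
    if "n_samples" in d:
        d["n_samples"] = tuple(d["n_samples"])
    if "dataset_ids" in d:
        d["dataset_ids"] = tuple(d["dataset_ids"])
    return ScenarioConfig(**d)
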