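"""Synthetic methylation cohorts with planted ground truth.

The generator emulates the statistical structure of a prospective
case-control Infinium-style beta-value matrix:

* beta-distributed per-CpG baselines (low-methylation baselines at risk CpGs);
* **risk CpGs** — in case samples only, a random minority ("outliers") gains
  0.2-0.3 methylation, producing differential variability with only a small
  mean shift; risk CpGs also drift upward with age (they are a subset of the
  age CpGs by default, mirroring the observed overlap);
* **age CpGs** — methylation changes linearly with age in all samples,
  mostly hypermethylation;
* **vCpGs** — large phenotype-independent spread (range > 0.8), the
  signature of cell-composition variation;
* a **cancer-like bimodal regime** in which risk CpGs are hemi- or fully
  methylated in the majority of cases, compressing COPA outlier scores.

Everything is seeded and the planted truth is returned alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import CpgAnnotation, MethylationMatrix, SampleAnnotation, clip_beta

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "truth_metrics"]


@dataclass
class SimConfig:
    """Parameters of the simulated cohort (defaults mirror the study design:
    75 cases / 77 controls aged 19-55, outlier gains of 0.2-0.3 beta hitting
    ~15% of cases at risk CpGs)."""

    n_cases: int = 75
    n_controls: int = 77
    n_cpgs: int = 20000
    n_risk: int = 500
    n_age: int = 1000
    n_vcpg: int = 500
    outlier_fraction: float = 0.15
    outlier_shift_range: tuple = (0.2, 0.3)
    age_range: tuple = (19.0, 55.0)
    age_slope_range: tuple = (0.002, 0.006)  # beta per year
    age_hyper_fraction: float = 0.61  # fraction of non-risk age CpGs gaining methylation
    risk_beta_shape: tuple = (2.0, 18.0)  # low-methylation baseline, mean 0.1
    background_mean_range: tuple = (0.1, 0.9)
    noise_concentration: float = 100.0  # beta concentration a+b of background CpGs
    pcgt_fraction_of_risk: float = 0.5
    pcgt_background_rate: float = 0.05
    risk_within_age: bool = True  # risk CpGs are a subset of age-hypermethylated CpGs
    cancer_case_fraction: float = 0.7  # cases methylated per risk CpG (bimodal regime)
    regime: str = "prospective"  # or "cancer_bimodal"
    clip_epsilon: float = 1e-6
    seed: Optional[int] = None

    def __post_init__(self):
        if min(self.n_cases, self.n_controls, self.n_cpgs) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_risk + self.n_vcpg + (0 if self.risk_within_age else self.n_age) > self.n_cpgs:
            raise ValueError("planted CpG sets exceed the number of CpGs")
        if self.risk_within_age and self.n_age < self.n_risk:
            raise ValueError("risk CpGs are a subset of age CpGs: need n_age >= n_risk")
        if not 0 < self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in (0, 1)")
        if self.regime not in ("prospective", "cancer_bimodal"):
            raise ValueError(f"unknown regime {self.regime!r}")
        a, b = self.risk_beta_shape
        if a / (a + b) + self.outlier_shift_range[1] >= 1.0:
            raise ValueError(
                "outlier shift range infeasible: baseline mean + max shift reaches 1"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        payload = json.loads(text)
        for key in ("outlier_shift_range", "age_range", "age_slope_range", "risk_beta_shape",
                    "background_mean_range"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class SimTruth:
    """Planted ground truth: per-CpG flags and the realised outlier hits."""

    cpg_ids: pd.Index
    is_risk: np.ndarray
    is_age: np.ndarray
    is_vcpg: np.ndarray
    is_pcgt: np.ndarray
    hits: dict = field(default_factory=dict)  # risk cpg_id -> list of hit sample ids
    shifts: dict = field(default_factory=dict)  # risk cpg_id -> list of realised shifts
    ages: Optional[np.ndarray] = None
    age_slopes: Optional[dict] = None

    def risk_set(self) -> set:
        return set(self.cpg_ids[self.is_risk])

    def age_set(self) -> set:
        return set(self.cpg_ids[self.is_age])

    def vcpg_set(self) -> set:
        return set(self.cpg_ids[self.is_vcpg])

    def to_dict(self) -> dict:
        return {
            "cpg_ids": list(map(str, self.cpg_ids)),
            "is_risk": self.is_risk.astype(int).tolist(),
            "is_age": self.is_age.astype(int).tolist(),
            "is_vcpg": self.is_vcpg.astype(int).tolist(),
            "is_pcgt": self.is_pcgt.astype(int).tolist(),
            "hits": {k: list(v) for k, v in self.hits.items()},
            "shifts": {k: [float(s) for s in v] for k, v in self.shifts.items()},
            "ages": None if self.ages is None else [float(a) for a in self.ages],
            "age_slopes": None
            if self.age_slopes is None
            else {k: float(v) for k, v in self.age_slopes.items()},
        }


def simulate_cohort(config: SimConfig):
    """Generate (matrix, sample annotation, CpG annotation, truth) per config."""
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_cases + config.n_controls
    n = config.n_cpgs
    cpg_ids = pd.Index([f"cg{i:07d}" for i in range(n)], name="cpg_id")
    sample_ids = pd.Index([f"s{i:04d}" for i in range(n_samples)], name="sample_id")
    is_case = np.zeros(n_samples, dtype=bool)
    is_case[: config.n_cases] = True
    ages = rng.uniform(*config.age_range, size=n_samples)
    hpv = rng.choice(["positive", "negative"], size=n_samples, p=[0.6, 0.4])

    # -- planted CpG sets (disjoint except risk within age) ------------------
    order = rng.permutation(n)
    risk_idx = order[: config.n_risk]
    if config.risk_within_age:
        age_idx = order[: config.n_age]
    else:
        age_idx = order[config.n_risk : config.n_risk + config.n_age]
    used = config.n_age if config.risk_within_age else config.n_risk + config.n_age
    vcpg_idx = order[used : used + config.n_vcpg]
    is_risk = np.zeros(n, dtype=bool)
    is_risk[risk_idx] = True
    is_age = np.zeros(n, dtype=bool)
    is_age[age_idx] = True
    is_vcpg = np.zeros(n, dtype=bool)
    is_vcpg[vcpg_idx] = True

    # -- baselines ------------------------------------------------------------
    a_r, b_r = config.risk_beta_shape
    mu = rng.uniform(*config.background_mean_range, size=n)
    kappa = config.noise_concentration
    a = mu * kappa
    b = (1.0 - mu) * kappa
    a[is_risk] = a_r
    b[is_risk] = b_r
    beta = rng.beta(a[:, None], b[:, None], size=(n, n_samples))

    # -- age drift -------------------------------------------------------------
    slopes = np.zeros(n)
    lo_s, hi_s = config.age_slope_range
    magnitudes = rng.uniform(lo_s, hi_s, size=is_age.sum())
    sign = np.ones(is_age.sum())
    non_risk_age = ~is_risk[age_idx]
    hypo = rng.random(non_risk_age.sum()) > config.age_hyper_fraction
    sign_non_risk = np.ones(non_risk_age.sum())
    sign_non_risk[hypo] = -1.0
    sign[non_risk_age] = sign_non_risk
    slopes[age_idx] = magnitudes * sign
    beta[is_age] += slopes[is_age, None] * (ages[None, :] - config.age_range[0])

    # -- risk CpG signal ---------------------------------------------------------
    hits: dict = {}
    shifts: dict = {}
    case_cols = np.flatnonzero(is_case)
    if config.regime == "prospective":
        for i in risk_idx:
            hit = case_cols[rng.random(len(case_cols)) < config.outlier_fraction]
            sh = rng.uniform(*config.outlier_shift_range, size=len(hit))
            beta[i, hit] += sh
            cid = cpg_ids[i]
            hits[cid] = [sample_ids[j] for j in hit]
            shifts[cid] = list(sh)
    else:  # cancer_bimodal: hemi- or fully methylated in a majority of cases
        for i in risk_idx:
            hit = case_cols[rng.random(len(case_cols)) < config.cancer_case_fraction]
            level = rng.choice([0.5, 0.9], size=len(hit))
            beta[i, hit] = rng.beta(level * 100.0, (1.0 - level) * 100.0)
            cid = cpg_ids[i]
            hits[cid] = [sample_ids[j] for j in hit]
            shifts[cid] = list(level)

    # -- vCpGs: large phenotype-independent spread -------------------------------
    if config.n_vcpg:
        beta[is_vcpg] = rng.uniform(0.05, 0.95, size=(int(is_vcpg.sum()), n_samples))

    beta = clip_beta(beta, config.clip_epsilon)
    matrix = MethylationMatrix(beta, cpg_ids, sample_ids)
    annotation = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "status": np.where(is_case, "case", "control"),
                "age": ages,
                "hpv": hpv,
            }
        )
    )
    is_pcgt = rng.random(n) < config.pcgt_background_rate
    is_pcgt[risk_idx] = rng.random(config.n_risk) < config.pcgt_fraction_of_risk
    cpg_annotation = CpgAnnotation(
        pd.DataFrame(
            {
                "cpg_id": cpg_ids,
                "entrez_id": np.arange(1, n + 1),
                "gene_symbol": [f"GENE{i}" for i in range(n)],
                "pcgt": is_pcgt,
            }
        )
    )
    truth = SimTruth(
        cpg_ids=cpg_ids,
        is_risk=is_risk,
        is_age=is_age,
        is_vcpg=is_vcpg,
        is_pcgt=is_pcgt,
        hits=hits,
        shifts=shifts,
        ages=ages,
        age_slopes={cpg_ids[i]: slopes[i] for i in age_idx},
    )
    return matrix, annotation, cpg_annotation, truth


def truth_metrics(selected, truth: SimTruth) -> dict:
    """Precision and recall of a selected CpG set against the planted risk set."""
    selected = set(selected)
    universe = set(truth.cpg_ids)
    if not selected <= universe:
        raise ValueError("selected CpGs outside the simulated universe")
    planted = truth.risk_set()
    tp = len(selected & planted)
    precision = tp / len(selected) if selected else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    return {"precision": precision, "recall": recall, "n_selected": len(selected), "n_true": len(planted)}
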