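"""Core containers for methylation data and methylation-scale conversions.

The central object is :class:`MethylationMatrix`, a CpG x sample matrix of
beta-values (methylation fractions in the open interval (0, 1)) with an
explicit missing-value mask carried as NaN.  Sample phenotype/age/HPV
annotation and CpG gene annotation are plain pandas DataFrames with a
validated schema, constructed through :class:`SampleAnnotation` and
:class:`CpgAnnotation`.

Three value scales are supported:

* ``beta`` — the methylation fraction, beta = M/(M+U);
* ``r``    — the methylated/unmethylated ratio, R = beta/(1-beta);
* ``m``    — the log2 ratio, M-value = log2(beta/(1-beta)).

Conversions are strictly monotone and mutually inverse on (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "SampleAnnotation",
    "CpgAnnotation",
    "beta_to_r",
    "beta_to_m",
    "r_to_beta",
    "m_to_beta",
    "convert_scale",
    "clip_beta",
    "DEFAULT_CLIP_EPSILON",
]

DEFAULT_CLIP_EPSILON = 1e-6


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dup[:5]}")


@dataclass
class MethylationMatrix:
    """Beta-value matrix, rows = CpGs, columns = samples; NaN marks missing.

    Parameters
    ----------
    beta : (n_cpgs, n_samples) array of beta-values in (0, 1), NaN for missing.
    cpg_ids, sample_ids : unique ordered identifiers.
    """

    beta: np.ndarray
    cpg_ids: pd.Index
    sample_ids: pd.Index

    def __init__(self, beta, cpg_ids: Iterable, sample_ids: Iterable):
        beta = np.asarray(beta, dtype=float)
        cpg_ids = pd.Index(cpg_ids, dtype=object, name="cpg_id")
        sample_ids = pd.Index(sample_ids, dtype=object, name="sample_id")
        if beta.ndim != 2 or beta.shape != (len(cpg_ids), len(sample_ids)):
            raise ValueError(
                f"beta shape {beta.shape} does not match "
                f"({len(cpg_ids)} CpGs, {len(sample_ids)} samples)"
            )
        _check_unique(cpg_ids, "CpG")
        _check_unique(sample_ids, "sample")
        finite = beta[np.isfinite(beta)]
        if finite.size and (finite.min() <= 0.0 or finite.max() >= 1.0):
            raise ValueError("beta-values must lie strictly inside (0, 1); clip first")
        self.beta = beta
        self.cpg_ids = cpg_ids
        self.sample_ids = sample_ids

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.beta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.cpg_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MethylationMatrix":
        return cls(frame.to_numpy(dtype=float), frame.index, frame.columns)

    def select_samples(self, sample_ids: Sequence) -> "MethylationMatrix":
        idx = self.sample_ids.get_indexer(pd.Index(sample_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return MethylationMatrix(self.beta[:, idx], self.cpg_ids, pd.Index(sample_ids))

    def select_cpgs(self, cpg_ids: Sequence) -> "MethylationMatrix":
        idx = self.cpg_ids.get_indexer(pd.Index(cpg_ids))
        if (idx < 0).any():
            missing = [c for c, i in zip(cpg_ids, idx) if i < 0]
            raise KeyError(f"CpGs not in matrix: {missing[:5]}")
        return MethylationMatrix(self.beta[idx, :], pd.Index(cpg_ids), self.sample_ids)

    def drop_high_missing_cpgs(self, max_missing_fraction: float = 0.2) -> "MethylationMatrix":
        """Drop CpGs whose missing fraction exceeds ``max_missing_fraction``."""
        frac = self.missing_mask.mean(axis=1)
        keep = frac <= max_missing_fraction
        return MethylationMatrix(self.beta[keep], self.cpg_ids[keep], self.sample_ids)


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample phenotype annotation: case/control status, age, HPV status."""

    frame: pd.DataFrame = field(repr=False)

    STATUSES = ("case", "control")
    HPV = ("positive", "negative", "unknown")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = {"sample_id", "status", "age"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"sample annotation missing columns: {sorted(missing)}")
        _check_unique(pd.Index(frame["sample_id"]), "sample")
        bad = set(frame["status"]) - set(self.STATUSES)
        if bad:
            raise ValueError(
                f"invalid status values {sorted(bad)}; allowed: {list(self.STATUSES)}"
            )
        ages = pd.to_numeric(frame["age"], errors="coerce")
        if ages.isna().any() or (~np.isfinite(ages)).any() or (ages < 0).any():
            bad_ids = frame.loc[ages.isna() | (ages < 0), "sample_id"].tolist()
            raise ValueError(f"ages must be finite and >= 0; offending samples: {bad_ids[:5]}")
        frame["age"] = ages.astype(float)
        if "hpv" not in frame.columns:
            frame["hpv"] = "unknown"
        frame["hpv"] = (
            frame["hpv"].astype(object).where(frame["hpv"].notna(), "unknown").replace("", "unknown")
        )
        bad_hpv = set(frame["hpv"]) - set(self.HPV)
        if bad_hpv:
            raise ValueError(f"invalid hpv values {sorted(bad_hpv)}; allowed: {list(self.HPV)}")
        frame = frame.reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.frame["sample_id"], name="sample_id")

    @property
    def status(self) -> np.ndarray:
        return self.frame["status"].to_numpy()

    @property
    def age(self) -> np.ndarray:
        return self.frame["age"].to_numpy(dtype=float)

    @property
    def hpv(self) -> np.ndarray:
        return self.frame["hpv"].to_numpy()

    def is_case(self) -> np.ndarray:
        return self.status == "case"

    def reindex(self, sample_ids: Sequence) -> "SampleAnnotation":
        sub = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleAnnotation(sub)


@dataclass(frozen=True)
class CpgAnnotation:
    """Per-CpG gene annotation with named gene-set membership (e.g. PCGT)."""

    frame: pd.DataFrame = field(repr=False)

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "cpg_id" not in frame.columns:
            raise ValueError("cpg annotation requires a cpg_id column")
        _check_unique(pd.Index(frame["cpg_id"]), "CpG")
        for col in ("entrez_id", "gene_symbol"):
            if col not in frame.columns:
                frame[col] = None
        if "pcgt" not in frame.columns:
            frame["pcgt"] = False
        frame["pcgt"] = frame["pcgt"].fillna(0).astype(int).astype(bool)
        object.__setattr__(self, "frame", frame.reset_index(drop=True))

    @property
    def cpg_ids(self) -> pd.Index:
        return pd.Index(self.frame["cpg_id"], name="cpg_id")

    def pcgt_set(self) -> set:
        return set(self.frame.loc[self.frame["pcgt"], "cpg_id"])


# ---------------------------------------------------------------------------
# Scale conversions


def _validate_open_unit(x: np.ndarray) -> None:
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size and ((finite <= 0.0) | (finite >= 1.0)).any():
        raise ValueError("beta must lie strictly in (0, 1); clip to [eps, 1-eps] first")


def beta_to_r(beta):
    """R = beta/(1-beta), the methylated/unmethylated signal ratio."""
    beta = np.asarray(beta, dtype=float)
    _validate_open_unit(beta)
    return beta / (1.0 - beta)


def beta_to_m(beta):
    """M-value = log2(beta/(1-beta)); the variance-stabilised logit scale."""
    return np.log2(beta_to_r(beta))


def r_to_beta(r):
    r = np.asarray(r, dtype=float)
    if np.any(r[np.isfinite(r)] < 0):
        raise ValueError("R-values must be non-negative")
    return r / (1.0 + r)


def m_to_beta(m):
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def convert_scale(x, target: str):
    """Convert beta-values to the ``r`` or ``m`` scale (or return beta)."""
    if target == "beta":
        x = np.asarray(x, dtype=float)
        _validate_open_unit(x)
        return x
    if target == "r":
        return beta_to_r(x)
    if target == "m":
        return beta_to_m(x)
    raise ValueError(f"unknown scale {target!r}; expected beta, r or m")


def clip_beta(beta, epsilon: float = DEFAULT_CLIP_EPSILON):
    """Clip beta-values into [epsilon, 1-epsilon] so ratio scales stay finite."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    return np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
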