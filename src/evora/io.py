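"""Readers and writers for the package's tabular formats.

Formats
-------
* beta matrix: TSV, header ``cpg_id\\t<sample1>\\t...``, ``NA`` for missing;
* sample annotation: CSV with header ``sample_id,status,age,hpv``;
* CpG annotation: CSV with header ``cpg_id,entrez_id,gene_symbol,pcgt``;
* differential-variability table: TSV with a fixed column order;
* risk scores: TSV ``sample_id, score, n_hits, n_cpgs_used, scale``;
* trained model: JSON (schema-versioned), see :mod:`evora.model`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CpgAnnotation, MethylationMatrix, SampleAnnotation, clip_beta

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_cpg_annotation",
    "write_cpg_annotation",
    "DVC_COLUMNS",
    "write_dvc_table",
    "read_dvc_table",
    "write_scores",
    "read_scores",
    "read_category_file",
    "save_model",
    "load_model",
]

DVC_COLUMNS = [
    "cpg_id",
    "entrez_id",
    "gene_symbol",
    "var_ratio",
    "b_stat",
    "bartlett_stat",
    "p_bartlett",
    "q_bartlett",
    "mean_diff",
    "t_stat",
    "p_t",
    "q_t",
    "direction",
]

SCORE_COLUMNS = ["sample_id", "score", "n_hits", "n_cpgs_used", "scale"]


def read_beta_matrix(path, clip_epsilon: float = 1e-6) -> MethylationMatrix:
    """Read a beta-value TSV (rows CpGs, columns samples; NA = missing).

    Values exactly 0 or 1 are clipped to ``[clip_epsilon, 1-clip_epsilon]``;
    values outside [0, 1] or non-numeric cells other than NA are hard errors.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    frame.index.name = "cpg_id"
    for j, col in enumerate(frame.columns):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric cell at CpG {frame.index[i]!r}, sample {col!r}: "
                f"{frame[col].iloc[i]!r}"
            )
        frame[col] = coerced
    values = frame.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("beta-values outside [0, 1] found; refusing to clip silently")
    clipped = np.where(np.isfinite(values), clip_beta(values, clip_epsilon), np.nan)
    return MethylationMatrix(clipped, frame.index, frame.columns)


def write_beta_matrix(matrix: MethylationMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_sample_annotation(path) -> SampleAnnotation:
    frame = pd.read_csv(path, dtype={"sample_id": str, "status": str, "hpv": str})
    return SampleAnnotation(frame)


def write_sample_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.frame.to_csv(path, index=False)


def read_cpg_annotation(path) -> CpgAnnotation:
    frame = pd.read_csv(path, dtype={"cpg_id": str, "gene_symbol": str})
    return CpgAnnotation(frame)


def write_cpg_annotation(annotation: CpgAnnotation, path) -> None:
    out = annotation.frame.copy()
    out["pcgt"] = out["pcgt"].astype(int)
    out.to_csv(path, index=False)


def write_dvc_table(table: pd.DataFrame, path) -> None:
    """Write a differential-variability table with the documented column order."""
    out = table.copy()
    for col in DVC_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[DVC_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dvc_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_scores(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    missing = [c for c in SCORE_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    out[SCORE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_category_file(path) -> dict:
    """Read a two-column TSV (member id, set name) into {set_name: set of ids}.

    Members may be CpG identifiers or gene symbols; one row per membership.
    """
    frame = pd.read_csv(path, sep="\t", header=None, names=["member", "set_name"], dtype=str)
    if frame["member"].isna().any() or frame["set_name"].isna().any():
        raise ValueError("category file rows must have two non-empty columns")
    return {name: set(group["member"]) for name, group in frame.groupby("set_name")}


def save_model(model, path) -> None:
    """Serialise a trained risk model to JSON (see :class:`evora.model.RiskModel`)."""
    path = Path(path)
    path.write_text(json.dumps(model.to_dict(), indent=1, sort_keys=True))


def load_model(path):
    from .model import RiskModel

    payload = json.loads(Path(path).read_text())
    return RiskModel.from_dict(payload)
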