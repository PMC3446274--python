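"""Cancer Outlier Profile Analysis (COPA) transformation.

The COPA score of a value x at a given CpG is ``(x - median) / (1.4826 *
MAD)`` where the median and the raw median absolute deviation (MAD) are
estimated on training samples only and then frozen for application to test
data.  Median/MAD centering-scaling is robust to the very outliers the
score is meant to expose and is invariant under per-CpG affine
recalibration, which makes outlier calls comparable across CpGs and
platforms.  CpGs whose MAD is zero (more than half the training samples
identical) cannot be scaled and are flagged unusable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MethylationMatrix

__all__ = ["MAD_SCALE", "CopaParams", "fit_copa_params", "copa_transform"]

# consistency factor making the MAD estimate the standard deviation under normality
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class CopaParams:
    """Frozen per-CpG median and scaled MAD from a training set."""

    cpg_ids: pd.Index
    median: np.ndarray
    mad: np.ndarray  # raw MAD, unscaled

    @property
    def usable(self) -> np.ndarray:
        return np.isfinite(self.median) & np.isfinite(self.mad) & (self.mad > 0)

    def usable_cpgs(self) -> pd.Index:
        return self.cpg_ids[self.usable]

    def subset(self, cpg_ids) -> "CopaParams":
        idx = self.cpg_ids.get_indexer(pd.Index(cpg_ids))
        if (idx < 0).any():
            missing = [c for c, i in zip(cpg_ids, idx) if i < 0]
            raise KeyError(f"COPA parameters missing for CpGs: {missing[:5]}")
        return CopaParams(pd.Index(cpg_ids), self.median[idx], self.mad[idx])

    def to_dict(self) -> dict:
        return {
            "cpg_ids": list(map(str, self.cpg_ids)),
            "median": [float(v) for v in self.median],
            "mad": [float(v) for v in self.mad],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CopaParams":
        return cls(
            pd.Index(payload["cpg_ids"]),
            np.asarray(payload["median"], dtype=float),
            np.asarray(payload["mad"], dtype=float),
        )


def fit_copa_params(matrix: MethylationMatrix) -> CopaParams:
    """Estimate the per-CpG median and raw MAD on (training) samples."""
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(matrix.beta, axis=1)
        mad = np.nanmedian(np.abs(matrix.beta - med[:, None]), axis=1)
    all_missing = ~np.isfinite(matrix.beta).any(axis=1)
    med[all_missing] = np.nan
    mad[all_missing] = np.nan
    return CopaParams(matrix.cpg_ids, med, mad)


def copa_transform(matrix: MethylationMatrix, params: CopaParams | None = None) -> pd.DataFrame:
    """COPA scores ``(beta - median) / (1.4826 * MAD)`` per CpG and sample.

    With ``params=None`` the median/MAD are estimated from ``matrix`` itself
    (training); otherwise frozen parameters are applied (train-to-test
    transfer).  Rows for unusable CpGs (MAD = 0 or all-missing) are NaN.
    """
    if params is None:
        params = fit_copa_params(matrix)
    else:
        params = params.subset(matrix.cpg_ids)
    scale = MAD_SCALE * params.mad
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (matrix.beta - params.median[:, None]) / scale[:, None]
    scores[~params.usable, :] = np.nan
    return pd.DataFrame(scores, index=matrix.cpg_ids, columns=matrix.sample_ids)
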