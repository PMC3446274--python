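"""Per-CpG statistics: differential variability, differential methylation,
age association and false-discovery-rate estimation.

The central contrast is between two families of tests applied to the same
case/control methylation matrix:

* **Differential variability** (Bartlett's test): does the variance of a
  CpG's beta-values differ between phenotypes?  Outlier-driven methylation
  changes that affect only a small subset of samples inflate the variance of
  that group while barely moving its mean, so variance tests can reach
  genome-wide significance where mean tests do not.
* **Differential methylation** (Welch t-test): does the mean differ?

Variances are estimated after linear adjustment for age within each
phenotype, so that age-related drift does not masquerade as case/control
variability.  All per-CpG computations are vectorised over the full matrix
and tolerate missing values (NaN) by pairwise exclusion.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MethylationMatrix, SampleAnnotation, clip_beta, convert_scale

__all__ = [
    "adjust_covariate",
    "bartlett_two_group",
    "bartlett_matrix",
    "ttest_two_group",
    "ttest_matrix",
    "age_association",
    "estimate_pi0",
    "estimate_qvalues",
    "rank_dvcs",
    "rank_vcpgs",
]


# ---------------------------------------------------------------------------
# Covariate adjustment


def _nan_moments(values: np.ndarray):
    """Row-wise count, mean and unbiased variance ignoring NaN."""
    finite = np.isfinite(values)
    n = finite.sum(axis=1)
    filled = np.where(finite, values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=1) / n
        centered = np.where(finite, values - mean[:, None], 0.0)
        var = (centered**2).sum(axis=1) / np.where(n > 1, n - 1, np.nan)
    mean = np.where(n > 0, mean, np.nan)
    return n, mean, var


def _residualize(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Row-wise OLS of values on a covariate; residuals with row mean re-added.

    Samples whose covariate is NaN are passed through unadjusted.
    """
    x = np.asarray(covariate, dtype=float)
    usable = np.isfinite(x)
    out = values.copy()
    if usable.sum() < 3:
        raise ValueError("covariate adjustment needs >= 3 samples with a finite covariate")
    v = values[:, usable]
    xv = x[usable]
    finite = np.isfinite(v)
    if finite.all():
        xc = xv - xv.mean()
        sxx = float(xc @ xc)
        if sxx > 0:
            slope = (v @ xc) / sxx
            out[:, usable] = v - slope[:, None] * xc[None, :]
        return out
    n = finite.sum(axis=1)
    xs = np.where(finite, xv[None, :], 0.0)
    vs = np.where(finite, v, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = xs.sum(axis=1) / n
        vbar = vs.sum(axis=1) / n
        sxx = (np.where(finite, (xv[None, :] - xbar[:, None]) ** 2, 0.0)).sum(axis=1)
        sxy = (np.where(finite, (xv[None, :] - xbar[:, None]) * (v - vbar[:, None]), 0.0)).sum(
            axis=1
        )
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    adj = v - slope[:, None] * (xv[None, :] - xbar[:, None])
    out[:, usable] = np.where(finite, adj, np.nan)
    return out


def adjust_covariate(
    matrix: MethylationMatrix,
    covariate: Sequence[float],
    within: Optional[Sequence] = None,
) -> MethylationMatrix:
    """Linearly adjust each CpG for a per-sample covariate.

    For each CpG (optionally within each level of ``within``, e.g. the
    phenotype) an ordinary least-squares fit of the values on the covariate
    is computed and the residuals, with the group mean re-added, replace the
    original values.  Missing values pass through untouched.
    """
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape[0] != matrix.n_samples:
        raise ValueError("covariate length must equal the number of samples")
    values = matrix.beta.copy()
    groups = np.asarray(within) if within is not None else np.zeros(matrix.n_samples)
    for g in pd.unique(groups):
        cols = groups == g
        if cols.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples; cannot adjust")
        values[:, cols] = _residualize(values[:, cols], covariate[cols])
    # residuals can stray marginally outside (0,1); nudge back for the container
    adjusted = np.where(np.isfinite(values), clip_beta(values, 1e-9), np.nan)
    return MethylationMatrix(adjusted, matrix.cpg_ids, matrix.sample_ids)


# ---------------------------------------------------------------------------
# Two-group tests


def bartlett_matrix(case_values: np.ndarray, control_values: np.ndarray) -> pd.DataFrame:
    """Row-wise two-group Bartlett test of equal variances.

    Returns a frame with the chi-square statistic (1 degree of freedom), its
    p-value, the case/control variance ratio and its log2 (the b-statistic).
    Rows with fewer than two observations in either group, or zero variance
    in both, get NaN statistics.
    """
    n1, _, s1 = _nan_moments(np.atleast_2d(case_values))
    n0, _, s0 = _nan_moments(np.atleast_2d(control_values))
    N = n1 + n0
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * s1 + (n0 - 1) * s0) / (N - 2)
        correction = 1.0 + (1.0 / (n1 - 1) + 1.0 / (n0 - 1) - 1.0 / (N - 2)) / 3.0
        stat = ((N - 2) * np.log(sp2) - (n1 - 1) * np.log(s1) - (n0 - 1) * np.log(s0)) / correction
        var_ratio = s1 / s0
        b_stat = np.log2(var_ratio)
    testable = (n1 >= 2) & (n0 >= 2) & ((s1 > 0) | (s0 > 0))
    one_sided_zero = testable & ((s1 == 0) | (s0 == 0))
    stat = np.where(testable, stat, np.nan)
    stat = np.where(one_sided_zero, np.inf, stat)
    p = np.where(np.isfinite(stat), stats.chi2.sf(np.where(np.isfinite(stat), stat, 0.0), 1), np.nan)
    p = np.where(one_sided_zero, 0.0, p)
    var_ratio = np.where(testable, var_ratio, np.nan)
    b_stat = np.where(testable, b_stat, np.nan)
    return pd.DataFrame(
        {"bartlett_stat": stat, "p_bartlett": p, "var_ratio": var_ratio, "b_stat": b_stat}
    )


def bartlett_two_group(x, y) -> dict:
    """Bartlett's test for two vectors (cases ``x`` vs controls ``y``).

    Zero variance in both groups yields ``p = nan`` (untestable) rather than
    an exception; fewer than two observations in a group is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isfinite(x).sum() < 2 or np.isfinite(y).sum() < 2:
        raise ValueError("Bartlett's test needs at least 2 non-missing values per group")
    row = bartlett_matrix(x[None, :], y[None, :]).iloc[0]
    return {
        "stat": float(row["bartlett_stat"]),
        "p": float(row["p_bartlett"]),
        "var_ratio": float(row["var_ratio"]),
        "b_stat": float(row["b_stat"]),
    }


def ttest_matrix(case_values: np.ndarray, control_values: np.ndarray) -> pd.DataFrame:
    """Row-wise Welch t-test; mean_diff = mean(cases) - mean(controls)."""
    case_values = np.atleast_2d(case_values)
    control_values = np.atleast_2d(control_values)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case_values, control_values, axis=1, equal_var=False, nan_policy="omit")
    _, m1, _ = _nan_moments(case_values)
    _, m0, _ = _nan_moments(control_values)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    return pd.DataFrame({"t_stat": t, "p_t": p, "mean_diff": m1 - m0})


def ttest_two_group(x, y) -> dict:
    """Welch two-sample t-test for vectors (cases ``x`` vs controls ``y``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isfinite(x).sum() < 2 or np.isfinite(y).sum() < 2:
        raise ValueError("t-test needs at least 2 non-missing values per group")
    row = ttest_matrix(x[None, :], y[None, :]).iloc[0]
    return {"t_stat": float(row["t_stat"]), "p": float(row["p_t"]), "mean_diff": float(row["mean_diff"])}


# ---------------------------------------------------------------------------
# Age association


def _ols_tstats(Y: np.ndarray, X: np.ndarray, coef_index: int):
    """t-statistic of one coefficient for many responses sharing a design.

    Y is (n_samples, n_responses); X is (n_samples, n_params).  Responses
    containing NaN are refit on their complete cases.
    """
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than samples in regression design")
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    hjj = XtX_inv[coef_index, coef_index]

    def fit_block(Yb):
        B = H @ Yb
        resid = Yb - X @ B
        dof = n - p
        s2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(s2 * hjj)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, B[coef_index] / np.where(se > 0, se, 1.0), np.nan)
        pvals = 2.0 * stats.t.sf(np.abs(t), dof)
        pvals = np.where(np.isfinite(t), pvals, np.nan)
        constant = np.ptp(Yb, axis=0) == 0  # degenerate response: untestable
        slope_out = np.where(constant, 0.0, B[coef_index])
        return slope_out, np.where(constant, np.nan, t), np.where(constant, np.nan, pvals)

    has_nan = ~np.isfinite(Y).all(axis=0)
    slope = np.empty(Y.shape[1])
    tstat = np.empty(Y.shape[1])
    pval = np.empty(Y.shape[1])
    if (~has_nan).any():
        s, t, pv = fit_block(Y[:, ~has_nan])
        slope[~has_nan], tstat[~has_nan], pval[~has_nan] = s, t, pv
    for j in np.flatnonzero(has_nan):
        ok = np.isfinite(Y[:, j])
        if ok.sum() <= p:
            slope[j] = tstat[j] = pval[j] = np.nan
            continue
        Xj = X[ok]
        XtX_inv_j = np.linalg.pinv(Xj.T @ Xj)
        Bj = XtX_inv_j @ Xj.T @ Y[ok, j]
        resid = Y[ok, j] - Xj @ Bj
        dofj = ok.sum() - p
        s2 = (resid**2).sum() / dofj
        se = np.sqrt(s2 * XtX_inv_j[coef_index, coef_index])
        slope[j] = Bj[coef_index]
        if se > 0:
            tstat[j] = Bj[coef_index] / se
            pval[j] = 2.0 * stats.t.sf(abs(tstat[j]), dofj)
        else:
            tstat[j] = pval[j] = np.nan
    return slope, tstat, pval


def age_association(
    matrix: MethylationMatrix,
    annotation: SampleAnnotation,
    adjust_for_status: bool = True,
) -> pd.DataFrame:
    """Per-CpG linear regression of beta on age.

    When ``adjust_for_status`` the case/control status enters as an additive
    covariate, so the age slope is estimated net of phenotype differences.
    Returns one row per CpG with the slope (beta per year), t-statistic,
    p-value, Storey q-value, and the direction label (``hyper`` for positive
    slopes — methylation gained with age).
    """
    ann = annotation.reindex(matrix.sample_ids)
    age = ann.age
    if np.ptp(age) == 0:
        raise ValueError("age is constant across samples; age association undefined")
    if len(np.unique(age)) < 2 or matrix.n_samples < 10:
        raise ValueError("age association needs >= 10 samples with distinct ages")
    cols = [np.ones(matrix.n_samples), age]
    if adjust_for_status:
        cols.append(ann.is_case().astype(float))
    X = np.column_stack(cols)
    slope, t, p = _ols_tstats(matrix.beta.T, X, coef_index=1)
    q = estimate_qvalues(p)
    out = pd.DataFrame(
        {
            "cpg_id": matrix.cpg_ids,
            "slope": slope,
            "t_age": t,
            "p_age": p,
            "q_age": q,
            "direction": np.where(slope > 0, "hyper", "hypo"),
        }
    )
    return out


# ---------------------------------------------------------------------------
# q-values (Storey FDR)


def estimate_pi0(pvals: np.ndarray) -> float:
    """Estimate the null proportion pi0 by the cubic smoother over a lambda grid.

    Falls back to 1.0 (pure Benjamini-Hochberg behaviour) when the estimate
    is unstable (out of (0, 1], too few p-values, or a failed fit).
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    m = p.size
    if m < 100:
        return 1.0
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    try:
        coeffs = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coeffs, lam.max()))
    except Exception:
        return 1.0
    if not np.isfinite(pi0) or pi0 <= 0.0 or pi0 > 1.0:
        return 1.0
    return pi0


def estimate_qvalues(pvals, pi0: Optional[float] = None) -> np.ndarray:
    """Storey q-values: pi0-scaled Benjamini-Hochberg step-up, monotone in p.

    NaN p-values propagate to NaN q-values; ``pi0=None`` estimates the null
    proportion from the data (see :func:`estimate_pi0`).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    ok = np.isfinite(p)
    if ok.any() and ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    if pi0 is None:
        pi0 = estimate_pi0(pv)
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(pi0 * ranked, 1.0)
    q[ok] = qv
    return q


# ---------------------------------------------------------------------------
# Ranked tables


def _phenotype_values(matrix, annotation, adjust_age, adjust_hpv, scale):
    ann = annotation.reindex(matrix.sample_ids)
    values = np.array(convert_scale(matrix.beta, scale))  # copy: never mutate the input
    is_case = ann.is_case()
    if not is_case.any() or is_case.all():
        raise ValueError("both phenotypes (case and control) must be present")
    if adjust_age:
        for group in (is_case, ~is_case):
            values[:, group] = _residualize(values[:, group], ann.age[group])
    if adjust_hpv:
        hpv_num = np.where(ann.hpv == "positive", 1.0, np.where(ann.hpv == "negative", 0.0, np.nan))
        if np.isfinite(hpv_num).sum() >= 6 and len(np.unique(hpv_num[np.isfinite(hpv_num)])) > 1:
            for group in (is_case, ~is_case):
                values[:, group] = _residualize(values[:, group], hpv_num[group])
    return values, is_case, ann


def rank_dvcs(
    matrix: MethylationMatrix,
    annotation: SampleAnnotation,
    adjust_age: bool = True,
    adjust_hpv: bool = False,
    scale: str = "beta",
    cpg_annotation=None,
) -> pd.DataFrame:
    """Rank CpGs by differential variability between cases and controls.

    Runs Bartlett's test (variance) and a Welch t-test (mean) per CpG on
    age-adjusted values, attaches Storey q-values for both, labels each CpG
    ``hypervariable`` (variance greater in cases) or ``hypovariable``, and
    sorts ascending by Bartlett p-value with ties broken by CpG identifier.
    The mean difference is always reported in beta units.
    """
    values, is_case, _ = _phenotype_values(matrix, annotation, adjust_age, adjust_hpv, scale)
    bart = bartlett_matrix(values[:, is_case], values[:, ~is_case])
    tt = ttest_matrix(matrix.beta[:, is_case], matrix.beta[:, ~is_case])
    table = pd.concat([bart, tt], axis=1)
    table.insert(0, "cpg_id", matrix.cpg_ids)
    table["q_bartlett"] = estimate_qvalues(table["p_bartlett"].to_numpy())
    table["q_t"] = estimate_qvalues(table["p_t"].to_numpy())
    table["direction"] = np.where(table["var_ratio"] > 1, "hypervariable", "hypovariable")
    if cpg_annotation is not None:
        meta = cpg_annotation.frame[["cpg_id", "entrez_id", "gene_symbol"]]
        table = table.merge(meta, on="cpg_id", how="left")
    table = table.sort_values(
        ["p_bartlett", "cpg_id"], ascending=[True, True], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return table


def rank_vcpgs(
    matrix: MethylationMatrix,
    age: Sequence[float],
    scale: str = "beta",
) -> pd.DataFrame:
    """Rank CpGs by age-adjusted variance across *all* samples.

    These "variable CpGs" capture large phenotype-independent spread (for
    example cell-composition differences) and are distinct from CpGs whose
    variance differs *between* phenotypes.
    """
    values = np.array(convert_scale(matrix.beta, scale))
    values = _residualize(values, np.asarray(age, dtype=float))
    _, _, var = _nan_moments(values)
    out = pd.DataFrame({"cpg_id": matrix.cpg_ids, "variance": var})
    out = out.sort_values(
        ["variance", "cpg_id"], ascending=[False, True], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return out
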