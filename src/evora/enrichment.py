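"""Gene-set enrichment of CpG rankings.

Provides one-tailed Fisher's exact enrichment of a selected CpG set in a
binary category (e.g. polycomb-group-target genes), a relative odds ratio
(ROR) contrasting category enrichment among hypervariable versus
hypovariable top-ranked CpGs with a label-permutation null, and an exact
binomial test for directional skew.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .varstats import rank_dvcs

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "RorResult",
    "relative_odds_ratio",
    "binomial_skew",
]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    a: int  # selected & in category
    b: int  # selected & not in category
    c: int  # not selected & in category
    d: int  # not selected & not in category
    odds_ratio: float
    ci95: tuple
    p_one_tailed: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to OR/CI


def _odds_ratio_ci(a, b, c, d):
    """OR with Haldane-Anscombe 0.5 correction on zero cells; Woolf-logit CI."""
    corrected = 0 in (a, b, c, d)
    if corrected:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
    else:
        a2, b2, c2, d2 = a, b, c, d
    odds = (a2 * d2) / (b2 * c2)
    se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    lo = float(np.exp(np.log(odds) - 1.96 * se))
    hi = float(np.exp(np.log(odds) + 1.96 * se))
    return float(odds), (lo, hi), corrected


def fisher_enrichment(
    selected: set,
    category: Callable[[str], bool] | dict | set,
    universe: set,
    set_name: str = "category",
) -> EnrichmentResult:
    """One-tailed (greater) Fisher's exact enrichment of ``selected`` in a category.

    ``category`` may be a set of member CpGs, a dict mapping CpG to bool, or a
    callable.  The p-value is the hypergeometric upper tail; the odds ratio
    uses the Haldane-Anscombe 0.5 correction when a cell is zero, with a
    Woolf-logit 95% confidence interval.
    """
    universe = set(universe)
    selected = set(selected)
    if not universe or not selected:
        raise ValueError("universe and selected set must be non-empty")
    if not selected <= universe:
        raise ValueError("selected CpGs must be a subset of the universe")
    if isinstance(category, set):
        in_cat = lambda c: c in category  # noqa: E731
    elif isinstance(category, dict):
        in_cat = lambda c: bool(category.get(c, False))  # noqa: E731
    else:
        in_cat = category
    a = sum(1 for c in selected if in_cat(c))
    b = len(selected) - a
    c_ = sum(1 for c in universe - selected if in_cat(c))
    d = len(universe) - len(selected) - c_
    _, p = stats.fisher_exact([[a, b], [c_, d]], alternative="greater")
    odds, ci, corrected = _odds_ratio_ci(a, b, c_, d)
    return EnrichmentResult(
        set_name=set_name,
        a=a,
        b=b,
        c=c_,
        d=d,
        odds_ratio=odds,
        ci95=ci,
        p_one_tailed=float(p),
        corrected=corrected,
    )


@dataclass(frozen=True)
class RorResult:
    ror_observed: float
    ror_null: np.ndarray
    p_perm: float


def _ror_from_table(table: pd.DataFrame, category: set, universe: set, top_k: int) -> float:
    top = table.head(top_k)
    hyper = set(top.loc[top["var_ratio"] > 1, "cpg_id"])
    hypo = set(top.loc[~(top["var_ratio"] > 1), "cpg_id"])
    if not hyper or not hypo:
        return np.nan
    or_hyper = fisher_enrichment(hyper, category, universe).odds_ratio
    or_hypo = fisher_enrichment(hypo, category, universe).odds_ratio
    return or_hyper / or_hypo


def relative_odds_ratio(
    matrix,
    annotation,
    category: set,
    top_k: int = 500,
    n_perm: int = 50,
    seed: Optional[int] = None,
    adjust_age: bool = True,
) -> RorResult:
    """Relative odds ratio of category enrichment, hypervariable vs hypovariable.

    ROR = OR(category among top-k CpGs more variable in cases) /
    OR(category among top-k CpGs less variable in cases).  The null
    distribution re-ranks CpGs after random permutation of the case/control
    labels; the permutation p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    ann = annotation.reindex(matrix.sample_ids)
    if top_k > matrix.n_cpgs:
        raise ValueError("top_k exceeds the number of CpGs")
    universe = set(matrix.cpg_ids)
    observed_table = rank_dvcs(matrix, ann, adjust_age=adjust_age)
    observed = _ror_from_table(observed_table, category, universe, top_k)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    frame = ann.frame
    for i in range(n_perm):
        perm = frame.copy()
        perm["status"] = rng.permutation(perm["status"].to_numpy())
        perm_ann = type(ann)(perm)
        table = rank_dvcs(matrix, perm_ann, adjust_age=adjust_age)
        null[i] = _ror_from_table(table, category, universe, top_k)
    valid = np.isfinite(null)
    p_perm = (1 + np.sum(null[valid] >= observed)) / (1 + valid.sum())
    return RorResult(ror_observed=float(observed), ror_null=null, p_perm=float(p_perm))


def binomial_skew(k: int, n: int, p0: float = 0.5, tail: str = "two_sided") -> float:
    """Exact binomial test of a directional skew (k successes out of n).

    Two-sided p doubles the smaller tail, capped at 1; one-sided tails are
    ``greater`` and ``less``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    if tail == "greater":
        return float(upper)
    if tail == "less":
        return float(lower)
    if tail == "two_sided":
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown tail {tail!r}")
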