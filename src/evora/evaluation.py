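"""ROC/AUC evaluation, Wilcoxon tests and repeated train/test experiments.

AUC is the Mann-Whitney estimator (ties count one half), identical to the
C-index for binary outcomes; its confidence interval comes from a stratified
percentile bootstrap.  :func:`repeated_holdout` re-trains the risk
classifiers on many stratified splits and compares their held-out AUCs —
per algorithm against the chance value 0.5 and paired between algorithms —
with Wilcoxon tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = [
    "mann_whitney_auc",
    "RocResult",
    "roc_auc",
    "wilcoxon_tests",
    "PartitionExperiment",
    "repeated_holdout",
]


def mann_whitney_auc(scores, labels) -> float:
    """Tie-corrected AUC: P(score_case > score_control) + 0.5 P(equal)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = labels.sum()
    n0 = (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class RocResult:
    """AUC with bootstrap confidence interval and the ROC curve points."""

    auc: float
    ci95: tuple
    curve: pd.DataFrame  # columns fpr, sensitivity, threshold


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> RocResult:
    """AUC (Mann-Whitney), ROC curve, and stratified percentile-bootstrap CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    auc = mann_whitney_auc(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "sensitivity": tpr, "threshold": thr})
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        boots[b] = mann_whitney_auc(scores[take], labels[take])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, auc), max(hi, auc)
    return RocResult(auc=auc, ci95=(float(lo), float(hi)), curve=curve)


def wilcoxon_tests(
    x,
    y: Optional[Sequence[float]] = None,
    mu0: float = 0.0,
    paired: bool = False,
) -> float:
    """Wilcoxon p-value: signed-rank (one sample vs ``mu0`` or paired) or
    rank-sum (two independent samples); exact for small n without ties."""
    x = np.asarray(x, dtype=float)
    if paired or y is None:
        diffs = x - mu0 if y is None else x - np.asarray(y, dtype=float)
        diffs = diffs[np.isfinite(diffs)]
        if np.all(diffs == 0):
            import warnings

            warnings.warn("all paired differences are zero; p = 1")
            return 1.0
        method = "exact" if len(diffs) <= 25 and len(np.unique(np.abs(diffs))) == len(diffs) else "approx"
        return float(stats.wilcoxon(diffs, zero_method="wilcox", method=method).pvalue)
    y = np.asarray(y, dtype=float)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


@dataclass(frozen=True)
class PartitionExperiment:
    """Per-partition held-out AUCs for each algorithm plus Wilcoxon summaries."""

    aucs: pd.DataFrame  # one column per algorithm, one row per partition
    p_vs_chance: dict  # algorithm -> signed-rank p against AUC = 0.5
    p_paired: Optional[float]  # paired test between the two algorithms
    n_failed: int
    train_fraction: float
    seed: Optional[int]


def repeated_holdout(
    matrix,
    annotation,
    algorithms: Sequence[str] = ("evora", "mean"),
    n_partitions: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: Optional[int] = None,
    folds: int = 10,
    **train_kwargs,
) -> PartitionExperiment:
    """Repeated stratified train/test partitions comparing risk classifiers.

    For each partition the requested algorithms are trained on the training
    part only (internal CV included) and their risk scores evaluated by AUC
    on the held-out part.  Partitions where training fails (e.g. no
    candidate CpGs) are excluded and counted; more than 20% failures is an
    error.
    """
    from .model import score_samples, train_evora, train_mean_comparator

    trainers = {"evora": train_evora, "mean": train_mean_comparator}
    unknown = set(algorithms) - set(trainers)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")
    ann = annotation.reindex(matrix.sample_ids)
    y = ann.is_case().astype(int)
    seed_base = 0 if seed is None else int(seed)
    splitter = StratifiedShuffleSplit(
        n_splits=n_partitions, train_size=train_fraction, random_state=seed_base
    )
    rows = []
    n_failed = 0
    for part, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
        train_m = matrix.select_samples(matrix.sample_ids[tr])
        test_m = matrix.select_samples(matrix.sample_ids[te])
        train_a = ann.reindex(train_m.sample_ids)
        row = {}
        try:
            for alg in algorithms:
                model = trainers[alg](
                    train_m,
                    train_a,
                    folds=folds,
                    seed=(seed_base + 1009 * (part + 1)) % (2**31),
                    **train_kwargs,
                )
                scores = score_samples(model, test_m)["score"].to_numpy()
                row[alg] = mann_whitney_auc(scores, y[te])
        except ValueError:
            n_failed += 1
            continue
        rows.append(row)
    if n_partitions and n_failed > 0.2 * n_partitions:
        raise RuntimeError(f"{n_failed}/{n_partitions} partitions failed training")
    aucs = pd.DataFrame(rows)
    p_vs_chance = {
        alg: wilcoxon_tests(aucs[alg].to_numpy(), mu0=0.5, paired=True) for alg in algorithms
    }
    p_paired = None
    if len(algorithms) == 2:
        a, b = algorithms
        p_paired = wilcoxon_tests(aucs[a].to_numpy(), aucs[b].to_numpy(), paired=True)
    return PartitionExperiment(
        aucs=aucs,
        p_vs_chance=p_vs_chance,
        p_paired=p_paired,
        n_failed=n_failed,
        train_fraction=train_fraction,
        seed=seed,
    )
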