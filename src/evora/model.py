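"""Adaptive-index risk classifiers over methylation outlier profiles.

:class:`EvoraClassifier` implements EVORA (Epigenetic Variable Outliers for
Risk prediction Analysis): candidate risk CpGs are those that are both
hypervariable in cases (Bartlett q-value) and hypermethylated with age
(regression q-value); an internal stratified cross-validation over
COPA-transformed profiles picks the outlier threshold and the number of
top-ranked CpGs that maximise held-out AUC; a sample's risk score is then
the fraction of risk CpGs whose COPA score exceeds the threshold.

:class:`MeanMethylationClassifier` is the matched comparator that selects
candidates by differential *mean* methylation (t-test q-value) instead of
differential variability, with the COPA basis, cross-validation and scoring
machinery left identical — so any performance gap isolates the
variability-versus-mean contrast.

Both follow scikit-learn estimator conventions (``get_params``/``set_params``,
``fit(X, y)`` with X of shape (n_samples, n_features), fitted attributes with
trailing underscores) and compose with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .copa import CopaParams, copa_transform, fit_copa_params
from .evaluation import mann_whitney_auc
from .matrix import MethylationMatrix, SampleAnnotation
from .varstats import age_association, rank_dvcs

__all__ = [
    "RiskModel",
    "EvoraClassifier",
    "MeanMethylationClassifier",
    "select_candidates",
    "train_evora",
    "train_mean_comparator",
    "score_samples",
    "score_samples_beta",
]

SCHEMA_VERSION = 1

COPA_THRESHOLD_GRID = (2.0, 3.0, 4.0, 5.0, 7.0, 10.0)
BETA_THRESHOLD_GRID = (0.1, 0.15, 0.2, 0.25, 0.3)
SIZE_GRID = (25, 50, 100, 140, 200, None)  # None = all candidates


# ---------------------------------------------------------------------------
# Trained-model container


@dataclass
class RiskModel:
    """A trained risk model: risk CpGs, frozen COPA parameters, threshold."""

    risk_cpgs: list
    copa_params: CopaParams
    threshold: float
    scale: str = "copa"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.risk_cpgs) == 0:
            raise ValueError("risk model requires a non-empty risk CpG set")
        if not self.threshold > 0:
            raise ValueError("outlier threshold must be positive")
        params = self.copa_params.subset(self.risk_cpgs)
        if not params.usable.all():
            bad = list(pd.Index(self.risk_cpgs)[~params.usable])
            raise ValueError(f"risk CpGs without usable COPA parameters: {bad[:5]}")

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "risk_cpgs": list(map(str, self.risk_cpgs)),
            "copa_params": self.copa_params.subset(self.risk_cpgs).to_dict(),
            "threshold": float(self.threshold),
            "scale": self.scale,
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RiskModel":
        version = payload.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"model schema version {version!r} not supported (expected {SCHEMA_VERSION})"
            )
        return cls(
            risk_cpgs=list(payload["risk_cpgs"]),
            copa_params=CopaParams.from_dict(payload["copa_params"]),
            threshold=float(payload["threshold"]),
            scale=payload["scale"],
            training_meta=payload.get("training_meta", {}),
        )


def _hit_values(model: RiskModel, matrix: MethylationMatrix, scale: str) -> tuple:
    """Per-(risk CpG, sample) normalised values on the requested basis."""
    wanted = pd.Index(model.risk_cpgs)
    present = wanted[wanted.isin(matrix.cpg_ids)]
    missing_frac = 1.0 - len(present) / len(wanted)
    if missing_frac > 0.10:
        raise ValueError(
            f"{missing_frac:.0%} of risk CpGs absent from the matrix (> 10% tolerated)"
        )
    sub = matrix.select_cpgs(present)
    params = model.copa_params.subset(present)
    if scale == "copa":
        values = copa_transform(sub, params).to_numpy()
    elif scale == "beta":
        values = sub.beta - params.median[:, None]
    else:
        raise ValueError(f"unknown scoring scale {scale!r}")
    return values, sub.sample_ids


def _score_table(values: np.ndarray, sample_ids, threshold: float, scale: str) -> pd.DataFrame:
    finite = np.isfinite(values)
    hits = (np.where(finite, values, -np.inf) > threshold).sum(axis=0)
    n_used = finite.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n_used > 0, hits / np.where(n_used > 0, n_used, 1), np.nan)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "score": score,
            "n_hits": hits.astype(int),
            "n_cpgs_used": n_used.astype(int),
            "scale": scale,
        }
    )


def score_samples(model: RiskModel, matrix: MethylationMatrix) -> pd.DataFrame:
    """Risk score per sample: fraction of risk CpGs above the outlier threshold.

    Uses the model's frozen COPA parameters (or training medians on the beta
    scale).  Up to 10% of risk CpGs may be absent; the denominator is then
    the number of risk CpGs actually used.
    """
    values, sample_ids = _hit_values(model, matrix, model.scale)
    return _score_table(values, sample_ids, model.threshold, model.scale)


def score_samples_beta(
    model: RiskModel, matrix: MethylationMatrix, beta_threshold: float = 0.2
) -> pd.DataFrame:
    """Beta-scale scoring: a hit is a median-normalised beta exceeding the
    threshold (default 0.2, the scale of outlier methylation gains).

    Useful when outliers dominate the cohort (e.g. most cancers methylated),
    which compresses MAD-based COPA scores.
    """
    values, sample_ids = _hit_values(model, matrix, "beta")
    return _score_table(values, sample_ids, beta_threshold, "beta")


# ---------------------------------------------------------------------------
# Candidate selection


def select_candidates(
    dvc: pd.DataFrame,
    age: pd.DataFrame,
    fdr_dv: float = 0.05,
    fdr_age: float = 0.05,
    unusable: Optional[set] = None,
) -> pd.Index:
    """Candidate risk CpGs: hypervariable in cases AND hypermethylated with age.

    Keeps CpGs with Bartlett q < ``fdr_dv`` and case/control variance ratio
    > 1, intersected with age-regression q < ``fdr_age`` and positive age
    slope, minus COPA-unusable CpGs; ordered by ascending Bartlett p-value.
    """
    merged = dvc.merge(age[["cpg_id", "q_age", "slope"]], on="cpg_id", how="inner")
    keep = (
        (merged["q_bartlett"] < fdr_dv)
        & (merged["var_ratio"] > 1)
        & (merged["q_age"] < fdr_age)
        & (merged["slope"] > 0)
    )
    selected = merged.loc[keep.fillna(False)]
    if unusable:
        selected = selected[~selected["cpg_id"].isin(unusable)]
    selected = selected.sort_values(["p_bartlett", "cpg_id"], kind="mergesort")
    if selected.empty:
        raise ValueError(
            "no candidate risk CpGs at the given FDR cutoffs; loosen fdr_dv/fdr_age"
        )
    return pd.Index(selected["cpg_id"])


def _fallback_rank(
    table: pd.DataFrame, keep, p_col: str, top: int, unusable: Optional[set]
) -> pd.Index:
    selected = table.loc[keep.fillna(False)]
    if unusable:
        selected = selected[~selected["cpg_id"].isin(unusable)]
    selected = selected.sort_values([p_col, "cpg_id"], kind="mergesort").head(top)
    if selected.empty:
        raise ValueError("no direction-consistent candidate CpGs at all")
    return pd.Index(selected["cpg_id"])


def _select_mean_candidates(
    dvc: pd.DataFrame, fdr_dm: float, unusable: Optional[set] = None
) -> pd.Index:
    keep = (dvc["q_t"] < fdr_dm) & (dvc["mean_diff"] > 0)
    selected = dvc.loc[keep.fillna(False)]
    if unusable:
        selected = selected[~selected["cpg_id"].isin(unusable)]
    selected = selected.sort_values(["p_t", "cpg_id"], kind="mergesort")
    if selected.empty:
        raise ValueError("no candidate CpGs at the given mean-methylation FDR cutoff")
    return pd.Index(selected["cpg_id"])


# ---------------------------------------------------------------------------
# Estimators


class _AdaptiveIndexBase(BaseEstimator, ClassifierMixin):
    """Shared machinery: internal CV over (threshold, set size), COPA basis."""

    _scoring_scale = "copa"

    def __init__(
        self,
        folds: int = 10,
        threshold_grid: Optional[Sequence[float]] = None,
        size_grid: Sequence[Optional[int]] = SIZE_GRID,
        fdr_dv: float = 0.05,
        fdr_age: float = 0.05,
        fdr_dm: float = 0.05,
        scale: str = "copa",
        adjust_age: bool = True,
        fallback_top: int = 200,
        random_state: Optional[int] = None,
    ):
        self.folds = folds
        self.threshold_grid = threshold_grid
        self.size_grid = size_grid
        self.fdr_dv = fdr_dv
        self.fdr_age = fdr_age
        self.fdr_dm = fdr_dm
        self.scale = scale
        self.adjust_age = adjust_age
        self.fallback_top = fallback_top
        self.random_state = random_state

    # -- subclass hook -------------------------------------------------
    def _rank_candidates(self, matrix, annotation, unusable) -> pd.Index:
        raise NotImplementedError

    # -- helpers ---------------------------------------------------------
    def _effective_threshold_grid(self) -> tuple:
        if self.threshold_grid is not None:
            return tuple(float(t) for t in self.threshold_grid)
        return COPA_THRESHOLD_GRID if self.scale == "copa" else BETA_THRESHOLD_GRID

    @staticmethod
    def _as_matrix(X) -> tuple:
        """Coerce (n_samples, n_cpgs) input into a CpG x sample matrix."""
        if isinstance(X, pd.DataFrame):
            cpg_ids = X.columns
            sample_ids = X.index.astype(str)
            values = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-dimensional (n_samples, n_cpgs)")
            cpg_ids = pd.Index([f"cpg{i}" for i in range(X.shape[1])])
            sample_ids = pd.Index([f"s{i}" for i in range(X.shape[0])])
            values = X
        return MethylationMatrix(values.T, cpg_ids, pd.Index(sample_ids))

    @staticmethod
    def _annotation(sample_ids, y, age) -> SampleAnnotation:
        status = np.where(np.asarray(y, dtype=bool), "case", "control")
        if age is None:
            age = np.zeros(len(sample_ids))
        return SampleAnnotation(
            pd.DataFrame({"sample_id": list(sample_ids), "status": status, "age": np.asarray(age)})
        )

    def _normalized(self, matrix, params, cpg_ids) -> np.ndarray:
        sub = matrix.select_cpgs(cpg_ids)
        p = params.subset(cpg_ids)
        if self.scale == "copa":
            return copa_transform(sub, p).to_numpy()
        return sub.beta - p.median[:, None]

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y, age: Optional[Sequence[float]] = None):
        matrix = self._as_matrix(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("need exactly two classes (case/control) to train")
        y_bin = (y == self.classes_[1]).astype(int)
        counts = np.bincount(y_bin)
        if counts.min() < self.folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples < folds={self.folds}; "
                "reduce the number of folds"
            )
        if age is not None:
            age = np.asarray(age, dtype=float)
        thr_grid = self._effective_threshold_grid()
        size_grid = tuple(self.size_grid)
        seed = 0 if self.random_state is None else int(self.random_state)
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=seed)
        fold_aucs = np.full((len(thr_grid), len(size_grid), self.folds), np.nan)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y_bin)), y_bin)):
            try:
                auc = self._fold_aucs(matrix, y_bin, age, tr, te, thr_grid, size_grid)
            except ValueError:
                continue  # fold without candidates contributes no AUCs
            fold_aucs[:, :, fold] = auc
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid cells
            mean_auc = np.nanmean(fold_aucs, axis=2)
        if not np.isfinite(mean_auc).any():
            raise ValueError("no (threshold, size) pair with a computable CV AUC")
        self.cv_results_ = pd.DataFrame(
            [
                {"threshold": t, "size": s, "mean_auc": mean_auc[i, j]}
                for i, t in enumerate(thr_grid)
                for j, s in enumerate(size_grid)
            ]
        )
        t_star, s_star = self._pick(mean_auc, thr_grid, size_grid)
        # final refit on all training samples
        train_ids = matrix.sample_ids
        annotation = self._annotation(train_ids, y_bin, age)
        params = fit_copa_params(matrix)
        unusable = set(matrix.cpg_ids[~params.usable])
        candidates = self._rank_candidates(matrix, annotation, unusable)
        n_keep = len(candidates) if s_star is None else min(int(s_star), len(candidates))
        risk = list(candidates[:n_keep])
        meta = {
            "seed": seed,
            "folds": self.folds,
            "threshold_grid": list(thr_grid),
            "size_grid": [s if s is None else int(s) for s in size_grid],
            "selection_fdr": {
                "fdr_dv": self.fdr_dv,
                "fdr_age": self.fdr_age,
                "fdr_dm": self.fdr_dm,
            },
            "algorithm": type(self).__name__,
            "n_candidates": len(candidates),
            # CV AUC of the selected (threshold, size) pair: optimism-biased
            # upward under the null because it is a maximum over the grid
            "cv_mean_auc": float(np.nanmax(mean_auc)),
            # grid-average CV AUC: the calibrated permutation-null quantity
            "cv_grid_mean_auc": float(np.nanmean(mean_auc[np.isfinite(mean_auc)])),
        }
        self.model_ = RiskModel(
            risk_cpgs=risk,
            copa_params=params.subset(risk),
            threshold=float(t_star),
            scale=self.scale,
            training_meta=meta,
        )
        self.risk_cpgs_ = risk
        self.threshold_ = float(t_star)
        self.set_size_ = n_keep
        self.copa_params_ = self.model_.copa_params
        # ancillary class-label cutoff for predict(): best balanced accuracy on training scores
        train_scores = self._scores_for(matrix)
        self.predict_cutoff_ = _best_cutoff(train_scores, y_bin)
        self.n_features_in_ = matrix.n_cpgs
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def _fold_aucs(self, matrix, y_bin, age, tr, te, thr_grid, size_grid) -> np.ndarray:
        """Grid of held-out AUCs for one CV fold (statistics fit on ``tr`` only)."""
        train = matrix.select_samples(matrix.sample_ids[tr])
        test = matrix.select_samples(matrix.sample_ids[te])
        annotation = self._annotation(train.sample_ids, y_bin[tr], None if age is None else age[tr])
        params = fit_copa_params(train)
        unusable = set(train.cpg_ids[~params.usable])
        candidates = self._rank_candidates(train, annotation, unusable)
        values = self._normalized(test, params, candidates)
        finite = np.isfinite(values)
        auc = np.full((len(thr_grid), len(size_grid)), np.nan)
        y_test = y_bin[te]
        for j, s in enumerate(size_grid):
            eff = len(candidates) if s is None else min(int(s), len(candidates))
            if eff == 0:
                continue
            vals = values[:eff]
            fin = finite[:eff]
            n_used = fin.sum(axis=0)
            for i, t in enumerate(thr_grid):
                hits = (np.where(fin, vals, -np.inf) > t).sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    scores = np.where(n_used > 0, hits / np.where(n_used > 0, n_used, 1), np.nan)
                if len(np.unique(y_test)) < 2 or not np.isfinite(scores).all():
                    continue
                auc[i, j] = mann_whitney_auc(scores, y_test)
        return auc

    @staticmethod
    def _pick(mean_auc: np.ndarray, thr_grid, size_grid) -> tuple:
        """Best (threshold, size); ties favour the smaller size, then threshold."""
        best = np.nanmax(mean_auc)
        ties = np.argwhere(np.abs(mean_auc - best) <= 1e-12)
        size_key = [np.inf if size_grid[j] is None else size_grid[j] for j in range(len(size_grid))]
        ties = sorted(ties, key=lambda ij: (size_key[ij[1]], thr_grid[ij[0]]))
        i, j = ties[0]
        return thr_grid[i], size_grid[j]

    # -- prediction -------------------------------------------------------
    def _scores_for(self, matrix) -> np.ndarray:
        table = score_samples(self.model_, matrix)
        return table["score"].to_numpy()

    def decision_function(self, X) -> np.ndarray:
        """Risk score per sample: fraction of risk CpGs that are outlier hits."""
        check_is_fitted(self, "model_")
        return self._scores_for(self._as_matrix(X))

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_function(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        s = self.decision_function(X)
        return self.classes_[(s > self.predict_cutoff_).astype(int)]


def _best_cutoff(scores: np.ndarray, y_bin: np.ndarray) -> float:
    """Score cutoff maximising balanced accuracy on the training samples."""
    cuts = np.unique(scores)
    best_cut, best_acc = 0.5, -np.inf
    for c in cuts:
        pred = scores > c
        sens = pred[y_bin == 1].mean() if (y_bin == 1).any() else 0.0
        spec = (~pred[y_bin == 0]).mean() if (y_bin == 0).any() else 0.0
        acc = 0.5 * (sens + spec)
        if acc > best_acc:
            best_cut, best_acc = float(c), acc
    return best_cut


class EvoraClassifier(_AdaptiveIndexBase):
    """EVORA: risk CpGs from differential variability x age hypermethylation.

    Parameters
    ----------
    folds : internal stratified CV folds (default 10).
    threshold_grid : COPA outlier thresholds searched (default 2..10; beta
        offsets 0.1..0.3 when ``scale='beta'``).
    size_grid : candidate-set sizes searched; ``None`` means all candidates.
    fdr_dv, fdr_age : q-value cutoffs for the variability and age tests.
    scale : ``'copa'`` (robust z of beta) or ``'beta'`` (median-normalised beta).
    adjust_age : age-adjust variances within each phenotype before testing.
    random_state : seed for the CV fold assignment.

    Attributes (after fit)
    ----------------------
    risk_cpgs_, threshold_, set_size_, copa_params_, cv_results_, model_.
    """

    def _rank_candidates(self, matrix, annotation, unusable) -> pd.Index:
        dvc = rank_dvcs(matrix, annotation, adjust_age=self.adjust_age)
        age = age_association(matrix, annotation, adjust_for_status=True)
        try:
            return select_candidates(dvc, age, self.fdr_dv, self.fdr_age, unusable)
        except ValueError:
            # nothing genome-wide significant: fall back to the top-ranked
            # direction-consistent CpGs so cross-validation stays defined
            merged = dvc.merge(age[["cpg_id", "slope"]], on="cpg_id", how="inner")
            keep = (merged["var_ratio"] > 1) & (merged["slope"] > 0)
            return _fallback_rank(merged, keep, "p_bartlett", self.fallback_top, unusable)


class MeanMethylationClassifier(_AdaptiveIndexBase):
    """Comparator selecting candidates by differential mean methylation.

    Identical cross-validation, COPA basis and scoring to
    :class:`EvoraClassifier`; only the candidate ranking differs (Welch
    t-test q-values with positive mean difference, ordered by t-test
    p-value).
    """

    def _rank_candidates(self, matrix, annotation, unusable) -> pd.Index:
        dvc = rank_dvcs(matrix, annotation, adjust_age=self.adjust_age)
        try:
            return _select_mean_candidates(dvc, self.fdr_dm, unusable)
        except ValueError:
            keep = dvc["mean_diff"] > 0
            return _fallback_rank(dvc, keep, "p_t", self.fallback_top, unusable)


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimators


def _fit_wrapper(cls, matrix, annotation, folds, threshold_grid, size_grid, seed, **fdr):
    ann = annotation.reindex(matrix.sample_ids)
    est = cls(
        folds=folds,
        threshold_grid=threshold_grid,
        size_grid=size_grid if size_grid is not None else SIZE_GRID,
        random_state=seed,
        **fdr,
    )
    X = pd.DataFrame(matrix.beta.T, index=matrix.sample_ids, columns=matrix.cpg_ids)
    est.fit(X, ann.is_case().astype(int), age=ann.age)
    return est.model_


def train_evora(
    matrix: MethylationMatrix,
    annotation: SampleAnnotation,
    folds: int = 10,
    threshold_grid=None,
    size_grid=None,
    fdr_dv: float = 0.05,
    fdr_age: float = 0.05,
    seed: Optional[int] = None,
    scale: str = "copa",
) -> RiskModel:
    """Train an EVORA risk model on a methylation matrix with annotation."""
    return _fit_wrapper(
        EvoraClassifier,
        matrix,
        annotation,
        folds,
        threshold_grid,
        size_grid,
        seed,
        fdr_dv=fdr_dv,
        fdr_age=fdr_age,
        scale=scale,
    )


def train_mean_comparator(
    matrix: MethylationMatrix,
    annotation: SampleAnnotation,
    folds: int = 10,
    threshold_grid=None,
    size_grid=None,
    fdr_dm: float = 0.05,
    seed: Optional[int] = None,
    scale: str = "copa",
) -> RiskModel:
    """Train the mean-methylation comparator with the same CV machinery."""
    return _fit_wrapper(
        MeanMethylationClassifier,
        matrix,
        annotation,
        folds,
        threshold_grid,
        size_grid,
        seed,
        fdr_dm=fdr_dm,
        scale=scale,
    )
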