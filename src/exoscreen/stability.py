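"""Ensemble feature selection with stability and consistency scoring.

Three complementary selectors are run on repeated stratified subsamples of
the training data:

* ``l1-logistic`` — L1-penalized logistic regression, penalty chosen by
  internal cross-validated log-loss; the selected set is the features with
  non-zero coefficients.
* ``rf-importance`` — random forest; the selected set is the ``top_k``
  features by mean impurity decrease.
* ``svm-rfe`` — recursive feature elimination with a linear maximum-margin
  classifier, ranking features by squared weight and removing the lowest
  10% of the remainder each round until ``top_k`` remain.

A feature's *stability score* under a selector is the fraction of the
(default 20) subsampling iterations in which it was selected.  A feature is
*consensus-flagged* when its stability is >= 0.5 under every selector.  The
*consistency score* (x/10) counts the outer cross-validation folds whose
training data consensus-flag the feature; it is assembled by the nested
evaluation driver, which aggregates fold-level :func:`stability_scores`
reports via :func:`aggregate_reports`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

SELECTOR_NAMES = ("l1-logistic", "rf-importance", "svm-rfe")

_warned_topk: set = set()


def _warn_topk_once(top_k: int, n_feat: int) -> None:
    key = (top_k, n_feat)
    if key not in _warned_topk:
        _warned_topk.add(key)
        logger.warning("top_k >= feature count (%d >= %d); returning all features",
                       top_k, n_feat)


@dataclass
class SelectorConfig:
    """Shared configuration of the selector ensemble."""

    n_iterations: int = 20
    subsample_frac: float = 0.8
    top_k: int = 20
    l1_c_grid: tuple = tuple(np.logspace(-4, 2, 7))
    l1_cv_folds: int = 5
    rf_trees: int = 500
    rfe_step_frac: float = 0.10
    svm_c: float = 1.0
    consensus_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.subsample_frac <= 1.0:
            raise ValueError("subsample_frac must be in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _standardize(X: np.ndarray) -> np.ndarray:
    return StandardScaler().fit(X).transform(X)


def _check_two_class(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes are required for supervised selection")
    if min(np.bincount(y.astype(int))) < 2:
        raise ValueError("need at least 2 samples per class")


def select_l1(X: np.ndarray, y: np.ndarray, config: SelectorConfig,
              seed: int = 0) -> set:
    """Indices of non-zero-coefficient features of a cross-validated L1 fit."""
    _check_two_class(y)
    Xs = _standardize(X)
    n_folds = min(config.l1_cv_folds, int(np.bincount(y.astype(int)).min()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = LogisticRegressionCV(
            Cs=list(config.l1_c_grid), penalty="l1", solver="liblinear",
            cv=max(2, n_folds), scoring="neg_log_loss", random_state=seed,
            max_iter=200,
        ).fit(Xs, y)
    coef = model.coef_.ravel()
    return set(np.flatnonzero(coef != 0.0).tolist())


def select_rf(X: np.ndarray, y: np.ndarray, config: SelectorConfig,
              seed: int = 0) -> set:
    """Top-``top_k`` features by random-forest mean impurity decrease."""
    _check_two_class(y)
    n_feat = X.shape[1]
    if config.top_k >= n_feat:
        _warn_topk_once(config.top_k, n_feat)
        return set(range(n_feat))
    model = RandomForestClassifier(
        n_estimators=config.rf_trees, random_state=seed, n_jobs=1
    ).fit(X, y)
    order = np.argsort(-model.feature_importances_, kind="stable")
    return set(order[: config.top_k].tolist())


def rf_importances(X: np.ndarray, y: np.ndarray, config: SelectorConfig,
                   seed: int = 0) -> np.ndarray:
    """Normalized mean-impurity-decrease importances (non-negative, sum 1)."""
    _check_two_class(y)
    model = RandomForestClassifier(
        n_estimators=config.rf_trees, random_state=seed, n_jobs=1).fit(X, y)
    return model.feature_importances_


def svmrfe_ranking(X: np.ndarray, y: np.ndarray, config: SelectorConfig,
                   seed: int = 0) -> list:
    """Full SVM-RFE elimination order, worst first (a permutation of columns).

    Each round fits a linear-kernel SVM on the surviving features, ranks them
    by squared weight, and removes the lowest ``rfe_step_frac`` fraction
    (at least one).  A non-converging fit is retried once with stronger
    regularization before raising.
    """
    _check_two_class(y)
    Xs = _standardize(X)
    surviving = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(surviving) > 1:
        sub = Xs[:, surviving]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = SVC(kernel="linear", C=config.svm_c, random_state=seed).fit(sub, y)
            if any("max_iter" in str(w.message).lower() for w in caught):
                model = SVC(kernel="linear", C=config.svm_c / 10.0,
                            random_state=seed).fit(sub, y)
        w2 = (model.coef_.ravel() ** 2)
        n_drop = max(1, int(np.floor(config.rfe_step_frac * len(surviving))))
        order = np.argsort(w2, kind="stable")  # ascending: worst first
        drop = [surviving[i] for i in order[:n_drop]]
        eliminated.extend(drop)
        surviving = [f for f in surviving if f not in set(drop)]
    eliminated.extend(surviving)
    return eliminated


def select_svmrfe(X: np.ndarray, y: np.ndarray, config: SelectorConfig,
                  seed: int = 0) -> set:
    """Last ``top_k`` survivors of the SVM-RFE elimination order."""
    n_feat = X.shape[1]
    if config.top_k >= n_feat:
        _warn_topk_once(config.top_k, n_feat)
        _check_two_class(y)
        return set(range(n_feat))
    order = svmrfe_ranking(X, y, config, seed)
    return set(order[-config.top_k:])


_BUILTIN_SELECTORS: Mapping[str, Callable] = {
    "l1-logistic": select_l1,
    "rf-importance": select_rf,
    "svm-rfe": select_svmrfe,
}


def stability_scores(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    config: SelectorConfig | None = None,
    seed: int = 0,
    selectors: Mapping[str, Callable] | None = None,
) -> pd.DataFrame:
    """Per-feature, per-selector stability over stratified subsampling runs.

    For each of ``config.n_iterations`` iterations a stratified subsample of
    ``subsample_frac`` of the samples is drawn without replacement and every
    selector is run on it; the stability score is the exact fraction of
    iterations in which the feature was selected.  ``selectors`` may override
    the built-in ensemble (e.g. with deterministic mocks in tests); each
    callable has signature ``f(X, y, config, seed) -> set of column indices``.

    Returns a DataFrame with columns ``feature_id``, one ``stab_<name>``
    column per selector, and ``consensus`` (stability >= threshold under
    every selector).
    """
    config = config or SelectorConfig()
    selectors = selectors or _BUILTIN_SELECTORS
    _check_two_class(y)
    y = np.asarray(y).astype(int)
    n = len(y)
    feature_ids = list(feature_ids)
    if X.shape[1] != len(feature_ids):
        raise ValueError("feature_ids length must match X columns")
    rng = np.random.default_rng(seed)
    counts = {name: np.zeros(X.shape[1], dtype=int) for name in selectors}
    for it in range(config.n_iterations):
        idx = _stratified_subsample(y, config.subsample_frac, rng)
        y_sub = y[idx]
        if len(np.unique(y_sub)) < 2:
            raise ValueError("subsample lost a class; increase subsample_frac")
        it_seed = int(rng.integers(0, 2**31 - 1))
        for name, fn in selectors.items():
            chosen = fn(X[idx], y_sub, config, it_seed)
            for f in chosen:
                counts[name][f] += 1
    report = pd.DataFrame({"feature_id": feature_ids})
    stab_cols = []
    for name in selectors:
        col = f"stab_{_short_name(name)}"
        report[col] = counts[name] / config.n_iterations
        stab_cols.append(col)
    report["consensus"] = np.all(
        [report[c] >= config.consensus_threshold for c in stab_cols], axis=0)
    return report


def _short_name(name: str) -> str:
    return {"l1-logistic": "l1", "rf-importance": "rf", "svm-rfe": "rfe"}.get(
        name, name.replace("-", "_"))


def _stratified_subsample(y: np.ndarray, frac: float, rng: np.random.Generator
                          ) -> np.ndarray:
    """Without-replacement subsample preserving class proportions."""
    idx_parts = []
    for cls in np.unique(y):
        cls_idx = np.flatnonzero(y == cls)
        n_take = max(1, int(round(frac * len(cls_idx))))
        idx_parts.append(rng.choice(cls_idx, size=min(n_take, len(cls_idx)),
                                    replace=False))
    return np.sort(np.concatenate(idx_parts))


def aggregate_reports(fold_reports: Sequence[pd.DataFrame],
                      all_feature_ids: Sequence[str],
                      consensus_threshold: float = 0.5) -> pd.DataFrame:
    """Combine per-fold stability reports into a cohort-level StabilityReport.

    Stability columns are averaged over the folds in which the feature was a
    candidate; ``consistency_num`` counts folds whose training data
    consensus-flagged the feature, out of ``consistency_den`` folds total.
    The cohort-level ``consensus`` flag applies the selector-intersection
    rule to the averaged stabilities (>= threshold under every selector).
    """
    all_feature_ids = list(all_feature_ids)
    n_folds = len(fold_reports)
    stab_cols = sorted({c for r in fold_reports for c in r.columns
                        if c.startswith("stab_")})
    sums = {c: pd.Series(0.0, index=all_feature_ids) for c in stab_cols}
    seen = pd.Series(0, index=all_feature_ids)
    flags = pd.Series(0, index=all_feature_ids)
    for rep in fold_reports:
        rep = rep.set_index("feature_id")
        seen.loc[rep.index] += 1
        flags.loc[rep.index[rep["consensus"]]] += 1
        for c in stab_cols:
            if c in rep:
                sums[c].loc[rep.index] += rep[c]
    out = pd.DataFrame({"feature_id": all_feature_ids})
    denom = seen.replace(0, np.nan)
    for c in stab_cols:
        out[c] = (sums[c] / denom).fillna(0.0).to_numpy()
    out["consistency_num"] = flags.to_numpy()
    out["consistency_den"] = n_folds
    out["consensus"] = np.all(
        [out[c] >= consensus_threshold for c in stab_cols], axis=0
    ) & (seen > 0).to_numpy()
    return out


@dataclass
class ConsensusPanel:
    """Ordered biomarker panel with its supporting scores."""

    feature_ids: list
    table: pd.DataFrame
    size: int


def consensus_panel(report: pd.DataFrame, de: pd.DataFrame, size: int
                    ) -> ConsensusPanel:
    """Build the consensus biomarker panel.

    Candidates are the consensus-flagged features of ``report``; they are
    ordered by (consistency desc, mean stability desc, adjusted p asc) and
    the first ``size`` are returned.  If fewer consensus features exist than
    requested, all are returned with a warning.
    """
    if size < 1:
        raise ValueError("panel size must be >= 1")
    stab_cols = [c for c in report.columns if c.startswith("stab_")]
    tbl = report.copy()
    tbl["mean_stability"] = tbl[stab_cols].mean(axis=1)
    padj = de.set_index("feature_id")["padj"]
    tbl["padj"] = tbl["feature_id"].map(padj).fillna(1.0).to_numpy()
    if "consistency_num" not in tbl:
        tbl["consistency_num"] = tbl["consensus"].astype(int)
        tbl["consistency_den"] = 1
    flagged = tbl[tbl["consensus"]].copy()
    flagged = flagged.sort_values(
        by=["consistency_num", "mean_stability", "padj", "feature_id"],
        ascending=[False, False, True, True], kind="stable")
    if len(flagged) < size:
        logger.warning("only %d consensus features for requested panel size %d",
                       len(flagged), size)
    chosen = flagged.head(size)
    return ConsensusPanel(list(chosen["feature_id"]), flagged.reset_index(drop=True),
                          min(size, len(flagged)))
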