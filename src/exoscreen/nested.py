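"""Leakage-safe nested cross-validation of biomarker panels.

Outer stratified 10-fold cross-validation estimates generalization; inside
each outer training partition (90% of samples) an inner stratified 5-fold
loop tunes an RBF-kernel SVM by grid search, SMOTE rebalances only training
data, and — in auto-selection mode — the whole candidate-screening cascade
(differential-expression gate, then the stability/consensus selector
ensemble) is recomputed from the fold's training counts, so no information
from a held-out test partition ever reaches feature selection, rebalancing,
tuning or threshold choice.

Operating point: the probability threshold maximizing Youden's J on the
training partition, applied unchanged to the test partition.  AUC confidence
intervals use the t-distribution over the outer-fold AUC values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import CountMatrix, NormalizedMatrix, SampleMeta
from .diffexpr import DEGate, nb_wald, select_de
from .stability import (SelectorConfig, aggregate_reports, consensus_panel,
                        stability_scores)

logger = logging.getLogger(__name__)


@dataclass
class CVScheme:
    """Outer/inner stratified cross-validation layout."""

    outer_folds: int = 10
    inner_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")


@dataclass
class ClassifierSpec:
    """RBF-SVM grid and rebalancing policy."""

    c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple | None = None  # None -> (1e-3, 1e-2, 1e-1, 1/n_features)
    rebalance: str = "smote"
    smote_k: int = 5

    def __post_init__(self) -> None:
        if not self.c_grid:
            raise ValueError("C grid must be non-empty")
        if self.rebalance not in ("smote", "none"):
            raise ValueError("rebalance must be 'smote' or 'none'")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")

    def gammas(self, n_features: int) -> tuple:
        if self.gamma_grid is not None:
            return tuple(self.gamma_grid)
        return (1e-3, 1e-2, 1e-1, 1.0 / max(n_features, 1))


@dataclass
class MetricSet:
    """Discrimination metrics and the ROC polyline they derive from."""

    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    roc_points: np.ndarray  # (n_points, 2) columns fpr, tpr
    threshold: float

    def as_dict(self) -> dict:
        return {"auc": self.auc, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "accuracy": self.accuracy,
                "threshold": self.threshold}


def smote_oversample(X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    New minority points are ``x + u * (neighbor - x)`` with ``u ~ U(0, 1)``
    and the neighbor drawn among the ``k`` nearest minority samples of ``x``.
    Originals are preserved verbatim (synthetic rows are appended) and the
    output classes are exactly balanced.  Already-balanced input is returned
    unchanged.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_new = int(abs(counts[0] - counts[1]))
    Xmin = X[y == minority]
    if len(Xmin) < 2:
        raise ValueError("minority class needs >= 2 samples for SMOTE")
    k_eff = min(k, len(Xmin) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    neigh = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xmin), size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.random(size=n_new)
    synth = Xmin[base] + u[:, None] * (Xmin[neigh[base, pick]] - Xmin[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return X_out, y_out


def evaluate_roc(scores: np.ndarray, y: np.ndarray,
                 threshold: float | None = None) -> MetricSet:
    """ROC metrics for continuous scores against binary labels.

    The ROC is a threshold sweep with tied scores moving together; the AUC is
    its trapezoidal area, which equals the pairwise-concordance probability
    with ties counted 1/2.  ``threshold`` fixes the operating point for
    sensitivity/specificity/accuracy; if omitted, the Youden-optimal
    threshold *on these data* is used (callers doing out-of-sample evaluation
    should pass the training-derived threshold).
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to compute a ROC")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    if threshold is None:
        threshold = float(thr[np.argmax(tpr - fpr)])
    pred = (scores >= threshold).astype(int)
    pos, neg = y == 1, y == 0
    sens = float((pred[pos] == 1).mean())
    spec = float((pred[neg] == 0).mean())
    acc = float((pred == y).mean())
    return MetricSet(auc, sens, spec, acc, np.column_stack([fpr, tpr]),
                     float(threshold))


def fold_auc_ci(fold_aucs: Sequence[float], level: float = 0.95
                ) -> tuple[float, float]:
    """t-based confidence interval over per-fold AUCs, clipped to [0, 1]."""
    a = np.asarray(list(fold_aucs), float)
    if len(a) < 2:
        raise ValueError("need at least 2 folds for a confidence interval")
    mean = a.mean()
    sd = a.std(ddof=1)
    t = stats.t.ppf(0.5 + level / 2.0, df=len(a) - 1)
    half = t * sd / np.sqrt(len(a))
    return (float(np.clip(mean - half, 0, 1)), float(np.clip(mean + half, 0, 1)))


@dataclass
class FittedSVM:
    """RBF-SVM with its scaler and Platt-style probability map."""

    scaler: StandardScaler
    svc: SVC
    platt: LogisticRegression
    c: float
    gamma: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self.scaler.transform(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (case) class."""
        return self.platt.predict_proba(self.decision(X)[:, None])[:, 1]


def fit_rbf_svm(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec | None = None,
                inner: CVScheme | None = None, seed: int = 0) -> FittedSVM:
    """Grid-searched RBF-SVM with SMOTE applied inside inner training splits.

    ``(C, gamma)`` maximizes mean inner-fold AUC (margin scores; AUC is
    rank-invariant so the Platt map is deferred).  The final model is refit
    on the full — rebalanced — training partition; the sigmoid probability
    map is then fit on the *original* training samples so predicted
    probabilities reflect the true class prevalence.
    """
    spec = spec or ClassifierSpec()
    inner = inner or CVScheme()
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all feature columns are constant")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    gammas = spec.gammas(X.shape[1])
    n_inner = int(min(inner.inner_folds, np.bincount(y).min()))
    best = (-np.inf, None)
    if n_inner >= 2:
        skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
        splits = []
        for f, (tr, te) in enumerate(skf.split(Xs, y)):
            Xtr, ytr = Xs[tr], y[tr]
            if spec.rebalance == "smote":
                Xtr, ytr = smote_oversample(Xtr, ytr, spec.smote_k, seed + 101 * f)
            splits.append((Xtr, ytr, te))
        for c in spec.c_grid:
            for g in gammas:
                aucs = []
                for Xtr, ytr, te in splits:
                    if len(np.unique(y[te])) < 2:
                        continue
                    m = SVC(kernel="rbf", C=c, gamma=g, max_iter=100_000).fit(Xtr, ytr)
                    s = m.decision_function(Xs[te])
                    fpr, tpr, _ = roc_curve(y[te], s, drop_intermediate=False)
                    aucs.append(np.trapezoid(tpr, fpr))
                score = float(np.mean(aucs)) if aucs else -np.inf
                if score > best[0]:
                    best = (score, (float(c), float(g)))
    if best[1] is None:
        best = (0.0, (float(spec.c_grid[0]), float(gammas[0])))
    c, g = best[1]
    Xfit, yfit = Xs, y
    if spec.rebalance == "smote":
        Xfit, yfit = smote_oversample(Xs, y, spec.smote_k, seed + 7919)
    svc = SVC(kernel="rbf", C=c, gamma=g).fit(Xfit, yfit)
    margins = svc.decision_function(Xs)
    platt = LogisticRegression(C=1e6, max_iter=1000).fit(margins[:, None], y)
    return FittedSVM(scaler, svc, platt, c, g)


@dataclass
class NestedCVResult:
    """Outer-fold metrics, pooled metrics and supporting per-fold records."""

    fold_metrics: list
    pooled: MetricSet
    auc_ci: tuple
    fold_params: list
    fold_features: list
    mean_auc: float
    stability_report: pd.DataFrame | None = None
    pooled_scores: np.ndarray | None = None
    pooled_labels: np.ndarray | None = None
    pooled_sample_ids: np.ndarray | None = None

    @property
    def fold_aucs(self) -> list:
        return [m.auc for m in self.fold_metrics]

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "auc_ci": list(self.auc_ci),
            "pooled": self.pooled.as_dict(),
            "folds": [
                {"metrics": m.as_dict(), "params": list(p), "features": list(f)}
                for m, p, f in zip(self.fold_metrics, self.fold_params,
                                   self.fold_features)
            ],
        }


def _fold_panel(counts_tr: CountMatrix, meta_tr: SampleMeta,
                norm_tr: NormalizedMatrix, panel_size: int,
                selector_config: SelectorConfig, de_gate: DEGate,
                fallback_top: int, seed: int) -> tuple[list, pd.DataFrame]:
    """Candidate gate + stability consensus inside one training partition."""
    de = nb_wald(counts_tr, meta_tr)
    candidates = select_de(de, de_gate)
    need = max(panel_size, 2)
    if len(candidates) < need:
        ranked = de.sort_values(["padj", "p"]).loc[
            ~de.sort_values(["padj", "p"])["feature_id"].isin(candidates),
            "feature_id"]
        candidates = candidates + list(ranked.head(fallback_top - len(candidates)))
        logger.info("DE gate yielded <%d candidates; topped up by padj rank", need)
    X = norm_tr.subset_features(candidates).samples_by_features()
    report = stability_scores(X, meta_tr.y, candidates, selector_config, seed)
    panel = consensus_panel(report, de, panel_size)
    chosen = panel.feature_ids
    if len(chosen) < panel_size:
        pool = report.merge(de[["feature_id", "padj"]], on="feature_id")
        extra = pool[~pool["feature_id"].isin(chosen)].sort_values("padj")
        chosen = chosen + list(extra["feature_id"].head(panel_size - len(chosen)))
    return chosen, report


def run_nested(
    norm: NormalizedMatrix,
    meta: SampleMeta,
    counts: CountMatrix | None = None,
    panel: Sequence[str] | None = None,
    panel_size: int = 3,
    selector_config: SelectorConfig | None = None,
    spec: ClassifierSpec | None = None,
    scheme: CVScheme | None = None,
    de_gate: DEGate | None = None,
    fallback_top: int = 10,
) -> NestedCVResult:
    """Nested cross-validation of a biomarker panel.

    With ``panel`` fixed, selection is disabled and the given features are
    evaluated.  Otherwise ``counts`` must be supplied and each outer fold
    reruns the DE candidate gate and the stability/consensus selection on its
    own training partition before tuning the classifier.

    Returns one :class:`MetricSet` per outer fold, pooled metrics over the
    concatenated held-out scores, the t-based AUC CI, chosen hyperparameters
    and selected features per fold, and (in selection mode) the aggregated
    stability/consistency report.
    """
    spec = spec or ClassifierSpec()
    scheme = scheme or CVScheme()
    selector_config = selector_config or SelectorConfig()
    de_gate = de_gate or DEGate()
    meta = meta.aligned_to(norm.sample_ids)
    y = meta.y
    if panel is None and counts is None:
        raise ValueError("auto-selection requires the count matrix")
    if panel is not None:
        missing = set(panel) - set(norm.feature_ids)
        if missing:
            raise KeyError(f"panel features absent from matrix: {sorted(missing)[:5]}")

    skf = StratifiedKFold(n_splits=scheme.outer_folds, shuffle=True,
                          random_state=scheme.seed)
    fold_metrics, fold_params, fold_features, fold_reports = [], [], [], []
    pooled_scores, pooled_labels, pooled_ids = [], [], []
    X_all = norm.values.T  # samples x features
    for f, (tr, te) in enumerate(skf.split(X_all, y)):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError(f"outer fold {f} is missing a class; "
                             "reduce outer_folds or rebalance the cohort")
        meta_tr = meta.subset(tr)
        fold_seed = scheme.seed + 1009 * (f + 1)
        if panel is not None:
            chosen = list(panel)
        else:
            counts_tr = counts.subset_samples(norm.sample_ids[tr])
            norm_tr = norm.subset_samples(tr)
            chosen, report = _fold_panel(counts_tr, meta_tr, norm_tr, panel_size,
                                         selector_config, de_gate, fallback_top,
                                         fold_seed)
            fold_reports.append(report)
        cols = norm.feature_index(chosen)
        Xtr, Xte = X_all[np.ix_(tr, cols)], X_all[np.ix_(te, cols)]
        model = fit_rbf_svm(Xtr, y[tr], spec, scheme, fold_seed)
        p_tr = model.predict_proba(Xtr)
        thr = evaluate_roc(p_tr, y[tr]).threshold  # Youden on training
        p_te = model.predict_proba(Xte)
        fold_metrics.append(evaluate_roc(p_te, y[te], threshold=thr))
        fold_params.append((model.c, model.gamma))
        fold_features.append(chosen)
        pooled_scores.append(p_te)
        pooled_labels.append(y[te])
        pooled_ids.append(norm.sample_ids[te])

    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    pooled = evaluate_roc(scores, labels, threshold=0.5)
    aucs = [m.auc for m in fold_metrics]
    stab = None
    if fold_reports:
        stab = aggregate_reports(fold_reports, norm.feature_ids)
    return NestedCVResult(
        fold_metrics=fold_metrics, pooled=pooled, auc_ci=fold_auc_ci(aucs),
        fold_params=fold_params, fold_features=fold_features,
        mean_auc=float(np.mean(aucs)), stability_report=stab,
        pooled_scores=scores, pooled_labels=labels,
        pooled_sample_ids=np.concatenate(pooled_ids))


@dataclass
class PanelSweepResult:
    """Metrics per panel size k with the comprehensive-score argmax."""

    table: pd.DataFrame
    best_k: int
    results: dict


def comprehensive_score(m: MetricSet) -> float:
    """Unweighted mean of AUC, sensitivity and specificity."""
    return float(np.mean([m.auc, m.sensitivity, m.specificity]))


def sweep_panel_size(
    norm: NormalizedMatrix,
    meta: SampleMeta,
    ranked_features: Sequence[str],
    spec: ClassifierSpec | None = None,
    scheme: CVScheme | None = None,
    k_range: Sequence[int] = tuple(range(2, 11)),
) -> PanelSweepResult:
    """Evaluate nested-CV performance of the top-k panel for each k.

    ``ranked_features`` is the consensus ordering; for each ``k`` the fixed
    top-k panel is evaluated by :func:`run_nested` and summarized by the
    comprehensive score (mean of AUC, sensitivity, specificity over pooled
    predictions).  Ties in the argmax resolve to the smaller panel.
    """
    k_range = list(k_range)
    if max(k_range) > len(ranked_features):
        raise ValueError("k_range exceeds the number of ranked features")
    rows, results = [], {}
    for k in k_range:
        res = run_nested(norm, meta, panel=list(ranked_features[:k]),
                         spec=spec, scheme=scheme)
        m = res.pooled
        rows.append({"k": k, "auc": m.auc, "sensitivity": m.sensitivity,
                     "specificity": m.specificity, "accuracy": m.accuracy,
                     "comprehensive_score": comprehensive_score(m),
                     "mean_fold_auc": res.mean_auc})
        results[k] = res
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["comprehensive_score"].idxmax(), "k"])
    return PanelSweepResult(table=table, best_k=best_k, results=results)
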