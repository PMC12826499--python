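"""External-cohort validation and local gene-set enrichment.

Reduced biomarker panels are re-evaluated on independent cohorts with linear
classifiers (linear SVM, logistic regression, LDA) under stratified
cross-validation — deliberately simple models for small validation cohorts.
Cross-cancer specificity re-scores the fixed panel on each cohort, either
retrained per cohort or transferred from a reference cohort.  Enrichment is
an upper-tail hypergeometric test of a query feature set against
user-supplied gene-set collections (GMT), BH-corrected across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .data import NormalizedMatrix, SampleMeta
from .diffexpr import bh_adjust
from .nested import fold_auc_ci, evaluate_roc

logger = logging.getLogger(__name__)

LINEAR_MODELS = ("linear-svm", "logistic", "lda")


@dataclass
class ValidationResult:
    model: str
    auc: float
    auc_ci: tuple
    sensitivity: float
    specificity: float
    panel: list
    n_case: int
    n_control: int

    def to_dict(self) -> dict:
        return {"model": self.model, "auc": self.auc, "auc_ci": list(self.auc_ci),
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "panel": list(self.panel), "n_case": self.n_case,
                "n_control": self.n_control}


def _make_model(name: str, seed: int):
    if name == "linear-svm":
        est = LinearSVC(C=1.0, random_state=seed)
    elif name == "logistic":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    elif name == "lda":
        est = LinearDiscriminantAnalysis()
    else:
        raise ValueError(f"unknown model {name!r}; choose from {LINEAR_MODELS}")
    return make_pipeline(StandardScaler(), est)


def _scores(model, X):
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def external_validate(
    norm: NormalizedMatrix,
    meta: SampleMeta,
    panel: Sequence[str],
    models: Sequence[str] = LINEAR_MODELS,
    n_folds: int = 5,
    seed: int = 0,
) -> list[ValidationResult]:
    """Stratified-CV performance of linear models on a (possibly reduced) panel.

    Panel members absent from the validation matrix are dropped with a
    warning — mirroring the common situation where an external platform
    quantifies only part of the panel.  Fold counts are capped so every fold
    holds at least one sample of each class; the AUC CI is the fold-based
    t interval.
    """
    meta = meta.aligned_to(norm.sample_ids)
    meta.require_both_groups()
    present = [f for f in panel if f in set(norm.feature_ids)]
    missing = [f for f in panel if f not in set(norm.feature_ids)]
    if missing:
        logger.warning("panel members absent from validation data: %s", missing)
    if not present:
        raise ValueError("no panel feature present in the validation matrix")
    X = norm.subset_features(present).samples_by_features()
    y = meta.y
    n_folds = int(min(n_folds, np.bincount(y).min()))
    if n_folds < 2:
        raise ValueError("too few samples in the minority class for CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    results = []
    for name in models:
        fold_aucs, scores, labels = [], [], []
        for tr, te in splits:
            m = _make_model(name, seed).fit(X[tr], y[tr])
            s = _scores(m, X[te])
            scores.append(s)
            labels.append(y[te])
            if len(np.unique(y[te])) == 2:
                fold_aucs.append(evaluate_roc(s, y[te]).auc)
        pooled = evaluate_roc(np.concatenate(scores), np.concatenate(labels))
        ci = fold_auc_ci(fold_aucs) if len(fold_aucs) >= 2 else (0.0, 1.0)
        results.append(ValidationResult(
            model=name, auc=pooled.auc, auc_ci=ci,
            sensitivity=pooled.sensitivity, specificity=pooled.specificity,
            panel=list(present), n_case=int(y.sum()),
            n_control=int((1 - y).sum())))
    return results


def specificity_panel(
    cohorts: Mapping[str, tuple[NormalizedMatrix, SampleMeta]],
    panel: Sequence[str],
    mode: str = "retrain",
    reference: str | None = None,
    model: str = "linear-svm",
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC of the fixed biomarker panel on each cohort.

    ``retrain`` (default) fits/scores per cohort under the same stratified-CV
    scheme as :func:`external_validate`; ``transfer`` trains once on the
    ``reference`` cohort and applies the frozen model to every other cohort.
    Returns one row per cohort.
    """
    if mode not in ("retrain", "transfer"):
        raise ValueError("mode must be 'retrain' or 'transfer'")
    rows = []
    frozen = None
    if mode == "transfer":
        if reference is None or reference not in cohorts:
            raise ValueError("transfer mode requires a reference cohort name")
        norm_r, meta_r = cohorts[reference]
        meta_r = meta_r.aligned_to(norm_r.sample_ids)
        Xr = norm_r.subset_features(list(panel)).samples_by_features()
        frozen = _make_model(model, seed).fit(Xr, meta_r.y)
    for name, (norm, meta) in cohorts.items():
        meta = meta.aligned_to(norm.sample_ids)
        meta.require_both_groups()
        missing = set(panel) - set(norm.feature_ids)
        if missing:
            raise KeyError(f"cohort {name!r} lacks panel features "
                           f"{sorted(missing)}")
        if mode == "transfer" and name != reference:
            X = norm.subset_features(list(panel)).samples_by_features()
            auc = evaluate_roc(_scores(frozen, X), meta.y).auc
        else:
            res = external_validate(norm, meta, panel, models=(model,),
                                    n_folds=n_folds, seed=seed)[0]
            auc = res.auc
        rows.append({"cohort": name, "auc": auc,
                     "n_case": int(meta.y.sum()),
                     "n_control": int((1 - meta.y).sum())})
    return pd.DataFrame(rows)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a feature universe."""

    sets: dict  # set_id -> (description, tuple of member ids)
    universe: frozenset

    @classmethod
    def from_gmt(cls, path, universe: Sequence[str]) -> "GeneSetCollection":
        universe = frozenset(universe)
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                set_id, desc, members = parts[0], parts[1], parts[2:]
                kept = tuple(m for m in members if m in universe)
                if kept:
                    sets[set_id] = (desc, kept)
        return cls(sets=sets, universe=universe)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Sequence[str]],
                  universe: Sequence[str]) -> "GeneSetCollection":
        universe = frozenset(universe)
        sets = {}
        for set_id, members in mapping.items():
            kept = tuple(m for m in members if m in universe)
            if kept:
                sets[set_id] = ("", kept)
        return cls(sets=sets, universe=universe)


def enrich_hypergeom(query: Sequence[str], collection: GeneSetCollection
                     ) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` against every set.

    With universe size N, set size K, query size n and overlap x, the p-value
    is ``P(X >= x)`` for X ~ Hypergeometric(N, K, n); BH correction is
    applied across sets.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    outside = query - collection.universe
    if outside:
        raise ValueError(f"query features outside universe: {sorted(outside)[:5]}")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for set_id, (desc, members) in collection.sets.items():
        K = len(members)
        x = len(query & set(members))
        p = float(stats.hypergeom.sf(x - 1, N, K, n))  # P(X >= x)
        rows.append({"set_id": set_id, "description": desc, "overlap": x,
                     "set_size": K, "query_size": n, "universe_size": N,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)
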