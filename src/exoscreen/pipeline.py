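"""End-to-end biomarker screen as a fitted-model object.

:class:`BiomarkerScreen` is the package's top-level surface, in the style of
a statsmodels model: construct it from the three data tables (or from TSV
paths), call :meth:`~BiomarkerScreen.fit`, and receive a
:class:`ScreenResults` carrying the differential-expression table, the
stability/consistency report, the consensus biomarker panel, nested
cross-validation metrics with their t-based confidence interval, and the
calibration report, with a :meth:`~ScreenResults.summary` table.

:func:`run_pipeline` wraps the model for the command line: it persists every
stage artifact to an output directory and emits a checksummed
:class:`RunManifest`, so identical config + seed reproduce identical
checksums for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationReport, assess_calibration
from .config import RunConfig
from .data import CountMatrix, FeatureMeta, SampleMeta, check_aligned
from .diffexpr import DEGate, nb_wald, select_de
from .io import (read_features, read_matrix, read_meta, write_frame,
                 write_json, write_matrix, write_meta, write_features)
from .nested import ClassifierSpec, CVScheme, NestedCVResult, run_nested
from .preprocess import FilterParams, filter_features, harmonize_strata, normalize_cpm
from .simulate import simulate_cohort
from .stability import ConsensusPanel, SelectorConfig, consensus_panel


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ScreenResults:
    """Everything the screen estimated, with a printable summary."""

    config: RunConfig
    n_input_features: int
    n_retained_features: int
    de_table: pd.DataFrame
    candidates: list
    stability_report: pd.DataFrame
    panel: ConsensusPanel
    selection_cv: NestedCVResult
    panel_cv: NestedCVResult | None
    calibration: CalibrationReport | None

    @property
    def panel_features(self) -> list:
        return list(self.panel.feature_ids)

    def summary(self) -> str:
        cv = self.panel_cv or self.selection_cv
        lines = [
            "Exosome-RNA biomarker screen",
            "=" * 60,
            f"features: {self.n_input_features} input, "
            f"{self.n_retained_features} retained after filtering",
            f"candidates passing DE gate: {len(self.candidates)}",
            f"consensus panel (size {len(self.panel_features)}): "
            + ", ".join(self.panel_features),
        ]
        rep = self.stability_report.set_index("feature_id")
        for f in self.panel_features:
            row = rep.loc[f]
            stab = ", ".join(f"{c.split('_', 1)[1]}={row[c]:.2f}"
                             for c in rep.columns if c.startswith("stab_"))
            lines.append(f"  {f}: consistency {int(row['consistency_num'])}/"
                         f"{int(row['consistency_den'])} ({stab})")
        lo, hi = cv.auc_ci
        lines += [
            f"nested CV ({len(cv.fold_metrics)} outer folds): "
            f"AUC {cv.mean_auc:.3f} (95% CI {lo:.3f}-{hi:.3f})",
            f"pooled: sensitivity {cv.pooled.sensitivity:.3f}, "
            f"specificity {cv.pooled.specificity:.3f}, "
            f"accuracy {cv.pooled.accuracy:.3f}",
        ]
        if self.calibration is not None:
            c = self.calibration
            lines.append(
                f"calibration: slope {c.slope:.3f}, Brier {c.brier:.3f}, "
                f"Hosmer-Lemeshow p {c.hl_p:.3f} (df {c.hl_df})")
        return "\n".join(lines)


class BiomarkerScreen:
    """Machine-learning biomarker screen for a case/control expression cohort.

    Parameters
    ----------
    counts
        Raw feature-by-sample count matrix.
    meta
        Sample metadata (case/control labels, cohorts), aligned on construction.
    features
        Feature metadata (RNA types), aligned on construction.
    config
        Flat parameter record; see :class:`~exoscreen.config.RunConfig`.
    """

    def __init__(self, counts: CountMatrix, meta: SampleMeta,
                 features: FeatureMeta, config: RunConfig | None = None):
        self.counts = counts
        self.meta = meta.aligned_to(counts.sample_ids)
        self.features = features.aligned_to(counts.feature_ids)
        self.config = config or RunConfig(seed=0)
        check_aligned(counts, self.meta, self.features)
        self.meta.require_both_groups()

    @classmethod
    def from_tsv(cls, counts_path, meta_path, features_path,
                 config: RunConfig | None = None) -> "BiomarkerScreen":
        return cls(read_matrix(counts_path), read_meta(meta_path),
                   read_features(features_path), config)

    # -- assembled stage parameter objects ---------------------------------
    def _filter_params(self) -> FilterParams:
        c = self.config
        return FilterParams(c.min_nonzero_frac, c.min_count, c.min_count_frac)

    def _de_gate(self) -> DEGate:
        c = self.config
        return DEGate(c.de_alpha, c.de_min_lfc, c.de_min_mean)

    def _selector_config(self) -> SelectorConfig:
        c = self.config
        return SelectorConfig(n_iterations=c.n_iterations,
                              subsample_frac=c.subsample_frac, top_k=c.top_k,
                              rf_trees=c.rf_trees,
                              consensus_threshold=c.consensus_threshold)

    def _scheme(self) -> CVScheme:
        c = self.config
        return CVScheme(c.outer_folds, c.inner_folds, True, int(c.seed))

    def _spec(self) -> ClassifierSpec:
        c = self.config
        return ClassifierSpec(rebalance=c.rebalance, smote_k=c.smote_k)

    def fit(self, evaluate_panel: bool = True) -> ScreenResults:
        """Run the full screen.

        Stages: prevalence/abundance filtering -> log2(CPM+1) normalization
        -> RNA-type harmonization -> cohort-level NB-Wald DE (reported; the
        candidate gate is *re-estimated inside each outer fold*) -> nested CV
        with per-fold stability/consensus selection -> cohort-level consensus
        panel -> optionally, nested CV of the fixed final panel plus
        calibration of its pooled held-out probabilities.
        """
        cfg = self.config
        filtered = filter_features(self.counts, self._filter_params())
        feats = self.features.aligned_to(filtered.feature_ids)
        norm = harmonize_strata(normalize_cpm(filtered, cfg.norm_method), feats)

        de = nb_wald(filtered, self.meta)
        candidates = select_de(de, self._de_gate())

        sel_cv = run_nested(
            norm, self.meta, counts=filtered, panel=None,
            panel_size=cfg.panel_size, selector_config=self._selector_config(),
            spec=self._spec(), scheme=self._scheme(), de_gate=self._de_gate())
        panel = consensus_panel(sel_cv.stability_report, de, cfg.panel_size)

        panel_cv = None
        calib = None
        if evaluate_panel and panel.feature_ids:
            panel_cv = run_nested(norm, self.meta, panel=panel.feature_ids,
                                  spec=self._spec(), scheme=self._scheme())
            calib = assess_calibration(panel_cv.pooled_scores,
                                       panel_cv.pooled_labels,
                                       bins=cfg.calibration_bins)
        return ScreenResults(
            config=cfg, n_input_features=self.counts.n_features,
            n_retained_features=filtered.n_features, de_table=de,
            candidates=candidates, stability_report=sel_cv.stability_report,
            panel=panel, selection_cv=sel_cv, panel_cv=panel_cv,
            calibration=calib)


@dataclass
class RunManifest:
    version: str
    config: dict
    checksums: dict
    timestamps: dict

    def to_dict(self) -> dict:
        return {"version": self.version, "config": self.config,
                "checksums": self.checksums, "timestamps": self.timestamps}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir, counts: CountMatrix | None = None,
                 meta: SampleMeta | None = None,
                 features: FeatureMeta | None = None) -> RunManifest:
    """Execute the full screen and persist every stage artifact.

    With no input data, a synthetic cohort is generated from the config's
    simulation block (and its ground truth persisted).  Any stage failure
    raises :class:`StageError` naming the stage; artifacts written before
    the failure remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict = {}
    timestamps: dict = {}

    def persist(stage: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        checksums[name] = _sha256(path)
        timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    stage = "simulate"
    try:
        if counts is None:
            counts, meta, features, truth = simulate_cohort(
                n_case=config.n_case, n_control=config.n_control,
                n_features=config.n_features, n_planted=config.n_planted,
                seed=int(config.seed))
            persist(stage, "counts.tsv", lambda p: write_matrix(counts, p))
            persist(stage, "samples.tsv", lambda p: write_meta(meta, p))
            persist(stage, "features.tsv", lambda p: write_features(features, p))
            persist(stage, "sim_truth.json",
                    lambda p: p.write_text(truth.to_json()))
        model = BiomarkerScreen(counts, meta, features, config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "screen"
    try:
        results = model.fit(evaluate_panel=True)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "persist"
    try:
        persist("de", "de_table.tsv",
                lambda p: write_frame(results.de_table, p))
        persist("stability", "stability_report.tsv",
                lambda p: write_frame(results.stability_report, p))
        persist("panel", "panel.json", lambda p: write_json(
            {"features": results.panel_features,
             "table": results.panel.table.to_dict(orient="records")}, p))
        persist("evaluate", "selection_cv.json",
                lambda p: write_json(results.selection_cv.to_dict(), p))
        if results.panel_cv is not None:
            persist("evaluate", "panel_cv.json",
                    lambda p: write_json(results.panel_cv.to_dict(), p))
            roc = pd.DataFrame(results.panel_cv.pooled.roc_points,
                               columns=["fpr", "tpr"])
            persist("evaluate", "roc_points.tsv", lambda p: write_frame(roc, p))
        if results.calibration is not None:
            persist("calibrate", "calibration.json",
                    lambda p: write_json(results.calibration.to_dict(), p))
        persist("summary", "summary.txt",
                lambda p: p.write_text(results.summary() + "\n"))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = RunManifest(version=__version__, config=config.to_dict(),
                           checksums=checksums, timestamps=timestamps)
    write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
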