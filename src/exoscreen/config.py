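"""Flat run configuration shared by the CLI and the end-to-end pipeline.

A run is fully determined by this record: every stochastic stage takes an
explicit seed derived from ``seed``, so a frozen config file is a complete,
auditable description of the 20-iteration / 10-fold protocol actually
executed.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml


@dataclass
class RunConfig:
    # simulation (used by the `simulate` and `run --simulate` paths)
    n_case: int = 111
    n_control: int = 362
    n_features: int = 2000
    n_planted: int = 3

    # preprocessing
    min_nonzero_frac: float = 0.80
    min_count: float = 5.0
    min_count_frac: float = 0.10
    norm_method: str = "total-count"

    # differential expression gate
    de_alpha: float = 0.05
    de_min_lfc: float = 1.2
    de_min_mean: float = 50.0

    # stability selection
    n_iterations: int = 20
    subsample_frac: float = 0.8
    top_k: int = 20
    rf_trees: int = 500
    consensus_threshold: float = 0.5

    # nested evaluation
    outer_folds: int = 10
    inner_folds: int = 5
    panel_size: int = 3
    smote_k: int = 5
    rebalance: str = "smote"

    # calibration
    calibration_bins: int = 10

    # bookkeeping
    seed: int | None = None
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a run config must carry an explicit seed")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError("config file must contain a flat mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
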