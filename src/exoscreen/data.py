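"""Core in-memory containers for exosome-RNA expression cohorts.

The pipeline moves three aligned objects through every stage: a
feature-by-sample count matrix, per-sample metadata (case/control label and
cohort of origin) and per-feature metadata (RNA type, which defines the
technical stratum used for batch harmonization).  All three are thin
dataclasses over numpy arrays with strict identity validation, plus
``pandas`` conversion helpers for I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
GROUPS = (CASE, CONTROL)
RNA_TYPES = ("mRNA", "lncRNA", "circRNA")


class DataValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


def _as_str_array(values: Iterable, name: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=object)
    if arr.ndim != 1:
        raise DataValidationError(f"{name} must be one-dimensional")
    return arr


def _check_unique(ids: np.ndarray, name: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise DataValidationError(f"duplicated {name}: {sorted(set(dups))[:5]}")


@dataclass
class CountMatrix:
    """Non-negative feature-by-sample expression counts.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique string identifiers for rows and columns.
    counts
        ``(n_features, n_samples)`` array of non-negative values.  Raw input
        is expected to be integer-valued counts, but fractional values are
        accepted (some public exosome resources distribute normalized counts).
    """

    feature_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = _as_str_array(self.feature_ids, "feature_ids")
        self.sample_ids = _as_str_array(self.sample_ids, "sample_ids")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise DataValidationError("counts must be a 2-D array")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.feature_ids) < 1 or len(self.sample_ids) < 2:
            raise DataValidationError("need at least 1 feature and 2 samples")
        _check_unique(self.feature_ids, "feature_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if not np.all(np.isfinite(self.counts)):
            bad = np.argwhere(~np.isfinite(self.counts))[0]
            raise DataValidationError(
                f"non-finite count at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise DataValidationError(
                f"negative count at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in lookup]
        if missing:
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        return np.array([lookup[f] for f in ids], dtype=int)

    def subset_features(self, mask_or_ids) -> "CountMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            idx = self.feature_index(list(mask_or_ids))
        return CountMatrix(self.feature_ids[idx], self.sample_ids, self.counts[idx])

    def subset_samples(self, mask_or_ids) -> "CountMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([lookup[s] for s in mask_or_ids], dtype=int)
        return CountMatrix(self.feature_ids, self.sample_ids[idx], self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=list(self.sample_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(frame.index.to_numpy(dtype=object),
                   np.asarray(frame.columns, dtype=object),
                   frame.to_numpy(dtype=float))


@dataclass
class SampleMeta:
    """Per-sample group label (case/control) and cohort of origin."""

    sample_id: np.ndarray
    group: np.ndarray
    cohort: np.ndarray

    def __post_init__(self) -> None:
        self.sample_id = _as_str_array(self.sample_id, "sample_id")
        self.group = _as_str_array(self.group, "group")
        self.cohort = _as_str_array(self.cohort, "cohort")
        if not (len(self.sample_id) == len(self.group) == len(self.cohort)):
            raise DataValidationError("sample metadata columns differ in length")
        _check_unique(self.sample_id, "sample_id")
        bad = sorted(set(self.group) - set(GROUPS))
        if bad:
            raise DataValidationError(f"unknown group labels {bad}; expected {GROUPS}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    @property
    def y(self) -> np.ndarray:
        """Binary outcome vector: 1 = case, 0 = control."""
        return (self.group == CASE).astype(int)

    def require_both_groups(self) -> None:
        if len(set(self.group)) < 2:
            raise DataValidationError("both case and control samples are required")

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleMeta":
        """Reorder to ``sample_ids``; error if the sets differ."""
        lookup = {s: i for i, s in enumerate(self.sample_id)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise DataValidationError(f"metadata missing samples: {missing[:5]}")
        extra = set(self.sample_id) - set(sample_ids)
        if extra:
            raise DataValidationError(f"metadata has unknown samples: {sorted(extra)[:5]}")
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return SampleMeta(self.sample_id[idx], self.group[idx], self.cohort[idx])

    def subset(self, idx: np.ndarray) -> "SampleMeta":
        return SampleMeta(self.sample_id[idx], self.group[idx], self.cohort[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "group": self.group, "cohort": self.cohort}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleMeta":
        return cls(frame["sample_id"].to_numpy(dtype=object),
                   frame["group"].to_numpy(dtype=object),
                   frame["cohort"].to_numpy(dtype=object))


@dataclass
class FeatureMeta:
    """Per-feature RNA type; the RNA type defines the technical stratum."""

    feature_id: np.ndarray
    rna_type: np.ndarray

    def __post_init__(self) -> None:
        self.feature_id = _as_str_array(self.feature_id, "feature_id")
        self.rna_type = _as_str_array(self.rna_type, "rna_type")
        if len(self.feature_id) != len(self.rna_type):
            raise DataValidationError("feature metadata columns differ in length")
        _check_unique(self.feature_id, "feature_id")

    def aligned_to(self, feature_ids: Sequence[str]) -> "FeatureMeta":
        lookup = {f: i for i, f in enumerate(self.feature_id)}
        missing = [f for f in feature_ids if f not in lookup]
        if missing:
            raise DataValidationError(f"feature metadata missing: {missing[:5]}")
        idx = np.array([lookup[f] for f in feature_ids], dtype=int)
        return FeatureMeta(self.feature_id[idx], self.rna_type[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.feature_id, "rna_type": self.rna_type})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMeta":
        return cls(frame["feature_id"].to_numpy(dtype=object),
                   frame["rna_type"].to_numpy(dtype=object))


@dataclass
class NormalizedMatrix:
    """log2(CPM + 1) expression values with the library sizes used."""

    feature_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    effective_library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.feature_ids = _as_str_array(self.feature_ids, "feature_ids")
        self.sample_ids = _as_str_array(self.sample_ids, "sample_ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataValidationError("values shape does not match identifiers")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("non-finite normalized values")
        if self.effective_library_sizes is None:
            self.effective_library_sizes = np.ones(len(self.sample_ids))
        self.effective_library_sizes = np.asarray(self.effective_library_sizes, float)
        if np.any(self.effective_library_sizes <= 0):
            raise DataValidationError("library sizes must be positive")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_by_features(self) -> np.ndarray:
        """Values in the sample-by-feature orientation used by classifiers."""
        return self.values.T.copy()

    def feature_index(self, ids: Sequence[str]) -> np.ndarray:
        return CountMatrix.feature_index(self, ids)  # same id layout

    def subset_features(self, ids: Sequence[str]) -> "NormalizedMatrix":
        idx = self.feature_index(list(ids))
        return NormalizedMatrix(self.feature_ids[idx], self.sample_ids,
                                self.values[idx], self.effective_library_sizes)

    def subset_samples(self, idx: np.ndarray) -> "NormalizedMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(self.feature_ids, self.sample_ids[idx],
                                self.values[:, idx],
                                self.effective_library_sizes[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.feature_ids, name="feature_id"),
                            columns=list(self.sample_ids))


def check_aligned(counts: CountMatrix, meta: SampleMeta | None = None,
                  features: FeatureMeta | None = None) -> None:
    """Cross-validate identifier agreement between containers."""
    if meta is not None and (
        len(meta.sample_id) != counts.n_samples
        or not np.array_equal(meta.sample_id, counts.sample_ids)
    ):
        raise DataValidationError(
            "sample metadata does not align with the count matrix; "
            "use SampleMeta.aligned_to(counts.sample_ids)"
        )
    if features is not None and (
        len(features.feature_id) != counts.n_features
        or not np.array_equal(features.feature_id, counts.feature_ids)
    ):
        raise DataValidationError(
            "feature metadata does not align with the count matrix; "
            "use FeatureMeta.aligned_to(counts.feature_ids)"
        )
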