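"""Readers and writers for the pipeline's plain-text formats.

Matrix dialect: TSV, first column ``feature_id``, one column per sample with
a header row of sample ids.  Sample metadata: ``sample_id, group, cohort``.
Feature metadata: ``feature_id, rna_type``.  Ground truth and result objects
are JSON.  All writers are atomic (write to a temp file in the destination
directory, then rename), and readers are gzip-transparent (pandas infers
compression from the ``.gz`` suffix).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountMatrix, DataValidationError, FeatureMeta, NormalizedMatrix, SampleMeta


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_frame(frame: pd.DataFrame, path, index: bool = False) -> None:
    atomic_write_text(path, frame.to_csv(sep="\t", index=index))


def write_matrix(counts: CountMatrix | NormalizedMatrix, path) -> None:
    write_frame(counts.to_frame(), path, index=True)


def read_matrix(path) -> CountMatrix:
    """Read the TSV matrix dialect into a validated :class:`CountMatrix`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index.name = "feature_id"
    non_numeric = [c for c in frame.columns
                   if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise DataValidationError(
            f"non-numeric cells in sample column(s) {non_numeric[:5]} of {path}")
    return CountMatrix.from_frame(frame)


def read_normalized(path) -> NormalizedMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return NormalizedMatrix(frame.index.to_numpy(dtype=object),
                            np.asarray(frame.columns, dtype=object),
                            frame.to_numpy(dtype=float))


def read_meta(path) -> SampleMeta:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "cohort"}
    missing = required - set(frame.columns)
    if missing:
        raise DataValidationError(f"sample metadata missing columns {sorted(missing)}")
    return SampleMeta.from_frame(frame)


def read_features(path) -> FeatureMeta:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"feature_id", "rna_type"} - set(frame.columns)
    if missing:
        raise DataValidationError(f"feature metadata missing columns {sorted(missing)}")
    return FeatureMeta.from_frame(frame)


def write_meta(meta: SampleMeta, path) -> None:
    write_frame(meta.to_frame(), path)


def write_features(features: FeatureMeta, path) -> None:
    write_frame(features.to_frame(), path)


def write_json(obj, path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=1, default=_json_default))


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")
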