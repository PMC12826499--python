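"""Quality filtering, log2(CPM+1) normalization and stratum harmonization.

The preprocessing contract mirrors common practice for public exosome-RNA
count matrices:

1. keep features that are non-zero in at least 80% of samples *and* reach
   counts >= 5 in at least 10% of samples;
2. normalize to log2(CPM + 1), with library sizes taken either as plain
   column totals or rescaled by trimmed-mean-of-M-values (TMM) factors;
3. remove the systematic offset between RNA-type strata (mRNA/lncRNA vs
   circRNA) with an empirical-Bayes location/scale adjustment.

Filtering precedes normalization, so library sizes are computed on the
filtered matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import CountMatrix, FeatureMeta, NormalizedMatrix, check_aligned

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Dual prevalence/abundance filter thresholds."""

    min_nonzero_frac: float = 0.80
    min_count: float = 5.0
    min_count_frac: float = 0.10

    def __post_init__(self) -> None:
        for frac in (self.min_nonzero_frac, self.min_count_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("filter fractions must lie in [0, 1]")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")


def filter_features(counts: CountMatrix, params: FilterParams | None = None) -> CountMatrix:
    """Retain features passing both the prevalence and abundance conditions.

    A feature is kept iff it is non-zero in at least ``min_nonzero_frac`` of
    samples and has counts >= ``min_count`` in at least ``min_count_frac`` of
    samples.  Feature order and the sample set are preserved.
    """
    params = params or FilterParams()
    n = counts.n_samples
    nonzero_frac = (counts.counts > 0).sum(axis=1) / n
    reliable_frac = (counts.counts >= params.min_count).sum(axis=1) / n
    keep = (nonzero_frac >= params.min_nonzero_frac) & \
           (reliable_frac >= params.min_count_frac)
    if not keep.any():
        logger.warning("filter_features removed every feature")
    return counts.subset_features(keep)


def _tmm_factors(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05
                 ) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors against a reference column.

    The reference is the column whose upper-quartile expression is closest to
    the mean upper quartile.  Zero-count features (in either column) are
    excluded before the doubly trimmed mean of M-values.
    """
    totals = counts.sum(axis=0)
    props = counts / totals
    uq = np.quantile(props, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        ok = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if ok.sum() < 10:
            continue
        pj, pr = props[ok, j], props[ok, ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.any():
            factors[j] = 2.0 ** np.mean(m[keep])
    # center factors so they multiply to 1 (edgeR convention)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def normalize_cpm(counts: CountMatrix, method: str = "total-count") -> NormalizedMatrix:
    """log2(CPM + 1) transform.

    ``value = log2(count / effective_library_size * 1e6 + 1)`` where the
    effective library size is the column total (``total-count``) or the column
    total times a TMM factor (``trimmed-mean``).
    """
    if method not in ("total-count", "trimmed-mean"):
        raise ValueError(f"unknown normalization method {method!r}")
    totals = counts.counts.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total count: {list(counts.sample_ids[zero[:5]])}")
    lib = totals.copy()
    if method == "trimmed-mean":
        lib = totals * _tmm_factors(counts.counts)
    values = np.log2(counts.counts / lib[None, :] * 1e6 + 1.0)
    return NormalizedMatrix(counts.feature_ids.copy(), counts.sample_ids.copy(),
                            values, lib)


def harmonize_strata(norm: NormalizedMatrix, features: FeatureMeta,
                     shrink_strength: float = 2.0) -> NormalizedMatrix:
    """Remove systematic location/scale offsets between RNA-type strata.

    The adjustment acts on the distribution of per-feature mean expression
    within each stratum: feature means are standardized against stratum-level
    location/scale estimates — shrunk toward the cross-stratum values by an
    empirical-Bayes step with weight ``n_s / (n_s + shrink_strength)`` — and
    re-expressed against the grand location and the pooled within-stratum
    scale.  Each feature's values are shifted by a single constant, so
    within-feature (case vs control) structure is untouched, output
    dimensions and identifiers are unchanged, and reapplying the adjustment
    is a near no-op.  Strata with fewer than 2 features pass through
    unadjusted, with a warning.
    """
    if len(features.feature_id) != norm.n_features or \
            not np.array_equal(features.feature_id, norm.feature_ids):
        features = features.aligned_to(norm.feature_ids)
    values = norm.values
    m = values.mean(axis=1)  # per-feature mean expression
    grand_loc = m.mean()
    strata = np.unique(features.rna_type)
    blocks = {}
    var_num, var_den = 0.0, 0.0
    for stratum in strata:
        mask = features.rna_type == stratum
        n_s = int(mask.sum())
        if n_s < 2:
            logger.warning("stratum %r has <2 features; passed through", stratum)
            continue
        blocks[stratum] = (mask, n_s, m[mask].mean(), m[mask].std(ddof=1))
        var_num += (n_s - 1) * m[mask].var(ddof=1)
        var_den += n_s - 1
    if not blocks:
        return NormalizedMatrix(norm.feature_ids.copy(), norm.sample_ids.copy(),
                                values.copy(), norm.effective_library_sizes.copy())
    pooled_scale = np.sqrt(var_num / var_den) if var_den > 0 else 1.0
    if pooled_scale == 0:
        pooled_scale = 1.0
    out = values.copy()
    for stratum, (mask, n_s, loc_s, scale_s) in blocks.items():
        w = n_s / (n_s + shrink_strength)
        loc = w * loc_s + (1 - w) * grand_loc
        scale = (scale_s ** w) * (pooled_scale ** (1 - w)) if scale_s > 0 else pooled_scale
        target = (m[mask] - loc) / scale * pooled_scale + grand_loc
        out[mask] += (target - m[mask])[:, None]
    return NormalizedMatrix(norm.feature_ids.copy(), norm.sample_ids.copy(),
                            out, norm.effective_library_sizes.copy())
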