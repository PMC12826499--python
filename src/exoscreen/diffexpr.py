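"""Negative-binomial Wald differential expression with a triple screening gate.

Per feature, counts are modelled as NB(mu_ij, alpha_i) with

    log mu_ij = beta0_i + beta1_i * case_j + log s_j

where ``s_j`` is the median-of-ratios size factor of sample *j* and
``alpha_i`` a per-feature dispersion estimated by method-of-moments (floored
at 1e-8, so the Poisson model is the alpha -> 0 limit).  ``beta1`` is
estimated by Fisher scoring, its Wald statistic ``beta1 / se(beta1)`` is
referred to the standard normal, p-values are Benjamini-Hochberg adjusted,
and candidate biomarkers are the features passing all three gates:
adjusted p < 0.05, |log2FC| > 1.2 and mean normalized expression > 50.

Everything is vectorised across features; a 2,000-feature, ~500-sample
cohort fits in well under a second, which is what makes recomputing the
candidate gate inside every outer cross-validation fold affordable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CountMatrix, SampleMeta, check_aligned

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 50.0


@dataclass
class DEGate:
    """Screening thresholds for candidate differentially expressed features."""

    alpha: float = 0.05
    min_abs_log2fc: float = 1.2
    min_base_mean: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_abs_log2fc < 0 or self.min_base_mean < 0:
            raise ValueError("gate thresholds must be >= 0")


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over reference features of
    ``count / geometric-mean-across-samples``.  Reference features are those
    with all-positive counts; if none exist, the median is taken per sample
    over that sample's positive-count features (with a warning).
    """
    k = counts.counts
    with np.errstate(divide="ignore"):
        log_k = np.where(k > 0, np.log(k), -np.inf)
    all_pos = np.all(k > 0, axis=1)
    factors = np.empty(counts.n_samples)
    if all_pos.any():
        log_gm = log_k[all_pos].mean(axis=1)
        ratios = np.exp(log_k[all_pos] - log_gm[:, None])
        factors = np.median(ratios, axis=0)
    else:
        logger.warning("no all-positive feature; size factors use "
                       "positive-count features only per sample")
        pos_any = k > 0
        log_gm = np.array([
            log_k[i, pos_any[i]].mean() if pos_any[i].any() else 0.0
            for i in range(counts.n_features)])
        for j in range(counts.n_samples):
            ok = pos_any[:, j]
            if not ok.any():
                raise ValueError(
                    f"sample {counts.sample_ids[j]!r} has no positive counts")
            factors[j] = np.median(np.exp(log_k[ok, j] - log_gm[ok]))
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor computed")
    return factors


def estimate_dispersions(k: np.ndarray, y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Per-feature method-of-moments NB dispersion.

    Works on size-factor-normalized counts ``k/s`` within each group (so the
    case/control mean shift does not inflate the estimate):
    ``Var(k/s) = mu * mean(1/s) + alpha * mu^2`` is solved for alpha per
    group and combined by a df-weighted average, floored at 1e-8.
    """
    norm = k / s[None, :]
    num = np.zeros(k.shape[0])
    den = 0.0
    for g in (0, 1):
        mask = y == g
        n_g = int(mask.sum())
        if n_g < 2:
            continue
        mu = norm[:, mask].mean(axis=1)
        var = norm[:, mask].var(axis=1, ddof=1)
        inv_s = float(np.mean(1.0 / s[mask]))
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_g = (var - mu * inv_s) / mu**2
        alpha_g = np.where(np.isfinite(alpha_g), alpha_g, 0.0)
        num += (n_g - 1) * alpha_g
        den += n_g - 1
    alpha = num / max(den, 1.0)
    return np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEIL)


def _fisher_scoring(k: np.ndarray, y: np.ndarray, s: np.ndarray,
                    alpha: np.ndarray, max_iter: int = 40, tol: float = 1e-8
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised NB GLM fit of (intercept, group effect) per feature.

    Returns natural-log coefficients ``beta1``, their standard errors, and a
    convergence mask.  Group totals of zero are handled by clipping the
    linear predictor, which bounds the reported fold change.
    """
    n_feat = k.shape[0]
    # moment start: per-group normalized means
    mask1 = y == 1
    mu0 = k[:, ~mask1].sum(axis=1) / s[~mask1].sum()
    mu1 = k[:, mask1].sum(axis=1) / s[mask1].sum()
    eps = 1e-8
    b0 = np.log(np.maximum(mu0, eps))
    b1 = np.log(np.maximum(mu1, eps)) - b0
    x = mask1.astype(float)
    log_s = np.log(s)
    # Fisher scoring on the active (not-yet-converged) feature set only.
    # All sample dependence enters through the size factor, so the mean matrix
    # is a rank-one product of per-feature group means and s_j — no matrix exp.
    active = np.arange(n_feat)
    for _ in range(max_iter):
        a0 = np.exp(np.clip(b0[active], -30.0, 30.0))
        a1 = np.exp(np.clip(b0[active] + b1[active], -30.0, 30.0))
        group_mean = np.where(mask1[None, :], a1[:, None], a0[:, None])
        mu = group_mean * s[None, :]
        denom = 1.0 + alpha[active, None] * mu
        w = mu / denom                 # Fisher weights
        r = (k[active] - mu) / denom   # working residual term
        # score and information for (b0, b1); x is 0/1 so i11 = i01
        u0 = r.sum(axis=1)
        u1 = r[:, mask1].sum(axis=1)
        i00 = w.sum(axis=1)
        i01 = w[:, mask1].sum(axis=1)
        det = i00 * i01 - i01**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        d0 = np.clip((i01 * u0 - i01 * u1) / det, -5, 5)
        d1 = np.clip((i00 * u1 - i01 * u0) / det, -5, 5)
        b0[active] = b0[active] + d0
        b1[active] = np.clip(b1[active] + d1, -30.0, 30.0)
        step = np.maximum(np.abs(d0), np.abs(d1))
        active = active[step >= tol]
        if active.size == 0:
            break
    converged = np.ones(n_feat, dtype=bool)
    converged[active] = False
    # standard error of b1 from the inverse Fisher information
    a0 = np.exp(np.clip(b0, -30.0, 30.0))
    a1 = np.exp(np.clip(b0 + b1, -30.0, 30.0))
    mu = np.where(mask1[None, :], a1[:, None], a0[:, None]) * s[None, :]
    w = mu / (1.0 + alpha[:, None] * mu)
    i00 = w.sum(axis=1)
    i01 = w[:, mask1].sum(axis=1)
    det = np.maximum(i00 * i01 - i01**2, 1e-300)
    se = np.sqrt(np.maximum(i00 / det, 0.0))
    return b1, se, converged


def nb_wald(counts: CountMatrix, meta: SampleMeta,
            dispersions: np.ndarray | None = None) -> pd.DataFrame:
    """Two-group negative-binomial Wald test per feature.

    Returns a DataFrame with one row per feature: ``feature_id, log2fc, se,
    wald_stat, p, padj, base_mean, dispersion`` plus the per-sample size
    factors in ``attrs["size_factors"]``.  Features with all-zero counts get
    ``log2fc = 0, p = 1`` and are flagged in ``all_zero``.
    """
    check_aligned(counts, meta=meta)
    meta.require_both_groups()
    y = meta.y
    for g, name in ((1, "case"), (0, "control")):
        if (y == g).sum() < 2:
            raise ValueError(f"need at least 2 {name} samples")
    s = size_factors(counts)
    k = counts.counts
    if dispersions is None:
        dispersions = estimate_dispersions(k, y, s)
    else:
        dispersions = np.clip(np.asarray(dispersions, float),
                              DISPERSION_FLOOR, DISPERSION_CEIL)

    b1, se, _ = _fisher_scoring(k, y, s, dispersions)
    all_zero = ~(k > 0).any(axis=1)
    log2fc = b1 / LN2
    se2 = se / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se2 > 0, log2fc / se2, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    log2fc[all_zero] = 0.0
    wald[all_zero] = 0.0
    p[all_zero] = 1.0
    base_mean = (k / s[None, :]).mean(axis=1)

    out = pd.DataFrame({
        "feature_id": counts.feature_ids,
        "log2fc": log2fc,
        "se": se2,
        "wald_stat": wald,
        "p": p,
        "padj": bh_adjust(p),
        "base_mean": base_mean,
        "dispersion": dispersions,
        "all_zero": all_zero,
    })
    out.attrs["size_factors"] = s
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de(results: pd.DataFrame, gate: DEGate | None = None) -> list:
    """Feature ids passing all three gates (strict inequalities)."""
    if len(results) == 0:
        raise ValueError("empty DE results")
    gate = gate or DEGate()
    ok = ((results["padj"] < gate.alpha)
          & (results["log2fc"].abs() > gate.min_abs_log2fc)
          & (results["base_mean"] > gate.min_base_mean))
    selected = list(results.loc[ok, "feature_id"])
    if not selected:
        logger.info("no feature passed the DE gate")
    return selected
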