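"""Calibration assessment of probabilistic predictions.

Hosmer-Lemeshow goodness-of-fit over risk deciles, Brier score, calibration
slope/intercept (logistic recalibration on the logit of the predicted
probability) and binned calibration-curve points.  Assessment only — no
recalibration is performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

PROB_EPS = 1e-6


@dataclass
class CalibrationReport:
    hl_stat: float
    hl_df: int
    hl_p: float
    brier: float
    slope: float
    intercept: float
    curve_points: np.ndarray  # (bins, 3): mean predicted, observed freq, count
    separation_flag: bool = False

    def to_dict(self) -> dict:
        return {"hl_stat": self.hl_stat, "hl_df": self.hl_df, "hl_p": self.hl_p,
                "brier": self.brier, "slope": self.slope,
                "intercept": self.intercept,
                "curve_points": self.curve_points.tolist(),
                "separation_flag": self.separation_flag}


def _check_inputs(p, y):
    p = np.asarray(p, float)
    y = np.asarray(y).astype(int)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("p and y must be 1-D arrays of equal length")
    if p.size == 0:
        raise ValueError("empty input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return p, y


def _bin_edges(p: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin assignment; tied probabilities share a bin
    (assigned to the lower one)."""
    order = np.argsort(p, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(p))
    raw = np.minimum((ranks * bins) // len(p), bins - 1)
    # samples with identical p must land in the same bin: take the min bin per value
    assign = raw.astype(int)
    for val in np.unique(p):
        m = p == val
        if m.sum() > 1:
            assign[m] = assign[m].min()
    return assign


def hosmer_lemeshow(p, y, bins: int = 10, df_mode: str = "fitted"
                    ) -> tuple[float, int, float]:
    """Hosmer-Lemeshow chi-square goodness-of-fit statistic.

    Samples are binned into risk deciles of predicted probability; bins whose
    expected event count falls below 1 are merged with their neighbor.  The
    statistic is ``sum (O - E)^2 / (E (1 - E/n_bin))`` with an upper-tail
    chi-square p-value.

    ``df_mode`` selects the reference distribution: ``"fitted"`` uses
    ``df = bins_used - 2``, the convention when the probabilities come from a
    model fitted on the same data; ``"external"`` uses ``df = bins_used``,
    appropriate when the probabilities were produced independently of the
    evaluated outcomes (e.g. held-out or simulated predictions).
    """
    if df_mode not in ("fitted", "external"):
        raise ValueError("df_mode must be 'fitted' or 'external'")
    p, y = _check_inputs(p, y)
    if len(p) < bins:
        raise ValueError("need at least as many samples as bins")
    assign = _bin_edges(p, bins)
    groups = []
    for b in np.unique(assign):
        m = assign == b
        groups.append([p[m].sum(), y[m].sum(), m.sum()])  # E, O, n
    # merge bins with expected count < 1 into the neighbor above
    merged = []
    for g in groups:
        if merged and merged[-1][0] < 1.0:
            merged[-1] = [merged[-1][0] + g[0], merged[-1][1] + g[1],
                          merged[-1][2] + g[2]]
        else:
            merged.append(list(g))
    if len(merged) > 1 and merged[-1][0] < 1.0:
        merged[-2] = [merged[-2][i] + merged[-1][i] for i in range(3)]
        merged.pop()
    if len(merged) < 3:
        raise ValueError("fewer than 3 usable bins after merging")
    stat = 0.0
    for e, o, n in merged:
        denom = e * (1.0 - e / n)
        if denom <= 0:
            denom = PROB_EPS
        stat += (o - e) ** 2 / denom
    df = len(merged) - (2 if df_mode == "fitted" else 0)
    p_value = float(stats.chi2.sf(stat, df))
    return float(stat), int(df), p_value


def brier_score(p, y) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p, y = _check_inputs(p, y)
    return float(np.mean((p - y) ** 2))


def calibration_slope(p, y) -> tuple[float, float, bool]:
    """Logistic regression of outcomes on logit(p): (slope, intercept, flag).

    Probabilities are clipped to [1e-6, 1 - 1e-6] before the logit.  Perfect
    separation is reported with ``flag=True`` rather than raised.
    """
    p, y = _check_inputs(p, y)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required")
    logit = np.log(np.clip(p, PROB_EPS, 1 - PROB_EPS))
    logit -= np.log(1 - np.clip(p, PROB_EPS, 1 - PROB_EPS))
    X = sm.add_constant(logit)
    # perfect separation: the score ranges of the two outcomes do not overlap
    flag = bool(p[y == 1].min() > p[y == 0].max()
                or p[y == 0].min() > p[y == 1].max())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            params = fit.params
        except Exception:  # perfect separation can break IRLS outright
            flag = True
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-4)
            params = fit.params
    intercept, slope = float(params[0]), float(params[1])
    if abs(slope) > 50:
        flag = True
        logger.warning("calibration slope unstable (|slope| > 50); "
                       "possible separation")
    return slope, intercept, flag


def calibration_curve(p, y, bins: int = 10) -> np.ndarray:
    """Binned calibration points: (mean predicted, observed fraction, count).

    Equal-frequency bins over predicted probability; empty bins (possible
    with heavy ties) are dropped.
    """
    p, y = _check_inputs(p, y)
    if len(p) < bins:
        raise ValueError("need at least as many samples as bins")
    assign = _bin_edges(p, bins)
    pts = []
    for b in np.unique(assign):
        m = assign == b
        pts.append([p[m].mean(), y[m].mean(), int(m.sum())])
    return np.asarray(pts, float)


def assess_calibration(p, y, bins: int = 10) -> CalibrationReport:
    """Full calibration report: HL test, Brier score, slope, curve points."""
    stat, df, hp = hosmer_lemeshow(p, y, bins)
    slope, intercept, flag = calibration_slope(p, y)
    return CalibrationReport(
        hl_stat=stat, hl_df=df, hl_p=hp, brier=brier_score(p, y),
        slope=slope, intercept=intercept,
        curve_points=calibration_curve(p, y, bins), separation_flag=flag)
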