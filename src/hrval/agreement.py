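"""Method-agreement statistics for windowed device-vs-criterion HR pairs.

Implements the usual validation battery: Bland-Altman systematic bias
with 95% limits of agreement, a two-tailed one-sample t test on the
differences, MAE / MAPE / 5%-accuracy / RMSE, ordinary least squares of
device on reference, Pearson r, and Lin's concordance correlation
coefficient with a Fisher-z confidence interval.

Throughout, a "pair" is one 10-second window mean and the difference is
``d = device - reference``. Statistics are pooled over subjects within a
grouping (per activity x wearing position, and overall per position);
a per-subject-then-average variant is available for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

#: Bland-Altman limits-of-agreement multiplier for a 95% interval
LOA_MULTIPLIER = 1.96
#: fewest pairs for which the full battery is computed
MIN_PAIRS = 3


@dataclass(frozen=True)
class AgreementReport:
    """The full accuracy statistic set for one grouping."""

    n_pairs: int
    bias: float
    loa_low: float
    loa_high: float
    t_stat: float
    t_p: float
    mae: float
    mape: float
    acc5: float
    rmse: float
    slope: float
    intercept: float
    r2: float
    pearson_r: float
    ccc: float
    ccc_ci_low: float
    ccc_ci_high: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _as_pairs(device, reference) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(device, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise ValueError("device and reference must have equal length")
    return x, y


def bias_loa(device, reference, multiplier: float = LOA_MULTIPLIER
             ) -> tuple[float, float, float]:
    """Systematic bias (mean of d) with limits of agreement
    ``bias ± multiplier * SD(d)`` (sample SD)."""
    x, y = _as_pairs(device, reference)
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - multiplier * sd, bias + multiplier * sd


def one_sample_t(diffs) -> tuple[float, float]:
    """Two-tailed one-sample t test of the differences against zero.

    A zero-variance input is degenerate: the statistic is reported as 0
    (all differences zero, p = 1) or signed infinity (constant non-zero
    difference, p = 0) rather than raising.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 differences")
    if d.std(ddof=1) == 0:
        m = float(d.mean())
        return (0.0, 1.0) if m == 0 else (math.copysign(math.inf, m), 0.0)
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue)


def error_metrics(device, reference) -> tuple[float, float, float, float]:
    """(MAE bpm, MAPE %, 5%-accuracy %, RMSE bpm).

    5%-accuracy is the percentage of windows whose absolute percentage
    error is within 5% of the reference value (boundary inclusive).
    """
    x, y = _as_pairs(device, reference)
    if np.any(y <= 0):
        raise ValueError("reference values must be positive")
    d = x - y
    ape = np.abs(d) / y
    mae = float(np.mean(np.abs(d)))
    mape = float(100.0 * ape.mean())
    acc5 = float(100.0 * np.mean(ape <= 0.05))
    rmse = float(np.sqrt(np.mean(d ** 2)))
    return mae, mape, acc5, rmse


def ols_fit(device, reference) -> tuple[float, float, float]:
    """Least-squares fit of device on reference: (slope, intercept, r²)."""
    x, y = _as_pairs(device, reference)
    if len(x) < MIN_PAIRS:
        raise ValueError("need at least 3 pairs")
    if np.std(y) == 0:
        raise ValueError("reference variance is zero")
    res = stats.linregress(y, x)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def pearson_r(device, reference) -> float:
    """Product-moment correlation between device and reference."""
    x, y = _as_pairs(device, reference)
    if len(x) < MIN_PAIRS:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def lin_ccc(device, reference, alpha: float = 0.05
            ) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with a CI.

    The point estimate uses population (1/n) moments,
    ``ccc = 2 s_xy / (s_x² + s_y² + (mean_x - mean_y)²)``; the CI is a
    Fisher z-interval with Lin's asymptotic standard error,
    back-transformed. Degenerate cases (|ccc| = 1) collapse the CI onto
    the point estimate.
    """
    x, y = _as_pairs(device, reference)
    n = len(x)
    if n < MIN_PAIRS:
        raise ValueError("need at least 3 pairs")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    if sx2 == 0 or sy2 == 0:
        raise ValueError("concordance undefined for a constant series")
    mx, my = float(x.mean()), float(y.mean())
    sxy = float(np.mean((x - mx) * (y - my)))
    ccc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    r = sxy / math.sqrt(sx2 * sy2)
    if 1.0 - ccc ** 2 < 1e-12 or r == 0 or n <= 2:
        return float(ccc), float(ccc), float(ccc)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    c2 = ccc ** 2
    var_z = (
        (1.0 - r ** 2) * c2 / ((1.0 - c2) * r ** 2)
        + 2.0 * ccc ** 3 * (1.0 - ccc) * u ** 2 / (r * (1.0 - c2) ** 2)
        - ccc ** 4 * u ** 4 / (2.0 * r ** 2 * (1.0 - c2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = math.atanh(ccc)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    half = zcrit * math.sqrt(var_z)
    return float(ccc), float(math.tanh(z - half)), float(math.tanh(z + half))


def agreement_stats(device, reference) -> AgreementReport:
    """The full battery for one group of windowed pairs."""
    x, y = _as_pairs(device, reference)
    bias, lo, hi = bias_loa(x, y)
    t_stat, t_p = one_sample_t(x - y)
    mae, mape, acc5, rmse = error_metrics(x, y)
    slope, intercept, r2 = ols_fit(x, y)
    r = pearson_r(x, y)
    ccc, ci_lo, ci_hi = lin_ccc(x, y)
    return AgreementReport(len(x), bias, lo, hi, t_stat, t_p, mae, mape, acc5,
                           rmse, slope, intercept, r2, r, ccc, ci_lo, ci_hi)


OVERALL = "overall"


def _group_row(g: pd.DataFrame) -> dict:
    x = g["hr_device"].to_numpy(dtype=float)
    y = g["hr_reference"].to_numpy(dtype=float)
    try:
        return agreement_stats(x, y).to_dict()
    except ValueError:
        # group too small or degenerate: report its size, not fabricated stats
        return {"n_pairs": len(g)}


def agreement_report(windows: pd.DataFrame,
                     aggregate: str = "pooled") -> pd.DataFrame:
    """Per-group agreement table from tidy windowed pairs.

    ``windows`` must carry ``position``, ``activity``, ``hr_device``,
    ``hr_reference`` (and ``subject_id`` for the ``"subject_mean"``
    variant). One row per (position, activity) plus an overall row per
    position. ``aggregate="pooled"`` pools windows across subjects (the
    conventional per-activity validation table); ``"subject_mean"``
    computes the battery per subject and averages the statistics,
    trading pseudo-replication for fewer effective n.
    """
    if aggregate not in ("pooled", "subject_mean"):
        raise ValueError("aggregate must be 'pooled' or 'subject_mean'")
    rows = []
    groups = [((pos, act), g) for (pos, act), g in
              windows.groupby(["position", "activity"], sort=True)]
    groups += [((pos, OVERALL), g) for pos, g in windows.groupby("position", sort=True)]
    for (pos, act), g in groups:
        if aggregate == "pooled":
            stats_row = _group_row(g)
        else:
            per_subject = [
                _group_row(sg) for _, sg in g.groupby("subject_id")
            ]
            per_subject = [r for r in per_subject if len(r) > 1]
            if not per_subject:
                stats_row = {"n_pairs": len(g)}
            else:
                keys = per_subject[0].keys()
                stats_row = {k: float(np.mean([r[k] for r in per_subject])) for k in keys}
                stats_row["n_pairs"] = int(len(g))
        rows.append({"position": pos, "activity": act, **stats_row})
    cols = ["position", "activity"] + [f.name for f in fields(AgreementReport)]
    return pd.DataFrame(rows).reindex(columns=cols)
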