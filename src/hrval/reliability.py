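"""Reliability and between-session reproducibility statistics.

Two questions are answered here. How consistently does a device track
the criterion within a subject (within-subject coefficient of variation
of the device-minus-reference differences)? And does the error
distribution shift between the two protocol sessions (Wilcoxon
signed-rank on paired subject x activity mean differences)?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import OVERALL


def wscv(windows: pd.DataFrame) -> float:
    """Within-subject coefficient of variation of d, in percent.

    For each subject with at least two retained windows in the group,
    the variance of ``d = hr_device - hr_reference`` is computed over
    that subject's windows; the variances are pooled with df weights
    (``sum (n_i - 1) s_i² / sum (n_i - 1)``) and the pooled SD is
    expressed as a percentage of the grand mean reference HR of the
    group. Pure per-subject bias therefore does not contribute — only
    within-subject variability of the error does.
    """
    num = 0.0
    den = 0
    for _, g in windows.groupby("subject_id"):
        d = (g["hr_device"] - g["hr_reference"]).to_numpy(dtype=float)
        if len(d) < 2:
            continue
        num += (len(d) - 1) * float(d.var(ddof=1))
        den += len(d) - 1
    if den == 0:
        raise ValueError("no subject has at least 2 windows in this group")
    grand_mean = float(windows["hr_reference"].mean())
    return 100.0 * float(np.sqrt(num / den)) / grand_mean


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided paired signed-rank result; W is min(W+, W-)."""

    w: float
    p: float
    n_used: int          # non-zero paired differences actually ranked
    exact: bool          # exact null enumeration vs normal approximation
    degenerate: bool = False  # all differences were zero


def wilcoxon_sessions(session1, session2) -> WilcoxonResult:
    """Paired signed-rank test of session-1 vs session-2 values.

    Zero differences are dropped (Wilcoxon's original treatment). The
    null distribution is enumerated exactly for n <= 25 when the
    absolute differences are untied; otherwise the normal approximation
    with tie and continuity correction is used. If every difference is
    zero the test is vacuous: W = 0, p = 1, flagged degenerate.
    """
    a = np.asarray(session1, dtype=float)
    b = np.asarray(session2, dtype=float)
    if a.shape != b.shape or len(a) == 0:
        raise ValueError("sessions must be equal-length, non-empty paired arrays")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, True, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    untied = len(np.unique(np.abs(d))) == n
    if n <= 25 and untied:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                             method="exact")
        return WilcoxonResult(w, float(res.pvalue), n, True)
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method="approx", correction=True)
    return WilcoxonResult(w, float(res.pvalue), n, False)


def session_cells(windows: pd.DataFrame) -> pd.DataFrame:
    """Subject x activity mean differences per session, wide format.

    Returns one row per (subject_id, activity) cell present in both
    sessions, with columns ``d_s1`` and ``d_s2``.
    """
    f = windows.assign(d=windows["hr_device"] - windows["hr_reference"])
    cells = (f.groupby(["subject_id", "activity", "session"])["d"]
             .mean().unstack("session"))
    cells = cells.dropna()
    if cells.shape[1] < 2:
        return pd.DataFrame(columns=["d_s1", "d_s2"])
    cells = cells.rename(columns={1: "d_s1", 2: "d_s2"})
    return cells.reset_index()[["subject_id", "activity", "d_s1", "d_s2"]]


def reliability_report(windows: pd.DataFrame) -> pd.DataFrame:
    """Per-position reliability table from tidy windowed pairs.

    One row per (position, activity) plus an overall row per position
    carrying the WSCV; the overall row additionally carries the
    between-session Wilcoxon test over subject x activity cell mean
    differences and per-session mean/SD of d. Groups where the WSCV is
    undefined (no subject with two windows) are reported with NaN.
    """
    rows = []
    for pos, gp in windows.groupby("position", sort=True):
        for act, g in gp.groupby("activity", sort=True):
            try:
                v = wscv(g)
            except ValueError:
                v = np.nan
            rows.append({"position": pos, "activity": act, "wscv": v})
        row = {"position": pos, "activity": OVERALL}
        try:
            row["wscv"] = wscv(gp)
        except ValueError:
            row["wscv"] = np.nan
        sessions = sorted(gp["session"].unique())
        d = gp["hr_device"] - gp["hr_reference"]
        for s in (1, 2):
            sel = d[gp["session"] == s]
            row[f"s{s}_mean_diff"] = float(sel.mean()) if len(sel) else np.nan
            row[f"s{s}_sd_diff"] = float(sel.std(ddof=1)) if len(sel) > 1 else np.nan
        if len(sessions) >= 2:
            cells = session_cells(gp)
            if len(cells):
                res = wilcoxon_sessions(cells["d_s1"], cells["d_s2"])
                row.update(wilcoxon_w=res.w, wilcoxon_p=res.p,
                           wilcoxon_n=res.n_used, wilcoxon_exact=res.exact)
        rows.append(row)
    cols = ["position", "activity", "wscv", "wilcoxon_w", "wilcoxon_p",
            "wilcoxon_n", "wilcoxon_exact",
            "s1_mean_diff", "s1_sd_diff", "s2_mean_diff", "s2_sd_diff"]
    return pd.DataFrame(rows).reindex(columns=cols)
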