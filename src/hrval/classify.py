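"""Interpretation bands, the validation table, and the end-to-end pipeline.

Computed statistics are mapped onto the interpretation scales customary
in wearable HR validation: MAPE accuracy bands, Pearson correlation
strength bands, McBride's concordance bands for the CCC, and WSCV
reliability bands. Band edges follow the lower-edge-inclusive
convention so adjacent printed ranges tile the scale without gaps
(e.g. "good 0.85-0.94" next to "very good 0.95-0.994" becomes
[0.85, 0.95) and [0.95, 0.995)). Pearson values below the bottom of the
printed scale are labeled ``below_scale`` rather than forced into the
lowest band.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import math
import numpy as np
import pandas as pd

from .preprocess import CleaningConfig, HRSeries, preprocess_cohort, read_hr_table, PreprocessResult
from .agreement import agreement_report
from .reliability import reliability_report

logger = logging.getLogger("hrval")

BELOW_SCALE = "below_scale"
UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class BandScheme:
    """Interpretation bands; each entry is (lower edge, label), labels
    applying on [edge_i, edge_{i+1})."""

    mape: tuple = ((0.0, "very_high"), (3.0, "high"), (5.0, "moderate"), (10.0, "low"))
    r: tuple = ((0.45, "very_poor"), (0.70, "poor"), (0.85, "good"),
                (0.95, "very_good"), (0.995, "excellent"))
    ccc: tuple = ((-1.0, "poor"), (0.90, "moderate"), (0.95, "substantial"),
                  (0.99, "almost_perfect"))
    wscv: tuple = ((0.0, "high_reliability"), (5.0, "acceptable"), (10.0, "poor"))

    def __post_init__(self) -> None:
        for name in ("mape", "r", "ccc", "wscv"):
            edges = [e for e, _ in getattr(self, name)]
            if edges != sorted(edges) or len(set(edges)) != len(edges):
                raise ValueError(f"{name} band edges must be strictly increasing")


DEFAULT_BANDS = BandScheme()

_SCALES = {"mape": "mape", "r": "r", "pearson_r": "r", "ccc": "ccc", "wscv": "wscv"}


def classify(statistic: str, value: float, scheme: BandScheme = DEFAULT_BANDS) -> str:
    """Band label for one statistic value.

    Values below the lowest edge of a scale (possible only for Pearson
    r, whose printed scale starts at 0.45) are labeled ``below_scale``;
    non-finite values are ``unavailable``.
    """
    if statistic not in _SCALES:
        raise ValueError(f"no band scheme for statistic {statistic!r}")
    if value is None or not math.isfinite(value):
        return UNAVAILABLE
    bands = getattr(scheme, _SCALES[statistic])
    label = BELOW_SCALE
    for edge, name in bands:
        if value >= edge:
            label = name
        else:
            break
    return label


def build_table(agreement: pd.DataFrame, reliability: pd.DataFrame,
                scheme: BandScheme = DEFAULT_BANDS) -> pd.DataFrame:
    """Merge agreement and reliability reports and attach band labels.

    One row per (position, activity) plus the overall rows; pure
    function of its inputs, so identical reports give a byte-identical
    serialized table.
    """
    table = agreement.merge(
        reliability[["position", "activity", "wscv", "wilcoxon_w", "wilcoxon_p"]],
        on=["position", "activity"], how="outer")
    table = table.sort_values(["position", "activity"]).reset_index(drop=True)
    table["mape_band"] = [classify("mape", v, scheme) for v in table["mape"]]
    table["r_band"] = [classify("r", v, scheme) for v in table["pearson_r"]]
    table["ccc_band"] = [classify("ccc", v, scheme) for v in table["ccc"]]
    table["wscv_band"] = [classify("wscv", v, scheme) for v in table["wscv"]]
    return table


def write_table(table: pd.DataFrame, out_dir) -> None:
    """Serialize the validation table as CSV and structured JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "validation_table.csv", index=False, float_format="%.6g")
    records = json.loads(table.to_json(orient="records"))
    (out / "validation_table.json").write_text(
        json.dumps(records, indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineResult:
    """Everything one validation run produces."""

    preprocess: PreprocessResult
    agreement: pd.DataFrame
    reliability: pd.DataFrame
    table: pd.DataFrame


def run_pipeline(series: Sequence[HRSeries] | None = None,
                 input_path=None,
                 cfg: CleaningConfig | None = None,
                 scheme: BandScheme = DEFAULT_BANDS,
                 out_dir=None) -> PipelineResult:
    """Execute preprocess -> agreement -> reliability -> classify -> table.

    Input is either in-memory traces or a trace table file. With
    ``out_dir`` set, the table (CSV + JSON) and a run log are written
    there.
    """
    if series is None:
        if input_path is None:
            raise ValueError("either series or input_path is required")
        series = read_hr_table(input_path)
    if not series:
        raise ValueError("empty cohort")
    cfg = cfg or CleaningConfig()
    pre = preprocess_cohort(series, cfg)
    if pre.windows.empty:
        raise ValueError("no retained windows after cleaning")
    agree = agreement_report(pre.windows)
    rel = reliability_report(pre.windows)
    table = build_table(agree, rel, scheme)
    if out_dir is not None:
        write_table(table, out_dir)
        lines = ["applied lags (s):"]
        lines += [f"  {r.subject_id}/s{r.session}/{r.position}: {r.lag_s:+d}"
                  for r in pre.lags.itertuples()]
        excluded = [s for s in pre.segments if s.excluded]
        lines.append(f"excluded activity segments: {len(excluded)}")
        lines += [f"  {s.subject_id}/s{s.session}/{s.position}/{s.activity}: "
                  f"{s.exclusion_reason}" for s in excluded]
        lines.append("artifact counts per series:")
        lines += ["  " + r.to_json() for _, r in pre.artifact_counts.iterrows()]
        Path(out_dir, "run_log.txt").write_text("\n".join(lines) + "\n")
    return PipelineResult(pre, agree, rel, table)
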