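"""Trace I/O and the cleaning pipeline for paired heart-rate validation.

The pipeline mirrors the standard processing chain for validating a
PPG-based wearable against an ECG criterion, in fixed order:

1. remove inter-activity rest periods,
2. synchronize each device to the reference by cross-correlation,
3. quantify and remove missing values and artifacts,
4. flag suspicious activity segments and screen the reference itself,
5. average the retained paired samples into 10-second windows.

All traces are 1 Hz beats-per-minute series carried as small pandas
DataFrames; missing samples are NaN (zeros in input files are parsed as
missing, the usual dropout encoding of commercial HR loggers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hrval")

REST_LABEL = "rest"
REFERENCE_POSITION = "chest"
DEVICE_POSITIONS = ("upper_arm", "forearm", "wrist_dominant", "wrist_nondominant")
VALID_POSITIONS = (REFERENCE_POSITION,) + DEVICE_POSITIONS

#: column order of the delimited trace format (one row per second)
TRACE_COLUMNS = ("subject_id", "device_id", "position", "session", "activity", "t_s", "hr_bpm")

ARTIFACT_TYPES = ("type_I", "type_II", "type_III")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds of the cleaning chain.

    Defaults are the conventional values for 1 Hz adult HR traces:
    physiological range 30-230 bpm, a 15 bpm single-second jump as a
    motion artifact, segment flags at more than 10 missing samples /
    more than 10 artifacts / Pearson r below 0.9, and 10-second
    averaging windows.
    """

    low_bpm: float = 30.0
    high_bpm: float = 230.0
    jump_bpm: float = 15.0
    flag_missing_max: int = 10
    flag_artifact_max: int = 10
    flag_r_min: float = 0.9
    window_s: int = 10
    max_lag_s: int = 120
    min_samples_per_window: int = 5

    def __post_init__(self) -> None:
        if not self.low_bpm < self.high_bpm:
            raise ValueError("low_bpm must be below high_bpm")
        for name in ("jump_bpm", "flag_missing_max", "flag_artifact_max",
                     "flag_r_min", "window_s", "max_lag_s", "min_samples_per_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class HRSeries:
    """One device's 1 Hz HR trace for one subject and session.

    ``samples`` has columns ``t_s`` (int seconds from session start,
    strictly increasing), ``activity`` (label, ``"rest"`` between
    activities) and ``hr_bpm`` (float bpm, NaN = missing).
    """

    subject_id: str
    device_id: str
    position: str
    session: int
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.position not in VALID_POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")
        t = self.samples["t_s"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        hr = self.samples["hr_bpm"].to_numpy(dtype=float)
        if np.any(hr[np.isfinite(hr)] <= 0):
            raise ValueError("hr_bpm must be missing or positive")

    @property
    def t(self) -> np.ndarray:
        return self.samples["t_s"].to_numpy()

    @property
    def hr(self) -> np.ndarray:
        return self.samples["hr_bpm"].to_numpy(dtype=float)

    @property
    def activity(self) -> np.ndarray:
        return self.samples["activity"].to_numpy()

    def __len__(self) -> int:
        return len(self.samples)

    def with_samples(self, samples: pd.DataFrame) -> "HRSeries":
        return HRSeries(self.subject_id, self.device_id, self.position,
                        self.session, samples.reset_index(drop=True))


@dataclass(frozen=True)
class ArtifactReport:
    """Per-sample artifact labels plus category counts for one series.

    Categories are disjoint per sample: range violations (type I below
    the floor, type II above the ceiling) take precedence over jump
    artifacts (type III); missing samples are counted separately and are
    never artifacts.
    """

    labels: pd.DataFrame  # columns t_s, activity, label
    counts: Mapping[str, int]

    @property
    def n_artifacts(self) -> int:
        return sum(self.counts[k] for k in ARTIFACT_TYPES)


@dataclass
class PairedSegment:
    """Lag-aligned device-vs-reference samples for one activity cell.

    ``data`` holds one row per second of the activity's time support
    (columns ``t_s``, ``hr_device``, ``hr_reference``); either side may
    be NaN, and :meth:`retained` gives the rows where both are present.
    After :func:`average_windows` the rows are window means instead and
    ``windowed`` is True.
    """

    subject_id: str
    session: int
    activity: str
    position: str
    data: pd.DataFrame
    applied_lag_s: int = 0
    t0: int = 0
    n_missing_device: int = 0
    n_missing_reference: int = 0
    n_artifacts_device: int = 0
    n_artifacts_reference: int = 0
    flags: frozenset = frozenset()
    excluded: bool = False
    exclusion_reason: str | None = None
    windowed: bool = False

    def retained(self) -> pd.DataFrame:
        return self.data.dropna(subset=["hr_device", "hr_reference"])

    @property
    def n_retained(self) -> int:
        return len(self.retained())


# ---------------------------------------------------------------------------
# step 0 — trace I/O
# ---------------------------------------------------------------------------

def read_hr_table(path) -> list[HRSeries]:
    """Read a delimited trace table into one HRSeries per (subject, device, session).

    Blank HR cells and zeros are parsed as missing.
    """
    df = pd.read_csv(path)
    missing_cols = set(TRACE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"malformed header, missing columns: {sorted(missing_cols)}")
    df = df.loc[:, list(TRACE_COLUMNS)].copy()
    df["hr_bpm"] = pd.to_numeric(df["hr_bpm"], errors="coerce")
    df.loc[df["hr_bpm"] == 0, "hr_bpm"] = np.nan
    bad = set(df["position"].unique()) - set(VALID_POSITIONS)
    if bad:
        raise ValueError(f"unknown position label(s): {sorted(bad)}")
    out = []
    for (subj, dev, pos, sess), g in df.groupby(
            ["subject_id", "device_id", "position", "session"], sort=True):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"non-monotone or duplicated timestamps for {subj}/{dev}/session {sess}")
        out.append(HRSeries(str(subj), str(dev), str(pos), int(sess),
                            g[["t_s", "activity", "hr_bpm"]].reset_index(drop=True)))
    return out


def write_hr_table(series: Iterable[HRSeries], path, missing_as_zero: bool = False) -> None:
    """Write traces in the same delimited format ``read_hr_table`` reads."""
    frames = []
    for s in series:
        f = s.samples.copy()
        f.insert(0, "subject_id", s.subject_id)
        f.insert(1, "device_id", s.device_id)
        f.insert(2, "position", s.position)
        f.insert(3, "session", s.session)
        frames.append(f[list(TRACE_COLUMNS)])
    table = pd.concat(frames, ignore_index=True)
    if missing_as_zero:
        table["hr_bpm"] = table["hr_bpm"].fillna(0.0)
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# step 1 — rest removal
# ---------------------------------------------------------------------------

def strip_rest(series: HRSeries) -> HRSeries:
    """Drop every sample labeled as between-activity rest."""
    keep = series.samples[series.samples["activity"] != REST_LABEL]
    return series.with_samples(keep)


# ---------------------------------------------------------------------------
# step 2 — synchronization
# ---------------------------------------------------------------------------

def _dense(series: HRSeries, t_min: int, t_max: int) -> np.ndarray:
    arr = np.full(t_max - t_min + 1, np.nan)
    arr[series.t - t_min] = series.hr
    return arr


def estimate_lag(device: HRSeries, reference: HRSeries, cfg: CleaningConfig) -> int:
    """Integer clock offset of the device against the reference.

    Returns the lag L in ``[-max_lag_s, +max_lag_s]`` maximizing the
    Pearson correlation between ``device[t]`` and ``reference[t - L]``
    over pairwise-complete samples; ties break toward the smallest
    ``|L|``, then toward the negative lag.
    """
    if not np.any(np.isfinite(device.hr)) or not np.any(np.isfinite(reference.hr)):
        raise ValueError("cannot synchronize all-missing series")
    t_min = int(min(device.t.min(), reference.t.min()))
    t_max = int(max(device.t.max(), reference.t.max()))
    d = _dense(device, t_min, t_max)
    r = _dense(reference, t_min, t_max)
    n = len(d)
    best_lag, best_r = None, -np.inf
    max_lag = int(cfg.max_lag_s)
    # visit lags in tie-break order: 0, -1, +1, -2, +2, ...
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda k: (abs(k), k > 0)):
        if abs(lag) >= n:
            continue
        if lag >= 0:
            x, y = d[lag:], r[:n - lag]
        else:
            x, y = d[:n + lag], r[-lag:]
        m = np.isfinite(x) & np.isfinite(y)
        if m.sum() < 3:
            continue
        xv, yv = x[m], y[m]
        sx, sy = xv.std(), yv.std()
        if sx == 0 or sy == 0:
            continue
        rho = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
        if rho > best_r:
            best_lag, best_r = lag, rho
    if best_lag is None:
        raise ValueError("correlation undefined at every lag (constant or disjoint series)")
    return int(best_lag)


def apply_lag(device: HRSeries, lag_s: int) -> HRSeries:
    """Shift device timestamps back by the estimated lag so the trace
    lives on the reference clock (``device[t] = reference[t - L]`` maps
    to ``t - L``)."""
    shifted = device.samples.copy()
    shifted["t_s"] = shifted["t_s"] - int(lag_s)
    return device.with_samples(shifted)


# ---------------------------------------------------------------------------
# step 3 — missing values and artifacts
# ---------------------------------------------------------------------------

def detect_artifacts(series: HRSeries, cfg: CleaningConfig) -> ArtifactReport:
    """Label each sample as ok / missing / type I / type II / type III.

    Type I: below ``low_bpm``.  Type II: above ``high_bpm``.  Type III:
    an absolute change of at least ``jump_bpm`` between consecutive
    seconds; the later sample of the jump is labeled, and jumps into or
    out of a sample already labeled type I/II are not double-counted.
    Jumps are only evaluated across adjacent timestamps (1 s apart) with
    both samples present.
    """
    hr = series.hr
    t = series.t
    n = len(hr)
    missing = ~np.isfinite(hr)
    type1 = np.isfinite(hr) & (hr < cfg.low_bpm)
    type2 = np.isfinite(hr) & (hr > cfg.high_bpm)
    range_art = type1 | type2
    type3 = np.zeros(n, dtype=bool)
    if n > 1:
        adjacent = np.diff(t) == 1
        both = np.isfinite(hr[1:]) & np.isfinite(hr[:-1])
        clean = ~range_art[1:] & ~range_art[:-1]
        jump = np.abs(np.diff(hr)) >= cfg.jump_bpm
        type3[1:] = adjacent & both & clean & jump
    labels = np.full(n, "ok", dtype=object)
    labels[missing] = "missing"
    labels[type3] = "type_III"
    labels[type1] = "type_I"
    labels[type2] = "type_II"
    frame = pd.DataFrame({"t_s": t, "activity": series.activity, "label": labels})
    counts = {
        "missing": int(missing.sum()),
        "type_I": int(type1.sum()),
        "type_II": int(type2.sum()),
        "type_III": int(type3.sum()),
    }
    return ArtifactReport(frame, counts)


def remove_artifacts(series: HRSeries, report: ArtifactReport) -> HRSeries:
    """Blank out every artifact-labeled sample (length and timestamps kept)."""
    if len(report.labels) != len(series) or not np.array_equal(
            report.labels["t_s"].to_numpy(), series.t):
        raise ValueError("artifact report does not match series")
    out = series.samples.copy()
    is_art = report.labels["label"].isin(ARTIFACT_TYPES).to_numpy()
    out.loc[is_art, "hr_bpm"] = np.nan
    return series.with_samples(out)


# ---------------------------------------------------------------------------
# pairing, flagging and reference screening
# ---------------------------------------------------------------------------

def _activity_order(series: HRSeries) -> list[str]:
    seen: dict[str, None] = {}
    for a in series.activity:
        if a != REST_LABEL and a not in seen:
            seen[a] = None
    return list(seen)


def build_pairs(reference: HRSeries, device: HRSeries, lag_s: int, cfg: CleaningConfig,
                ref_report: ArtifactReport, dev_report: ArtifactReport) -> list[PairedSegment]:
    """Join the cleaned, lag-aligned device onto the reference per activity.

    Missing and artifact counts per side come from the (pre-removal)
    artifact reports; device samples absent from an activity's time
    support (e.g. pushed out by the lag shift) count as missing.
    """
    ref = reference.samples.set_index("t_s")
    dev = device.samples.set_index("t_s")
    ref_lab = ref_report.labels.set_index("t_s")["label"]
    dev_lab = dev_report.labels.set_index("t_s")["label"]
    segments = []
    for act in _activity_order(reference):
        tt = ref.index[ref["activity"] == act]
        hr_ref = ref.loc[tt, "hr_bpm"].to_numpy(dtype=float)
        hr_dev = dev["hr_bpm"].reindex(tt).to_numpy(dtype=float)
        rl = ref_lab.loc[tt]
        dl = dev_lab.reindex(tt)  # NaN where the device has no sample at all
        seg = PairedSegment(
            subject_id=reference.subject_id,
            session=reference.session,
            activity=act,
            position=device.position,
            data=pd.DataFrame({"t_s": tt.to_numpy(), "hr_device": hr_dev,
                               "hr_reference": hr_ref}),
            applied_lag_s=int(lag_s),
            t0=int(tt.min()),
            n_missing_reference=int((rl == "missing").sum()),
            n_missing_device=int((dl == "missing").sum() + dl.isna().sum()),
            n_artifacts_reference=int(rl.isin(ARTIFACT_TYPES).sum()),
            n_artifacts_device=int(dl.isin(ARTIFACT_TYPES).sum()),
        )
        segments.append(seg)
    return segments


def flag_segment(pair: PairedSegment, cfg: CleaningConfig) -> PairedSegment:
    """Apply the three segment-quality rules.

    A segment is flagged when either side has more than
    ``flag_missing_max`` missing samples, either side has more than
    ``flag_artifact_max`` artifacts, or the device-reference Pearson
    correlation over retained pairs falls below ``flag_r_min`` (segments
    with fewer than 3 retained pairs, or a constant side, are flagged as
    low-correlation by convention).
    """
    flags = set()
    if max(pair.n_missing_device, pair.n_missing_reference) > cfg.flag_missing_max:
        flags.add("too_many_missing")
    if max(pair.n_artifacts_device, pair.n_artifacts_reference) > cfg.flag_artifact_max:
        flags.add("too_many_artifacts")
    kept = pair.retained()
    if len(kept) < 3:
        flags.add("low_correlation")
    else:
        x = kept["hr_device"].to_numpy()
        y = kept["hr_reference"].to_numpy()
        if x.std() == 0 or y.std() == 0:
            flags.add("low_correlation")
        elif float(np.corrcoef(x, y)[0, 1]) < cfg.flag_r_min:
            flags.add("low_correlation")
    return replace(pair, flags=frozenset(flags))


def screen_reference(pairs: Sequence[PairedSegment], cfg: CleaningConfig) -> list[PairedSegment]:
    """Deterministic stand-in for visual screening of the criterion trace.

    ``pairs`` are all flagged segments of one subject-session across
    positions. A flagged activity is excluded — for every position —
    only when the blame lies with the reference: its own artifact count
    in that activity exceeds ``flag_artifact_max``, or the activity is
    low-correlated against at least two independent device positions.
    """
    by_activity: dict[str, list[PairedSegment]] = {}
    for p in pairs:
        by_activity.setdefault(p.activity, []).append(p)
    out = []
    for act, segs in by_activity.items():
        ref_bad = any(s.n_artifacts_reference > cfg.flag_artifact_max for s in segs)
        low_pos = {s.position for s in segs if "low_correlation" in s.flags}
        if any(s.flags for s in segs) and (ref_bad or len(low_pos) >= 2):
            reason = ("reference_artifacts" if ref_bad else "reference_low_correlation")
            out.extend(replace(s, excluded=True, exclusion_reason=reason) for s in segs)
        else:
            out.extend(segs)
    return out


# ---------------------------------------------------------------------------
# step 5 — window averaging
# ---------------------------------------------------------------------------

def average_windows(pair: PairedSegment, cfg: CleaningConfig) -> PairedSegment:
    """Average retained pairs into non-overlapping windows.

    Windows are anchored at the activity start ``t0`` (half-open
    ``[t0 + k*w, t0 + (k+1)*w)``); a trailing window not fully covered
    by the activity's time span is dropped, as is any window with fewer
    than ``min_samples_per_window`` retained pairs.
    """
    w = int(cfg.window_s)
    span_end = int(pair.data["t_s"].max()) + 1
    n_full = (span_end - pair.t0) // w
    kept = pair.retained()
    k = (kept["t_s"].to_numpy() - pair.t0) // w
    kept = kept.assign(window=k)
    kept = kept[kept["window"] < n_full]
    g = kept.groupby("window")
    agg = g.agg(hr_device=("hr_device", "mean"), hr_reference=("hr_reference", "mean"),
                n=("t_s", "size")).reset_index()
    agg = agg[agg["n"] >= cfg.min_samples_per_window]
    data = pd.DataFrame({
        "t_s": pair.t0 + agg["window"].to_numpy() * w,
        "hr_device": agg["hr_device"].to_numpy(),
        "hr_reference": agg["hr_reference"].to_numpy(),
        "n": agg["n"].to_numpy(),
    })
    return replace(pair, data=data.reset_index(drop=True), windowed=True)


# ---------------------------------------------------------------------------
# whole-cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    """Windowed pairs plus the bookkeeping the cleaning chain produced."""

    windows: pd.DataFrame          # tidy: subject, session, position, activity, t_s, hr_device, hr_reference, n
    segments: list[PairedSegment]  # all segments incl. excluded ones (1 Hz resolution)
    lags: pd.DataFrame             # applied lag per subject x session x position
    artifact_counts: pd.DataFrame  # per series counts


def windows_table(segments: Iterable[PairedSegment]) -> pd.DataFrame:
    """Tidy table of window means from non-excluded windowed segments."""
    rows = []
    for s in segments:
        if s.excluded or not s.windowed:
            continue
        f = s.data.copy()
        f.insert(0, "subject_id", s.subject_id)
        f.insert(1, "session", s.session)
        f.insert(2, "position", s.position)
        f.insert(3, "activity", s.activity)
        rows.append(f)
    if not rows:
        return pd.DataFrame(columns=["subject_id", "session", "position", "activity",
                                     "t_s", "hr_device", "hr_reference", "n"])
    return pd.concat(rows, ignore_index=True)


def preprocess_cohort(series: Sequence[HRSeries],
                      cfg: CleaningConfig | None = None) -> PreprocessResult:
    """Run the full cleaning chain over a cohort of traces.

    ``series`` holds, per subject and session, one reference trace
    (position ``"chest"``) and one trace per device position. The lag is
    estimated once per subject x session x device, pooling activities,
    because a clock offset is a property of the recording, not of the
    activity.
    """
    cfg = cfg or CleaningConfig()
    by_cell: dict[tuple[str, int], dict[str, HRSeries]] = {}
    for s in series:
        by_cell.setdefault((s.subject_id, s.session), {})[s.position] = s

    all_segments: list[PairedSegment] = []
    lag_rows, art_rows = [], []
    for (subj, sess), traces in sorted(by_cell.items()):
        if REFERENCE_POSITION not in traces:
            raise ValueError(f"no reference trace for {subj} session {sess}")
        ref_raw = strip_rest(traces[REFERENCE_POSITION])
        ref_rep = detect_artifacts(ref_raw, cfg)
        ref_clean = remove_artifacts(ref_raw, ref_rep)
        art_rows.append({"subject_id": subj, "session": sess,
                         "position": REFERENCE_POSITION, **ref_rep.counts})
        cell_segments: list[PairedSegment] = []
        for pos in sorted(p for p in traces if p != REFERENCE_POSITION):
            dev_raw = strip_rest(traces[pos])
            lag = estimate_lag(dev_raw, ref_raw, cfg)
            aligned = apply_lag(dev_raw, lag)
            dev_rep = detect_artifacts(aligned, cfg)
            dev_clean = remove_artifacts(aligned, dev_rep)
            art_rows.append({"subject_id": subj, "session": sess,
                             "position": pos, **dev_rep.counts})
            lag_rows.append({"subject_id": subj, "session": sess,
                             "position": pos, "lag_s": lag})
            logger.info("lag %s/%s/%s: %+d s", subj, sess, pos, lag)
            pairs = build_pairs(ref_clean, dev_clean, lag, cfg, ref_rep, dev_rep)
            cell_segments.extend(flag_segment(p, cfg) for p in pairs)
        screened = screen_reference(cell_segments, cfg)
        for p in screened:
            if p.excluded:
                logger.info("excluded %s/%s/%s/%s: %s", subj, sess, p.position,
                            p.activity, p.exclusion_reason)
                all_segments.append(p)
            else:
                all_segments.append(average_windows(p, cfg))
    return PreprocessResult(
        windows=windows_table(all_segments),
        segments=all_segments,
        lags=pd.DataFrame(lag_rows, columns=["subject_id", "session", "position", "lag_s"]),
        artifact_counts=pd.DataFrame(art_rows),
    )
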