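"""Cleaning chain: I/O, rest removal, synchronization, artifacts,
flagging/screening and window averaging."""

import numpy as np
import pandas as pd
import pytest

from hrval import (
    CleaningConfig,
    DeviceErrorModel,
    SubjectParams,
    average_windows,
    build_pairs,
    detect_artifacts,
    estimate_lag,
    flag_segment,
    preprocess_cohort,
    read_hr_table,
    remove_artifacts,
    screen_reference,
    simulate_cohort,
    simulate_device,
    simulate_reference,
    strip_rest,
    write_hr_table,
)
from hrval.preprocess import PairedSegment, apply_lag


# ---------------------------------------------------------------- trace I/O

def test_zero_and_blank_cells_parse_as_missing(tmp_path):
    p = tmp_path / "traces.csv"
    p.write_text("subject_id,device_id,position,session,activity,t_s,hr_bpm\n"
                 "S01,dev,upper_arm,1,walking,0,80\n"
                 "S01,dev,upper_arm,1,walking,1,0\n"
                 "S01,dev,upper_arm,1,walking,2,90\n"
                 "S01,dev,upper_arm,1,walking,3,\n"
                 "S01,dev,upper_arm,1,walking,4,100\n")
    (back,) = read_hr_table(p)
    assert np.isnan(back.hr[[1, 3]]).all()
    np.testing.assert_array_equal(back.hr[[0, 2, 4]], [80, 90, 100])
    assert (back.subject_id, back.position, back.session) == ("S01", "upper_arm", 1)


def test_write_read_roundtrip(tmp_path, make_series):
    s = make_series([80, np.nan, 90], device_id="dev")
    path = tmp_path / "traces.csv"
    write_hr_table([s], path, missing_as_zero=True)
    (back,) = read_hr_table(path)
    pd.testing.assert_frame_equal(back.samples, s.samples)


def test_read_rejects_malformed_header(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("subject,hr\nS01,80\n")
    with pytest.raises(ValueError, match="header"):
        read_hr_table(p)


def test_read_rejects_duplicate_timestamps(tmp_path, make_series):
    s = make_series([80, 81, 82])
    df = s.samples.copy()
    df.loc[2, "t_s"] = 1
    p = tmp_path / "dup.csv"
    header = "subject_id,device_id,position,session,activity,t_s,hr_bpm\n"
    rows = "".join(f"S01,dev,upper_arm,1,walking,{t},{h}\n"
                   for t, h in zip(df.t_s, df.hr_bpm))
    p.write_text(header + rows)
    with pytest.raises(ValueError, match="timestamp"):
        read_hr_table(p)


def test_read_rejects_unknown_position(tmp_path):
    p = tmp_path / "pos.csv"
    p.write_text("subject_id,device_id,position,session,activity,t_s,hr_bpm\n"
                 "S01,dev,ankle,1,walking,0,80\n")
    with pytest.raises(ValueError, match="position"):
        read_hr_table(p)


# ------------------------------------------------------------- rest removal

def test_strip_rest_bookkeeping(make_series):
    s = make_series(np.full(420, 80.0),
                    activity=["walking"] * 300 + ["rest"] * 120)
    stripped = strip_rest(s)
    assert len(stripped) == 300
    assert set(stripped.activity) == {"walking"}


def test_strip_rest_identity_without_rest(make_series):
    s = make_series([80, 81, 82])
    pd.testing.assert_frame_equal(strip_rest(s).samples, s.samples)


def test_strip_rest_default_session_retains_85_minutes(proto, subject):
    (ses, _) = simulate_reference(proto, subject, seed=0)
    assert len(strip_rest(ses)) == 85 * 60


# ---------------------------------------------------------- synchronization

def _wandering(n, seed=0):
    rng = np.random.default_rng(seed)
    return 100 + np.cumsum(rng.standard_normal(n))


def test_lag_recovered_on_shifted_series(cfg, make_series):
    vals = _wandering(660)
    ref = make_series(vals, position="chest", device_id="ref")
    t = np.arange(7, 660)
    dev = make_series(vals[:-7], t=t)  # dev[t] = ref[t-7]
    assert estimate_lag(dev, ref, cfg) == 7
    assert estimate_lag(ref, ref, cfg) == 0


@pytest.mark.parametrize("lag", range(-30, 31, 5))
def test_lag_exhaustive_noiseless(cfg, make_series, lag):
    vals = _wandering(700, seed=3)
    ref = make_series(vals[50:650], t=np.arange(50, 650), position="chest")
    dev = make_series(vals[50 - lag:650 - lag], t=np.arange(50, 650))
    assert estimate_lag(dev, ref, cfg) == lag


def test_lag_recovered_under_noise_all_seeds(cfg, make_series):
    """+7 s shift plus 2 bpm Gaussian noise over 600 s: recovery on all of
    50 independent noise draws."""
    vals = _wandering(700, seed=8)
    ref = make_series(vals[60:660], t=np.arange(60, 660), position="chest")
    hits = 0
    for seed in range(50):
        noise = np.random.default_rng(seed).normal(0, 2, 600)
        dev = make_series(vals[53:653] + noise, t=np.arange(60, 660))
        hits += estimate_lag(dev, ref, cfg) == 7
    assert hits == 50


def test_lag_errors_on_degenerate_input(cfg, make_series):
    const = make_series(np.full(50, 80.0))
    with pytest.raises(ValueError):
        estimate_lag(const, const, cfg)
    empty = make_series(np.full(50, np.nan))
    with pytest.raises(ValueError):
        estimate_lag(empty, empty, cfg)


# ----------------------------------------------------------------- artifacts

def test_artifact_rule_traces(cfg, make_series):
    # a type I sample blocks the following jump from counting as type III
    rep = detect_artifacts(make_series([60, 25, 70]), cfg)
    assert rep.counts == {"missing": 0, "type_I": 1, "type_II": 0, "type_III": 0}
    assert list(rep.labels["label"]) == ["ok", "type_I", "ok"]

    # jumps of 14.9 and 5.1 stay under the 15 bpm threshold
    rep = detect_artifacts(make_series([100, 114.9, 120]), cfg)
    assert rep.n_artifacts == 0

    # range violation above the ceiling
    rep = detect_artifacts(make_series([100, 240, 100]), cfg)
    assert rep.counts["type_II"] == 1
    assert list(rep.labels["label"]) == ["ok", "type_II", "ok"]

    # the threshold itself is artifactual (|delta| >= 15), later sample labeled
    rep = detect_artifacts(make_series([100, 115]), cfg)
    assert list(rep.labels["label"]) == ["ok", "type_III"]


def test_artifact_jump_needs_adjacent_present_samples(cfg, make_series):
    # time gap between the samples: no jump evaluated
    rep = detect_artifacts(make_series([100, 130], t=[0, 5]), cfg)
    assert rep.n_artifacts == 0
    # missing neighbor: no jump evaluated, missing counted separately
    rep = detect_artifacts(make_series([100, np.nan, 130]), cfg)
    assert rep.counts == {"missing": 1, "type_I": 0, "type_II": 0, "type_III": 0}


def test_remove_artifacts_bookkeeping_and_idempotence(cfg, make_series):
    s = make_series([100, 25, 240, 100, 100, 140, 100])
    rep = detect_artifacts(s, cfg)
    assert rep.n_artifacts == 4  # 25, 240, and both edges of the 140 spike
    cleaned = remove_artifacts(s, rep)
    assert len(cleaned) == len(s)
    assert int(np.isfinite(cleaned.hr).sum()) == int(np.isfinite(s.hr).sum()) - 4
    re_rep = detect_artifacts(cleaned, cfg)
    assert re_rep.counts["type_I"] == 0 and re_rep.counts["type_II"] == 0
    assert re_rep.n_artifacts == 0
    # identity on a clean series
    clean = make_series([100, 101, 102])
    pd.testing.assert_frame_equal(
        remove_artifacts(clean, detect_artifacts(clean, cfg)).samples,
        clean.samples)


def test_remove_artifacts_rejects_mismatched_report(cfg, make_series):
    rep = detect_artifacts(make_series([100, 101]), cfg)
    with pytest.raises(ValueError, match="match"):
        remove_artifacts(make_series([100, 101, 102]), rep)


# ------------------------------------------------------- flagging, screening

def _segment(n=60, n_missing_dev=0, n_art_dev=0, n_art_ref=0, r_noise=0.5,
             position="upper_arm", activity="walking"):
    rng = np.random.default_rng(1)
    ref = np.linspace(80, 160, n)  # exercise-like HR ramp
    dev = ref + rng.normal(0, r_noise, n)
    return PairedSegment("S01", 1, activity, position,
                         pd.DataFrame({"t_s": np.arange(n), "hr_device": dev,
                                       "hr_reference": ref}),
                         n_missing_device=n_missing_dev,
                         n_artifacts_device=n_art_dev,
                         n_artifacts_reference=n_art_ref)


def test_flag_missing_boundary_is_strict(cfg):
    assert "too_many_missing" in flag_segment(_segment(n_missing_dev=11), cfg).flags
    assert not flag_segment(_segment(n_missing_dev=10), cfg).flags


def test_flag_clean_segment_has_high_correlation(cfg):
    flagged = flag_segment(_segment(r_noise=1.0), cfg)
    assert not flagged.flags


def test_flag_low_correlation_and_tiny_segments(cfg):
    noisy = _segment(r_noise=60.0)
    assert "low_correlation" in flag_segment(noisy, cfg).flags
    tiny = _segment(n=2)
    assert "low_correlation" in flag_segment(tiny, cfg).flags


def test_screen_excludes_only_reference_faults(cfg):
    # reference with 12 internal artifacts: the whole activity goes
    bad_ref = flag_segment(_segment(n_art_ref=12), cfg)
    (screened,) = screen_reference([bad_ref], cfg)
    assert screened.excluded and screened.exclusion_reason == "reference_artifacts"

    # one noisy device alone does not incriminate the reference
    noisy_dev = flag_segment(_segment(r_noise=60.0), cfg)
    (kept,) = screen_reference([noisy_dev], cfg)
    assert not kept.excluded

    # low correlation against two independent positions does
    a = flag_segment(_segment(r_noise=60.0, position="upper_arm"), cfg)
    b = flag_segment(_segment(r_noise=60.0, position="forearm"), cfg)
    screened = screen_reference([a, b], cfg)
    assert all(s.excluded for s in screened)
    assert {s.exclusion_reason for s in screened} == {"reference_low_correlation"}


# ----------------------------------------------------------------- windowing

def _pair_from(dev, ref, t0=0):
    n = len(dev)
    return PairedSegment("S01", 1, "walking", "upper_arm",
                         pd.DataFrame({"t_s": np.arange(t0, t0 + n),
                                       "hr_device": np.asarray(dev, float),
                                       "hr_reference": np.asarray(ref, float)}),
                         t0=t0)


def test_windows_constant_and_hand_means(cfg):
    out = average_windows(_pair_from([80.0] * 20, [80.0] * 20), cfg)
    assert out.windowed and len(out.data) == 2
    np.testing.assert_allclose(out.data["hr_device"], [80, 80])

    out = average_windows(_pair_from(np.arange(1.0, 21.0), [100.0] * 20), cfg)
    np.testing.assert_allclose(out.data["hr_device"], [5.5, 15.5])
    np.testing.assert_allclose(out.data["t_s"], [0, 10])


def test_windows_full_retention_count_for_15min_activity(cfg):
    n = 15 * 60
    out = average_windows(_pair_from(np.full(n, 90.0), np.full(n, 90.0)), cfg)
    assert len(out.data) == 90


def test_windows_drop_trailing_partial_and_sparse(cfg):
    # 25 samples: the third window is partial and dropped
    out = average_windows(_pair_from([80.0] * 25, [80.0] * 25), cfg)
    assert len(out.data) == 2
    # a window with fewer than min_samples_per_window retained pairs is dropped
    dev = np.full(20, 80.0)
    dev[:6] = np.nan
    out = average_windows(_pair_from(dev, [80.0] * 20), cfg)
    np.testing.assert_array_equal(out.data["t_s"], [10])


def test_windowing_conserves_the_mean_when_tiling_exactly(cfg):
    rng = np.random.default_rng(4)
    dev = 100 + rng.standard_normal(50)
    out = average_windows(_pair_from(dev, np.full(50, 100.0)), cfg)
    assert out.data["hr_device"].mean() == pytest.approx(dev.mean(), abs=1e-12)


# -------------------------------------------------------------- end to end

def test_pipeline_counts_never_increase_and_recover_lag(cfg, tiny_proto):
    model = DeviceErrorModel(lag_s=3, bias_bpm=1.0, noise_sd_bpm=0.5)
    cohort = simulate_cohort(2, tiny_proto, {"upper_arm": model}, seed=21)
    res = preprocess_cohort(cohort.series, cfg)
    assert (res.lags["lag_s"] == 3).all()
    raw_non_missing = sum(int(np.isfinite(s.hr).sum()) for s in cohort.series
                          if s.position == "upper_arm")
    retained = int(res.windows["n"].sum())
    assert retained <= raw_non_missing


def test_pipeline_excludes_corrupted_reference_session(cfg, tiny_proto):
    """A reference session riddled with artifacts loses its activities,
    while the other session's metrics survive untouched."""
    model = DeviceErrorModel(noise_sd_bpm=0.5)
    cohort = simulate_cohort(1, tiny_proto, {"upper_arm": model, "forearm": model},
                             seed=33)
    for s in cohort.series:
        if s.position == "chest" and s.session == 1:
            # alternating wild values -> many type III artifacts in every activity
            hr = s.samples["hr_bpm"].to_numpy()
            hr[::2] += 60.0
            s.samples["hr_bpm"] = hr
    res = preprocess_cohort(cohort.series, cfg)
    excluded = [seg for seg in res.segments if seg.excluded]
    assert excluded and all(seg.session == 1 for seg in excluded)
    kept_sessions = set(res.windows["session"])
    assert kept_sessions == {2}
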