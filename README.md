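# hrval

Accuracy and reliability validation of wearable heart-rate (HR) monitors
against a criterion measure.

Optical (PPG) wrist- and arm-worn devices estimate HR from blood-volume
changes and are sensitive to wearing position, motion artifacts and blood
flow, so they need ongoing validation against ECG-grade references.
`hrval` implements the complete validation workflow for paired 1 Hz HR
traces recorded over a structured exercise protocol: a synthetic cohort
generator with a configurable device error model, the data-cleaning chain,
the agreement statistic battery, test-retest reliability, and the
interpretation bands customary in this literature — assembled into a
per-activity × per-wearing-position validation table. It is aimed at
researchers validating devices (or processing pipelines) and at anyone who
needs a ground-truth-controlled test bed for HR agreement statistics.

## The statistics

For paired 10-second window means, with difference d = device − reference:

- **Systematic bias and 95% limits of agreement** (Bland–Altman):
  bias = mean(d), LoA = bias ± 1.96·SD(d); with a two-tailed one-sample
  *t* test of d against zero.
- **Error metrics**: MAE = mean|d|; MAPE = 100·mean(|d|/ref);
  5%-accuracy = % of windows with |d|/ref ≤ 0.05; RMSE = √mean(d²).
- **Association**: OLS of device on reference (slope, intercept, r²) and
  Pearson *r*.
- **Concordance**: Lin's CCC = 2·s_xy / (s_x² + s_y² + (x̄−ȳ)²), with a
  Fisher-z confidence interval using Lin's asymptotic standard error.
- **Reliability**: within-subject coefficient of variation,
  WSCV = 100·√(pooled within-subject Var(d)) / mean reference HR, and a
  Wilcoxon signed-rank test comparing per-cell mean differences between
  the two protocol sessions (exact null enumeration for n ≤ 25 untied
  pairs, normal approximation with tie/continuity correction otherwise).

Cleaning follows the conventional five steps: rest removal →
cross-correlation synchronization (integer lag, ±120 s) → artifact
removal (type I < 30 bpm, type II > 230 bpm, type III consecutive jump
≥ 15 bpm) with missing-value quantification → segment flagging (> 10
missing, > 10 artifacts, or r < 0.9) with deterministic screening of the
reference itself → 10-second window averaging.

## Worked example

Simulate a 4-subject cohort over the default 9-activity, 2-session
protocol with an upper-arm device carrying a 7 s clock lag, +2 bpm bias
and 1 bpm noise, then run the full pipeline:

```python
import hrval as hv

model = hv.DeviceErrorModel(lag_s=7, bias_bpm=2.0, noise_sd_bpm=1.0)
cohort = hv.simulate_cohort(4, hv.default_protocol(), {"upper_arm": model}, seed=1)
res = hv.run_pipeline(series=cohort.series)
print(res.preprocess.lags["lag_s"].unique())   # -> [7]
print(res.table[["position", "activity", "n_pairs", "bias", "mape",
                 "ccc", "wscv", "mape_band", "wscv_band"]])
```

Selected rows of the resulting table:

```
 position activity  n_pairs  bias  mape  pearson_r  ccc  wscv mape_band        wscv_band
upper_arm     hiit      376  1.98  1.34       1.00 1.00  0.21 very_high high_reliability
upper_arm  jogging      376  1.99  1.65       1.00 0.99  0.26 very_high high_reliability
upper_arm    lying      232  1.99  3.46       1.00 0.97  0.50      high high_reliability
upper_arm  overall     4008  2.00  2.27       1.00 1.00  0.32 very_high high_reliability
```

The injected clock lag is recovered exactly for every recording and the
overall bias matches the injected +2 bpm. MAPE is lowest during
high-HR activities (an error of fixed size is relatively smaller there)
and the lying-down MAPE of 3.46% drops the band from "very high" to
"high" accuracy — the same pattern real wrist/arm validation studies
report. The same workflow is available from the shell:

```sh
hrval simulate --n-subjects 4 --seed 1 --bias 2 --lag 7 --out traces.csv
hrval validate traces.csv --out-dir results/
hrval report results/validation_table.csv
```

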