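# wearqc

Data-quality toolkit for ambulatory wrist-wearable recordings (Empatica-E4
style): multi-modal **non-wear detection**, **EDA artifact processing**, a
raw-accelerometry **activity intensity index**, **block-gap bootstrapping**
for missing-data impact analysis, and **participant compliance analytics** —
all exercisable end-to-end on seeded synthetic recordings with ground-truth
wear structure, so nothing requires a real dataset.

It is written for researchers running ambulatory monitoring studies
(headache, stress, sleep, epilepsy …) who stream multi-channel wrist data
(3-axis ACC at 32 Hz, EDA at 4 Hz, skin temperature at 4 Hz, BVP at 64 Hz)
and need to answer: *when was the device actually worn, which samples are
trustworthy, and how much do missing segments distort my outcome metrics?*

## Methods at a glance

**Non-wear detection.** Per-signal boolean signal-quality indices (SQIs) are
thresholded and combined. Two variants:

| | Böttcher et al. | refined |
|---|---|---|
| movement SQI | Σ of 3 per-axis 10-s SDs ≥ 0.2 g | x-axis 1-s SD ≥ 0.1 g |
| temperature SQI | 25 °C ≤ T ≤ 40 °C | T ≥ 32 °C |
| EDA SQI | ≥ 0.05 μS | ≥ 0.03 μS |
| aggregation | ≥ 1 % on-body per 1-min window, then OR | reindex to 4-Hz EDA grid, OR, 1-min majority smoothing |
| output granularity | 1 min | 0.25 s |

**EDA processing.** A composite validity SQI (noise amplitude < threshold ∧
plausible range ∧ wrist on-body); invalid runs ≤ 5 s are linearly
interpolated, longer ones dropped, and surviving segments shorter than 60 s
excluded.

**Activity index.** Per tumbling epoch of length *e* (default 1 s),
`AI = sqrt(max(mean_axes(var_axis − σ²_noise), 0))` — the absolute form of
Bai et al.'s activity index on raw 3-axis acceleration in g.

**Gap bootstrap.** From a gap-free reference window, remove exactly
`round((1 − r)·n)` samples as contiguous blocks (single, multi-block, or
bout-length-sampled), recompute `{p50, p75, mean}` on the retained samples,
repeat with independent seeded substreams, and summarise bias/SD/90 %
interval per retention ratio `r` against the gap-free reference.

**Compliance.** Sample timestamps → data sessions; wear seconds apportioned
to local days by midnight clipping; a day is compliant at ≥ 8 h of wear;
plus coverage ratios, a 7 × 48 time-of-day × weekday heatmap, CCDF of
window data ratios, questionnaire interaction rates, and event-log sanity
checks (concurrent same-kind events, future-dated, backdated > 2 weeks).

## Worked example

```python
import numpy as np
from wearqc import (IntervalSet, ScenarioConfig, detect_nonwear,
                    EdaQualityProcessor, activity_index_abs, GapBootstrap)
from wearqc.synthetic import generate_recording

# 20 min of synthetic E4 data with a 5-min removal at 400-700 s
cfg = ScenarioConfig(duration_s=1200,
                     wear_bouts=IntervalSet("wear", [[0, 400], [700, 1200]]),
                     seed=3)
rec, truth = generate_recording(cfg)

sqi, nonwear = detect_nonwear(rec, "refined")
print(nonwear.intervals - cfg.start_time)
# [[426.75 694.75]]   <- the 400-700 s bout, onset delayed ~27 s (the time
#                        skin temperature needs to cool below 32 °C)

res = EdaQualityProcessor().transform(rec.channels["EDA"], sqi)
print(res.segments.intervals - cfg.start_time)
# [[   0.    426.75]
#  [ 695.   1200.  ]]  <- retained EDA segments; off-body data excluded

ai = activity_index_abs(rec.channels["ACC"])
gb = GapBootstrap(ratios=[0.9, 0.6], n_iter=50, master_seed=1).fit(ai)
print(gb.summary_[["metric", "ratio", "bias", "sd"]].round(4).to_string(index=False))
# metric  ratio    bias     sd
#   mean    0.6 -0.0012 0.0131
#   mean    0.9 -0.0013 0.0042
#    p50    0.6 -0.0000 0.0000
#    p50    0.9 -0.0000 0.0000
#    p75    0.6  0.0292 0.0754
#    p75    0.9 -0.0000 0.0000
```

The bootstrap table reads: at 60 % data retention the mean activity index
wobbles with SD ≈ 0.013 a.u. around its gap-free value, roughly three times
the spread at 90 % retention — the quantitative basis for choosing a
data-retention threshold for windows of interest.

The same pipelines are scriptable from a shell:

```bash
wearqc simulate --seed 3 --out session/ --duration 1200
wearqc nonwear session/ --variant refined --out qc/
wearqc eda-process session/ --out qc/
wearqc bootstrap session/ --seed 1 --out qc/ --ratios 0.9,0.6
wearqc compliance-report sessions.csv --out report/
```

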