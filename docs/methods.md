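# Methods

This note documents the models, defaults, numerical choices and known
limitations behind `wearqc`. It describes what the code computes; every
number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## Data model

All timestamps are UTC epoch seconds. Fixed-rate channels are
`UniformSeries` (sample *i* at `start + i/rate`; a sample owns one sampling
period, so a series of *n* samples spans `n/rate` seconds). Interval sets
are sorted, pairwise-disjoint and half-open `[start, end)`; the half-open
convention prevents double counting at bout boundaries and makes the
on-body/non-wear partition of an SQI span exact. Inter-beat intervals (IBI)
are parsed and round-tripped as an opaque irregular series; nothing consumes
them because their derivation is a proprietary device algorithm.

The on-disk session dialect follows the public E4 export convention: header
row 1 = start epoch seconds, row 2 = sample rate (Hz), then one sample per
row; ACC is stored as raw integers in 1/64 g and converted to g on read, so
a write/read round trip reproduces ACC within 1/128 g and every other
channel exactly.

## Non-wear detection

Both detectors build three boolean SQIs (True = on-body) and combine them.
All threshold comparisons are inclusive (≥, and a closed temperature range).

Rolling statistics are **centered with shrinking edge windows**: the window
for index *i* over *w* samples is `[i − (w−1)//2, i + w//2]` clipped to the
series. Centered alignment avoids phase lag between the SQIs and the
signals; the SD uses the unbiased (n−1) denominator, and single-sample edge
windows yield 0. The implementation runs on cumulative sums after removing
the global mean (O(n), well-conditioned for offset signals such as
temperature); tests verify it against a brute-force per-window oracle.

Refined variant: x-axis 1-s SD ≥ 0.1 g, T ≥ 32 °C, EDA ≥ 0.03 μS. The ACC
and TEMP SQIs are reindexed to the 4-Hz EDA timestamps by **nearest sample
within one source sampling period; unmatched targets become False**
(absence of evidence is not on-body). The OR-combination is then smoothed
by a centered 1-minute rolling mean thresholded at ≥ 0.5 — a majority
filter that removes brief misdetections; an exact 0.5 tie counts as
on-body. Output granularity: 0.25 s.

Böttcher variant: Σ of three per-axis 10-s SDs ≥ 0.2 g, 25 ≤ T ≤ 40 °C,
EDA ≥ 0.05 μS; each SQI is aggregated per **tumbling 1-minute window
aligned to the earliest SQI start** (a trailing partial window is kept) by
the ≥ 1 % on-body-fraction rule, then OR-combined. Output granularity:
1 minute.

The thresholds are taken as given; no per-climate or per-device adaptation
is implemented, and generalisation of the fixed thresholds to other
climates or devices is a known limitation.

## EDA artifact processing

The composite validity SQI requires (a) noise amplitude below
`noise_threshold_us`, (b) value inside the plausible range
`[0.01, 100] μS`, (c) wrist on-body (reindexed as above). The noise
estimator — the purple-line quantity in the pipeline's diagnostic plots —
is a deliberate, simple stand-in since no canonical formula exists:
residual against a centered 1-s rolling mean, then a centered 2-s rolling
mean of the absolute residual. The **baseline window is forced to an odd
sample count** so it is symmetric and linear trends cancel exactly in the
residual (a 4-sample window would alias a ramp into a constant offset of
slope/2 per sample). `noise_threshold_us` defaults to 0.1 μS and is
explicitly tunable; it was not derived from data.

Processing: invalid runs ≤ `max_interp_gap_s` (default 5 s, tunable, well
under the segment floor) with valid samples on both sides are filled by
linear interpolation between the flanking samples and flagged; leading and
trailing invalid runs have no flank and are dropped, never extrapolated.
Surviving contiguous segments shorter than 60 s are excluded; a segment of
exactly 60 s is kept (the exclusion rule is "shorter than"). Retained
non-interpolated samples always equal their source values (no fabrication),
and reprocessing the output with its own retained mask is the identity.
Only run *duration* gates interpolation; run frequency affects retention
implicitly through the segment floor.

## Activity index

Per tumbling epoch aligned to the series start (partial trailing epoch
discarded): `AI = sqrt(max(mean_axes(var_axis − σ²_noise), 0))` with
unbiased per-axis variances. "Absolute" means the variance is not divided
by the systematic noise variance; `σ²_noise` defaults to 0 and is exposed
as a parameter. Closed-form checks: a single-axis sinusoid of amplitude *a*
gives `AI → a/√6`; i.i.d. Gaussian noise of SD σ on all axes gives
`AI → σ`.

## Gap bootstrap

Gap induction removes **exactly** `round((1 − r)·n)` samples — an invariant
of the construction, not a Bernoulli expectation — so a target retention
ratio holds in every iteration. Strategies: one block; `n_blocks`
near-equal blocks (lengths differ by at most one sample); or block lengths
drawn with replacement from an empirical non-wear bout-length list, the
last block truncated to hit the exact count. Blocks are placed uniformly at
random without overlap by rejection sampling (longest first, at least one
sample of separation so each block is a distinct run); if 10 000 attempts
fail, an error advises fewer or shorter blocks — dense packings are
legitimately infeasible for this placement scheme.

Seeding: each (ratio, iteration) cell draws from
`SeedSequence([master_seed, ratio_index, iteration])`, so results are
bit-reproducible and independent of evaluation order. Quantiles use linear
interpolation between order statistics. Metrics are computed on the
retained samples only; imputation variants are out of scope.

A numerical subtlety verified by the tests: block placement covers indices
near the series edges with lower probability, so for one fixed data
realisation the bootstrapped mean carries a small deterministic
edge-coverage offset; it vanishes in expectation over data realisations,
which is how the unbiasedness property is asserted.

## Synthetic recordings

The generator emulates what wrist removal does to each channel, with
defaults chosen as typical of wrist physiology: skin temperature relaxes
toward ambient (24 °C) from skin temperature (34 °C) with a first-order
time constant of 120 s, integrated exactly per sample via a one-pole
filter; EDA collapses from a 1 μS tonic level (plus Poisson
skin-conductance responses, 2/min, asymmetric 1-s-rise/4-s-decay bumps of
0.1–1 μS) to 0.01 μS; the accelerometer is gravity plus 0.004 g sensor
noise, with 0.5–8 Hz band-limited motion bursts of 0.3 g SD covering ~30 %
of wear time in 10-s blocks; BVP is a plain sinusoid placeholder with no
waveform realism. Wear boundaries are cross-faded linearly over 10 s so
detectors face ramps, not steps. Everything derives from one seed;
identical configurations are bit-identical.

Consequences the tests rely on: off-body EDA settles below 0.03 μS and
temperature below 32 °C after ≈ 5 time constants, so both sides of the
refined thresholds are exercised; during quiet wear only the TEMP and EDA
SQIs are on-body (the OR keeps the combined SQI correct). The detector's
onset lag on a removal is physical, not algorithmic: ≈ 27 s for the
temperature to cool below 32 °C (120·ln(10/8)). A 10-minute bout is
therefore recovered with sample-level sensitivity/specificity ≥ 0.9 and
IoU ≥ 0.8, while bouts much below ~2 min shrink toward the detection
floor. What passing tests do **not** show: robustness to real-world
artifacts (humidity, electrode polarisation, loose straps), inter-subject
variation of skin temperature/EDA levels, or device clock drift — the
generator has none of these.

The event-log generator places `prompts_per_day` questionnaire prompts
uniformly in 08:00–22:00 of each day and answers each independently with
probability `answer_prob` within ten minutes, which keeps prompt/answer
pairs within one local day for the interaction-rate computation.

## Compliance analytics

Sessions merge consecutive sample timestamps spaced ≤ `session_gap_s`
(default 60 s — separates genuine disconnections from jitter) and extend by
one nominal sample period. Wear time is apportioned to local days by
clipping at midnight, conserving total duration exactly; exactly 8 h counts
as compliant (the boundary case is unstated in common usage; inclusive is
chosen and documented). Local days use a fixed UTC offset with no DST
handling — adequate for single-region studies. Interaction rates
denominate by prompts, and a day with zero prompts is reported as missing
rather than 0. Event-log checks: overlapping `[start, end)` spans of the
same kind (point events without an end time cannot overlap), future-dated
events, and events backdated beyond 14 days (exactly 14 days is allowed).

## Problem sizes and scope of the test suite

The suite and the acceptance script run on synthetic material sized for
desk-scale verification: recordings of 10 min–2 h (a 2-h recording at
native rates is ~230 k ACC samples), bootstrap references of 1 200–3 600
samples with up to 500 iterations per retention ratio, and parameter sweeps
of 17–61 points. These sizes make every assertion exact or tightly seeded
while keeping the whole suite in the seconds range; the pipelines
themselves are O(n) in the recording length and run unchanged on weeks of
data.

## Design notes

The transform-shaped operations are exposed as scikit-learn-style estimator
classes (`NonwearDetector`, `EdaQualityProcessor`, `ActivityIndexABS`,
`GapBootstrap`) with `get_params`/`set_params`, validation on `fit`, and
trailing-underscore result attributes; module-level functions are thin
wrappers. Inputs are domain time-series objects rather than feature
matrices, so the estimators follow the protocol but are not drop-in
`Pipeline` steps. The CLI (`wearqc`) is a thin layer over these functions
with exit codes 0 (success), 1 (validation/I-O error), 2 (usage), and all
randomness flows from an explicit `--seed`.
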