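# Methods

This note documents the models, numerical choices and known limitations of
`somnalert`. It complements the API docstrings; nothing here is a result —
every number the package claims is computed by the test suite or by
`scripts/acceptance.py` at run time.

## The problem setting

Longitudinal in-home sleep monitoring of older adults produces, per
participant, hundreds of nightly recordings from an under-mattress sensor
and weekly self-rated health scores (EQ-VAS, a 0–100 visual analogue
scale). Two questions drive the pipeline: *which* nightly sleep parameter
tracks self-rated health best, and *how* can structural changes in the most
informative parameter (large body movements in bed, "toss-and-turns") be
detected automatically?

## Synthetic cohort generator (`synth`)

No public dataset of this kind exists, so the generator is a first-class
component: it emits data with the statistical structure the downstream
stages assume, plus ground-truth labels for power experiments.

**Participants.** Age ~ Normal(87, 7) truncated to [70, 101]; 67% female;
EQ-VAS intercept ~ Normal(75, σ_intercept) with σ_intercept = 8 by default;
a personal toss-and-turn base rate `r_i = r0 · LogNormal(−σ²/2, σ)` with
unit mean, σ = 0.6 between participants. The lognormal dispersion
reproduces the heavily right-skewed pooled distribution of nightly counts
(pooled SD comparable to the mean).

**Hypnograms.** A semi-Markov chain over {awake-in-bed, light, deep, REM,
out-of-bed} with exponential dwell times and a fixed transition matrix.
No published transition structure exists for this population and device,
so dwell means and transitions were tuned once so that long-run nightly
means land on a realistic elderly profile: total recording ≈ 8.8 h, sleep
efficiency ≈ 0.84, light/deep/REM ≈ 15.5/4.6/6.6 ks, onset delay ≈ 1.4 ks,
≈ 3 bed exits and ≈ 2.2 awakenings per night. Durations are integer
multiples of the 30 s epoch, so all conservation identities hold exactly.

**Toss-and-turn events.** A Poisson process at `r_i` events per 30-minute
bin, thinned to zero while out of bed, and multiplied by `m ≥ 1` while a
health episode is active. Events are allowed during awake-in-bed epochs
(wakeful restlessness is still restlessness). The calm-state default is
r0 = 2.77 per bin: with ≈ 17.1 in-bed bins per night and the default
episode process (below) occupying ≈ 8.7% of nights at m = 3.5, the pooled
nightly mean lands at ≈ 57.6 events — the pooled cohort scale, which
includes episodes, is the calibration anchor.

**Health episodes.** Per night, a new episode starts with probability
0.01 (when none is active), lasts 5–14 nights, multiplies the toss rate by
3.5 and subtracts 20 EQ-VAS points. These stand in for real incidents
(flu, urinary tract infection, heart failure …); the frequency corresponds
to a few detectable episodes per participant-year.

**Reports.** Weekly per participant (±1 day jitter),
`EQVAS = intercept_i + β·z(c) + age/sex terms + Normal(0, 10) − decrement`,
clamped to [0, 100], where `c` is the toss count of the single night ending
on the report's morning and z() standardizes against the pooled simulated
counts. Using the single preceding night (rather than a weekly average)
makes the mixed model's generative assumption exact for recovery tests.
Default β = −2.5 per SD; age/sex coefficients default to 0 so the pooled
EQ-VAS mean stays at 75.

**Heart data.** Nightly mean heart/respiration rates are participant
baselines (≈ 61.8 bpm / 14.6 brpm) with small nightly jitter, slightly
elevated during episodes. Each night carries a 10-minute interbeat-interval
sample: RR(t) = RR0 + A_LF sin(2π·0.10t) + A_HF sin(2π·0.25t) + noise. The
HF amplitude is pre-boosted relative to the target band ratio because the
~1 Hz tachogram low-passes 0.25 Hz more than 0.10 Hz under linear
resampling; the normalized extracted powers land near LF 44 / HF 56.

**Imperfections.** Naps (p = 0.05), exact duplicate uploads (p = 0.02),
short fragments (p = 0.03: either the night truncated below 5 h or a
separate morning re-entry > 2 h after rising), and whole nights missing
completely at random (p = 0.22, emulating connectivity loss — the drop
decision never consults health state, so missingness is MCAR by
construction). An optional AR(1) night-effect knob exists for sensitivity
analyses but defaults to off: between-night autocorrelation of the rate is
not characterized for this setting, and the default keeps per-bin counts
exactly Poisson within participant (which the χ² null calibration relies
on).

**Granularities.** Besides the full event-level `simulate_dataset`, two
summary-level paths share the same generative parameters:
`simulate_matched_cohort` (one row per weekly report with the 20 nightly
parameters, only the toss count carrying signal) for ranking-recovery
experiments, and `simulate_restlessness_weeks` (per-bin counts per night)
for χ² calibration/power experiments. Event-level simulation of hundreds
of cohorts is unnecessary for these statistical questions and would
dominate runtime; the summary paths are the package's chosen experiment
scale. In the recovery experiments the between-participant rate dispersion
is set to 0 so that "slope −2.5 per SD" refers to night-to-night (Poisson)
variation — with the default dispersion most of the pooled variance is
between participants, where the slope is absorbed by the random intercept
and the per-SD calibration would not mean what it says.

**What passing tests do not show.** The generator emits ground-truth
staging and event streams; it cannot validate the device's proprietary
signal extraction, staging accuracy under heavy movement, movement-related
sleep disorders, or non-MCAR missingness. Results on synthetic data bound
what the pipeline can recover when its assumptions hold, not device
accuracy.

## Preprocessing (`preprocess`)

Rules apply in a fixed order: (1) night window — the recording must start
in [18:00 of day d, 11:00 of day d+1) and end by 11:00 of day d+1, and the
night slot is labeled d+1 (the morning date); (2) duration strictly
greater than 5 h; (3) exact-duplicate removal (identical participant,
start, end), with near-duplicates (> 90% of the shorter overlapped)
removed separately — real exports contain re-uploads; (4) longest
recording per slot, ties broken by earlier start for determinism. Segment
assembly merges bed-activity runs separated by ≤ 2 h of out-of-bed time
(explicit out-of-bed epochs or recording holes). Exclusions are tallied
per rule and conserved against the input count.

Standardization is pooled across participants (a single z-scale for the
cohort-level models), sample SD with ddof = 1; constant columns become
zeros and are flagged. Whether per-participant scaling would change the
ranking is an open sensitivity question; pooled was chosen because the
mixed models compare participants on one scale.

Report matching: the night ending on the report's calendar morning; an
optional 1-day-back fallback exists (off by default) for reports filed
before the morning's data sync. Unmatched reports are counted, never
imputed.

## Feature extraction (`features`)

Durations are epoch run-lengths; identities `in_bed + out_of_bed = total`,
`asleep = light + deep + REM`, `in_bed = asleep + awake` hold exactly.
Sleep efficiency and the stage percentages use the *total* recording
duration as denominator, so the three percentages sum exactly to the
efficiency. Sleep onset delay is the time to the first sleep epoch; an
awakening is an awake-in-bed run after onset of at least one epoch (30 s;
configurable — no standard minimum exists for this sensor class). An
all-awake night yields efficiency 0 and a flag, not an error.

HRV: the interbeat tachogram is linearly resampled to 4 Hz, mean-detrended,
and a periodogram integrated over 0.04–0.15 Hz (LF) and 0.15–0.40 Hz (HF);
only the normalized quantities 100·band/(LF+HF) are exposed, which
minimizes sensitivity to the (unknown) device-internal method. Series
under 5 minutes yield missing values that propagate out of the model rows.

## Mixed-model ranking (`ranking`)

One random-intercept LMM per parameter, REML by default (ML by flag).
The likelihood is profiled over θ = σ²_u/σ²_e: for fixed θ,
`W = (I + θZZᵀ)⁻¹` is block-diagonal with per-group closed forms, GLS gives
β̂(θ) and σ̂²_e(θ), and the profiled criterion
`Σ_g log(1+θn_g) + log|XᵀWX| + (n−p)(1+log 2πσ̂²)` is minimized by bounded
Brent search over log θ (xatol 1e−12), with the θ = 0 boundary checked
explicitly. Standard errors are `σ̂²_e (XᵀWX)⁻¹`.

Satterthwaite df = 2·Var(β̂₁)²/Var[Var(β̂₁)]; the denominator combines the
gradient of Var(β̂₁) w.r.t. (σ²_u, σ²_e) (central differences, relative
step 1e−5) with the asymptotic covariance 2H⁻¹ of the variance estimates,
H the Hessian of the REML deviance by Richardson-extrapolated central
differences (base relative steps 1e−2 and 5e−3 — smaller steps hit
deviance round-off before truncation error matters). The quadratic form is
invariant to the variance parametrization, so values agree with
lme4/lmerTest to ≈ 1e−6 relative on interior fits. At the σ²_u = 0
boundary the model is OLS and df = n − rank(X) exactly; non-finite
curvature falls back to the residual df n − rank(X) − G + 1, flagged.

Ranking is by |t| with two-sided p from the t distribution; Holm's
step-down correction runs over the tested (non-missing) hypotheses only,
and significance is declared at α = 0.05. Sex is coded 0/1, age enters
untransformed, and both covariates enter every model; constant covariates
(e.g. single-sex subcohorts) are dropped per model rather than erroring.
Spearman correlations use midranks with the t-approximation p-value
(scipy); the data-loss bias check pairs a Spearman test of per-participant
missing fraction vs mean EQ-VAS with a Welch two-sample t-test of included
vs excluded participants.

## Restlessness statistic (`anomaly`)

Per participant and 7-night window (aligned to the first measured night,
not calendar weeks — determinism independent of enrollment date), toss
events are counted in 30-minute bins restricted to in-bed time (bins under
50% in-bed coverage are dropped; out-of-bed periods must not masquerade as
quiet bins). λ̂ is the bin-count mean. The default statistic is the
histogram goodness-of-fit χ² of observed count frequencies f_o against
n·Poisson(k; λ̂), with the upper tail pooled until every pooled cell
expects ≥ 1 observation and dof = cells − 2 (reported, not used for
alerting). The per-bin dispersion variant Σ(n_i − λ̂)²/λ̂ is available
behind a flag for sensitivity analysis; the histogram form is the default
because it responds to any distributional distortion, not only variance
inflation. All-zero weeks define χ² = 0 (flagged); weeks with fewer than
100 measured bins emit undefined markers rather than deceptively small
values. Alerts fire on raw χ² > 1000; under calm defaults this is
conservative (the null statistic lives at χ² ~ dof), and in severe
mixed-rate weeks the statistic can reach astronomically large values
because low-count cells far from λ̂ have tiny expectations — harmless for
thresholding, and exactly the weeks an alert is wanted.

Screening rules mirror manual case review: nights above 200 events, local
peaks above 3× the trailing 14-night moving average, and sustained trends
where the centered 14-night moving average exceeds the baseline (median of
the first 28 measured nights) by 50%. The weekly association with
self-rated health is the pooled Spearman correlation between log χ² and
the week's mean EQ-VAS.

## Problem sizes and tolerances

The test suite runs the statistical experiments at desk scale chosen once:
1000 event-level nights for conservation identities; 20 oracle datasets
(5–15 groups × 3–10 observations) for the lmerTest comparison at 1e−4
relative; 100 summary-level cohorts (40 participants × 26 reports) for
ranking recovery and the permuted-response null; 10,000 null weeks × 168
bins per λ ∈ {0.5, 2, 5} for χ² calibration (exceedance of an
independently simulated 95th percentile within 5% ± 1%); 500 episode weeks
per multiplier for power monotonicity; and 100 cohorts of 15 participants
× 12 weeks for the direction of the χ²/EQ-VAS association.
`scripts/acceptance.py` re-runs the same experiments (some at reduced
replicate counts) from a single command-line seed.

## Known limitations

- The hypnogram model has no inter-night structure (no weekday effects,
  no insomnia phenotypes) and exponential dwell times; it matches means,
  not full sojourn distributions.
- The toss process is conditionally Poisson; real movement data may be
  self-exciting (bursts), which would inflate the χ² null. The alert
  threshold of 1000 is far above any such inflation at weekly bin counts.
- Episode effects are step functions; real deterioration often ramps.
  Trend detection compensates partially.
- The EQ-VAS link is linear in a standardized count with a single global
  slope; no nonlinearity, lag structure or participant-specific slopes.
- Only random intercepts are modeled (no random slopes, no crossed
  effects, no non-Gaussian responses), matching the analysis design.
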