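# Methods

This note documents the models, conventions and numerical choices behind
`tmsemg`: what the pipeline assumes, what the synthetic-data generator does
and does not emulate, and where genuinely open design points were settled.

## Measurement pipeline

**Filtering.** Every trace is filtered once, before any epoch extraction,
with a zero-lag 4th-order Butterworth band-pass (13–500 Hz defaults). The
zero-lag property comes from forward–backward application
(`scipy.signal.sosfiltfilt`), so the effective magnitude response is the
squared single-pass response and the net phase shift is zero. At 1 kHz
sampling a 500 Hz low-pass sits exactly at Nyquist, where the digital design
is singular; the cutoff is clamped to 0.99× Nyquist and a warning logged.
Traces must exceed the filter's padding length (27 samples at order 4).

**Windows.** The pre-stimulus epoch is `[stim − 100 ms, stim)` and the
post-stimulus epoch `(stim, stim + 100 ms]`; the stimulus-artifact sample
itself belongs to neither, and no artifact interpolation is performed. For
paired-pulse trials the pre-stimulus epoch precedes the first (conditioning)
stimulus, and the conditioning detection window is truncated at the second
stimulus so the two windows are always disjoint.

**Trial gating.** A trial is accepted when it was delivered inside the
valid range of motion and its pre-stimulus rmsEMG falls within
target ± tolerance (default 5% ± 2%) of the session's maximal isometric
rmsEMG. Bounds are inclusive (membership at exactly 3% or 7% accepts); a
1e-12 guard keeps the stated decimal bounds inclusive under binary
floating point. The first 10 accepted trials per outcome, in delivery
order, enter analysis; blocks with fewer are flagged incomplete and skipped
with a log entry.

**Normalization.** The session normalizer is the largest rmsEMG across the
session's isometric MVC trials, measured on the filtered trace with 50 ms
trimmed from each end: the forward–backward filter's edge transients
otherwise leak into the estimate and bias it upward by up to ~3% (max over
three trials), which would in turn bias every normalized outcome low.

**Averaging order.** By default the 10 accepted traces are ensemble-averaged
and one PPA measured on the average (`average_then_measure`). The
alternative reading — measure 10 per-trial PPAs and average them — is
available as `RunConfig(averaging="measure_then_average")`. The two differ
systematically: per-trial PPAs include a positive noise bias (max − min of
a noisy window), which averaging-first suppresses by √10. Averaging-first
is the default because the measurement chain is described trace-first.

**LICI detectability.** A paired-pulse MEP counts as *distinct* when its
PPA exceeds 3× the same trace's pre-stimulus peak-to-peak amplitude. In
average-then-measure mode this rule is applied to the ensemble-averaged
trace, and a failed test MEP excludes the session's LICI outcome (logged).
The per-trial version of the rule is retained for measure-then-average
mode, where a session is excluded when more than half of its trials lack a
detectable test MEP. The averaged-trace placement matters quantitatively:
at the study's own magnitudes (normalized MEP ≈ 1.2, background at 5% of
maximal rmsEMG) a genuine LICI test response sits almost exactly at 3× the
*single-trial* noise peak-to-peak, so a per-trial rule would misclassify
roughly half of genuine responses, whereas on the 10-trial average the
margin is ~9× for signal versus ~1× for noise-only windows.

**Responder screening.** A subject whose single-pulse averaged PPAs never
reach the motor-threshold criterion (0.5 mV) in any block is dropped with a
"no MEP elicited" log entry, mirroring cohort screening during threshold
determination. Set `RunConfig(amt_threshold_mv=0)` to disable — the
parameter-recovery experiments do, see below.

**Active motor threshold.** Given descending-intensity blocks of 10 PPAs,
AMT is the *lowest* tested intensity whose block has ≥5 PPAs ≥ 0.5 mV.
Scanning all supplied blocks (rather than stopping at the first failure)
makes the result deterministic and independent of delivery order. Hotspot
selection takes the site with the largest mean of three PPAs, ties broken
toward the first-visited site and logged.

## Reliability battery

Outcomes are assessed over consecutive session pairs (1→2, 2→3) with
pairwise complete cases: a subject missing one session drops out of the
pairs that touch it only. Per pair: ICC(3,1) (two-way consistency,
single-measure, from the subjects × sessions ANOVA mean squares), typical
error TE = SD(differences)/√2, and CV% = 100·(exp(TE_ln) − 1) computed on
natural-log scores (scale-invariant; subjects with non-positive values are
dropped from CV% with a warning). Point estimates per outcome are the
arithmetic means of the two pairs; MDC95 = TE × 1.96 × √2 uses the mean TE.
SWC = 0.2 × SD of subject means across available sessions, and
%SWC = 100 × SWC / grand mean of all available values — the denominator is
a documented choice, as is pooling the between-subject SD across sessions.
An outcome is *sensitive* when CV% < %SWC.

Confidence intervals are reported but never drive any decision: TE CIs via
chi-square limits on the difference-score SD, ICC CIs via the exact F
method for the consistency ICC, CV% CIs by back-transforming the log-scale
TE limits. The two pairwise CIs are reported as-is; no attempt is made to
combine them into one interval for the mean, since no standard construction
exists for that average. Display rounding is two decimals, half-up; all
internal computation is full precision.

ICC banding: < .40 poor, .40–.59 fair, .60–.74 good, ≥ .75 excellent.

## Synthetic study generator

The generator exists so that every downstream stage has a testable ground
truth. Its defaults are the study conditions the pipeline targets: 10
trials per outcome (up to 20 deliveries until 10 are accepted), 3 MVC
trials per session, 1 kHz sampling, background at 5% of a 0.5 mV maximal
rmsEMG with SD 0.9 percentage points (most trials inside the 3–7% gate,
matching a realized pre-stimulus level of ~4.9% ± 0.9%).

**Amplitude model.** The injected MEP amplitude for a trial is

```
amp = exp(mu + b_subject + s_session + eps_trial) · g(intensity) · c
```

with `mu = ln 0.6` (log-mV), `b ~ N(0, 0.45²)`, `s ~ N(0, 0.18²)`,
`eps ~ N(0, 0.42²)`, a logistic stimulus–response gain
`g(x) = L(x)/L(120)`, `L(x) = 1/(1+exp(−(x−130)/40))` (unit gain at the
120 %AMT reference, giving normalized session means ≈ 1.0–2.0 across
110–170 %AMT), and a conditioning factor `c` for paired-pulse trials
(SICI 0.7, ICF 1.2, LICI 0.6). Conditioning factors carry their own
subject- and session-level log-normal heterogeneity (SD 0.25 and 0.10):
without it the shared amplitude components would cancel in every ratio and
ratio outcomes would have essentially zero between-subject variance, i.e.
ICC ≈ 0, which is not the regime the pipeline is meant to be exercised in.
The defaults give a closed-form single-pulse session ICC of 0.80 and CV% of
about 25%.

**Closed-form expectations.** For the session-mean outcome on the log
scale, `expected_icc = σ_b²/(σ_b² + σ_s² + σ_e²/n)`; for ratio outcomes the
amplitude components cancel and the factor heterogeneity takes their place
with twice the trial noise, `σ_bf²/(σ_bf² + σ_sf² + 2σ_e²/n)`. These are
log-scale quantities, so recovery experiments log-transform the outcome
table before the reliability battery.

**Waveforms.** The MEP template is one biphasic sine cycle, Hann-tapered
and renormalized so its sampled peak-to-peak equals the drawn amplitude
exactly, placed at a 25 ms latency with 18 ms duration (conventions, not
measured values — the muscle's MEP latency/duration are not parameterized
anywhere authoritative). The taper suppresses spectral side-lobes below the
analysis band; without it the zero-lag filter spreads enough MEP energy
*backward* into the pre-stimulus epoch to perturb gating for large MEPs.
Background noise is Gaussian, synthesized in the frequency domain on a flat
35–250 Hz band — inside the flat region of the 13–500 Hz analysis passband —
and scaled so the raw pre-stimulus epoch rms equals the drawn target
exactly. Because the noise lives where the filter is flat, the pipeline's
own filtering pass changes the calibrated rms by <0.1%, keeping generator
and pipeline gating decisions consistent. MVC traces are 1 s of the same
noise calibrated on the 50 ms edge-trimmed interior window the normalizer
measures.

**Delivery gating.** The generator's accept/repeat decision uses the
realized pre-stimulus fraction of the *filtered* trace — the quantity the
experimenter's rmsEMG feedback display and the offline analysis both see —
so ground-truth acceptance labels agree with pipeline gating rather than
flipping for near-boundary trials. Both the drawn calibration fraction and
the realized fraction are recorded per trial.

**Cohort features.** Per subject-session-mode, the LICI second MEP is
absent with probability `p_lici_missing` (default 0.1; the conditioning MEP
is still present). Configured non-responders have all amplitudes scaled by
0.05 (far below 0.5 mV at every intensity). `missing_sessions` removes
whole subject-sessions (a participant who cannot be measured in session 3).
`n_forced_rejects` forces the first deliveries of each block out of window
or out of range-of-motion so gating always has work to do. The true motor
threshold is drawn per subject (48 ± 8 %MSO, clipped to 25–85).

**Reproducibility.** One global seed expands into per-subject, per-session
and per-trial substreams by hashing the (seed, subject, session, mode,
test-type, trial) coordinates through `numpy.random.SeedSequence`. Any
trial regenerates identically in isolation, and a block's content does not
depend on which other modes or test types are simulated.

**Known mismatches with real data.** The normalizer (maximal isometric
rmsEMG) is constant across subjects and sessions — real MVC output varies,
which would add between- and within-subject variance that the closed-form
ICC does not include; this is deliberate, so the closed form stays exact.
The background is stationary Gaussian (no bursting, motion artifact or
electrode drift), MEP shape is identical across subjects and intensities
(no latency jitter, no shape change with contraction mode), trial noise is
uncorrelated across trials, and stimulus artifacts are single clean
samples. Passing tests therefore demonstrate correctness of the analysis
arithmetic and bookkeeping under the stated model — not robustness to
artifact structure that real sEMG may contain. The amplitude model also
leaves amplitude-at-%AMT statistically unanchored to the subject's
threshold: a subject can draw MEPs below 0.5 mV at 120 %AMT while still
being a "responder". Recovery experiments therefore disable responder
screening, which would otherwise truncate the subject distribution that the
closed-form ICC assumes (at n = 200 the truncation depresses recovered ICC
by about 0.10).

## Numerical notes and exactness limits

- With all variance terms zero and no background, SICI and ICF come out
  equal to their configured factors to ~1e-15 (filter gain cancels in the
  ratio). LICI is exact only to ~5e-4 relative: the conditioning MEP's
  filtered tail crosses into the test window 100 ms later. Reliability on
  ratio outcomes is exactly perfect (TE = 0); on normalized amplitudes it
  is zero to ~0.1% of the outcome scale — the per-session MVC normalizer is
  itself an rms estimate with that much realization noise.
- The band-pass shrinks the template's peak-to-peak by a fixed factor
  (~0.8% for the default template; `pipeline.template_measurement_gain`
  computes it), so pipeline outcomes track injected ground truth times this
  gain. Ratios and every reliability statistic are invariant to it.
- Degenerate inputs are signalled, not silently absorbed: zero total
  variance makes the ICC undefined (raised as a distinct error), empty rms
  windows, non-positive normalizers, out-of-order stimuli and incomplete
  AMT blocks all raise typed errors.

## Problem sizes used in the shipped experiments

The recovery experiments run 20 studies of 200 subjects × 3 sessions × 10
trials (single isometric 120 %AMT block) across expected-ICC regimes
{0.5, 0.75, 0.9}; the acceptance script uses 5 replicates of 100 subjects
at the 0.75 regime plus a 10-subject, 3-mode cohort for the full battery.
These sizes put the Monte-Carlo error of the mean recovered ICC well below
the ±0.03 agreement band while keeping a full run in the minutes range on
one CPU.
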