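# Methods

This note documents the models, conventions and numerical choices behind the
`gonogo` package, and what its synthetic-data tests do and do not establish
about real recordings.

## Timing conventions

All event times live on one session clock, in seconds; trial-relative times
subtract the stimulus onset. Every analysis window is half-open,
`[start, end)`, so counts over a partition of an interval sum exactly to the
count over the whole interval and no event is double-counted. Relative to
stimulus onset, the waiting period is `[0, 0.5)` s, the answer period
`[0.5, 3.0)` s, and the "early waiting period" `[0, 0.3)` s. Whether window
boundaries are inclusive is a genuine convention choice; half-open was chosen
and is applied uniformly (spike binning, lick classification, PSTHs,
photometry windows).

## Behavioral metrics

Outcomes follow the standard Go/No-Go mapping (answer-period lick on
GO → Hit, else Miss; on NOGO → FA, else CR); waiting-period licks set a flag
but never alter the outcome, because the task neither rewards nor punishes
them. Rates are simple proportions within GO and NOGO trials.

**d′ clipping.** d′ = Φ⁻¹(hit) − Φ⁻¹(fa) diverges at 0% or 100% rates. Each
rate is clipped to `[1/(2n), 1 − 1/(2n)]` of its own trial count before the
inverse-normal transform. This log-linear-style correction keeps d′ finite,
makes the ceiling depend on the evidence (more trials → larger attainable
|d′|), and reduces to the raw formula elsewhere. How extreme rates should be
handled is underdetermined by the printed formulas; this is the package's
documented choice.

**First-lick latency** on No-Go trials is the time of the first lick within
1 s of stimulus onset (waiting-period licks count); trials without such a
lick carry exactly the 1-s cap, and the session statistic is the median.
Because of the cap the median is well defined even in sessions with few
licks.

**Block-position Δ-metrics.** Laser Δ-metrics (ON − OFF) are recomputed
within the first/middle/last third of the session's blocks and within the
first-10 vs last-10 trials of each block. With the canonical 12-block,
20-trial design this is the 4/4/4 split; other designs are partitioned by
thirds and flagged `generalized`. Cells with too few trials yield flagged
NaNs, never silent ones.

## Spike analyses

PSTHs use 25-ms bins and report raw trial-averaged rates; Gaussian smoothing
(σ = 1 bin, truncated at 3σ) exists only in `smooth_psth_for_display` and is
never applied on an analysis path.

**Responsiveness screen**: one-sided Wilcoxon signed-rank of per-trial
waiting-window rates against the 0.5-s pre-stimulus baseline, paired within
trial. Zero differences are dropped (standard convention); the exact null
distribution is used for n ≤ 25 without ties, otherwise the normal
approximation with tie and continuity correction. On discrete Poisson counts
the achieved level sits near the nominal 5% (the type-I calibration test
verifies this at ±3 binomial SE).

**Optogenetic tagging** compares per-pulse firing *rates* in `[-1, 0)` s vs
`[0, 6)` ms around laser onset with a one-sided paired *t* test. Raw counts
over windows that differ in length by a factor of ~167 would build a null
bias into the comparison, so counts are normalized by window length; this is
a deliberate reading of a protocol that names "spike number". The waveform
gate (Pearson r of mean spontaneous vs laser-evoked waveform > 0.95) is
applied after the latency test; failing either gate leaves the unit
untagged, with the failing gate recorded.

**Laser rate-modulation test**: waiting-window rates of laser-OFF vs
laser-ON trials are compared per outcome class (CR, FA, Hit) with a
*two-sided rank-sum* test, and a unit is flagged if any class has p < 0.05.
A paired signed-rank test is sometimes named for this comparison, but OFF
and ON are distinct trials of generally unequal number with no defined
pairing, so the unpaired analogue is the defensible test. Classes with < 3
trials in either condition yield missing p values. Under a null with three
independent tests the flag rate is ≈ 1 − 0.95³ ≈ 14%, which is a property of
the screening rule, not a bug.

## Choice preference

The ROC area between FA-trial and CR-trial responses is computed by the
Mann–Whitney rank identity with mid-ranks for ties, which equals the
all-pairs statistic `mean(1(x_fa > x_cr) + 0.5·1(x_fa = x_cr))` exactly —
ties matter because spike counts in 0.5-s windows tie constantly. Choice
preference is evaluated as `(2U − n_pairs)/n_pairs` so that swapping the
class labels negates it exactly in floating point.

Trial filtering: only No-Go trials without a waiting-period lick enter, to
limit lick-movement contamination, and a session contributes only with ≥ 10
such FA trials. Ineligible sessions raise a typed error carrying the
eligibility record, so pipelines log exclusions instead of silently dropping
data.

**Binned correlation**: neurons are pooled by session CR rate into
10-percentage-point bins that are half-open on the left — a CR rate of
exactly 50% belongs to (40%, 50%] — and Pearson's r (two-sided t test,
df = bins − 2) is computed between bin centers (25%, 35%, …) and per-bin
mean preference. At least 3 occupied bins are required. A per-neuron
(unbinned) correlation can be computed from the same inputs but is not the
default, since the bin-mean version is the one the n-per-bin reporting
convention implies.

## Photometry

ΔF/F uses a per-trial baseline: F₀ is the mean fluorescence over the 1 s
before that trial's onset, making ΔF/F exactly invariant to a global gain on
the raw trace. Trials with non-positive F₀ are recorded as bad (NaN rows),
not fatal.

**Latency**: the trial-averaged ΔF/F curve is binned at 25 ms, smoothed with
robust local quadratic regression ("rloess": tricube distance weights,
quadratic local fit over a 5-bin span, 5 bisquare reweighting iterations at
6× the median absolute residual), and compared against a threshold of
3 SD above the mean of the smoothed `[-0.5, 0)` s baseline bins. The latency
is the left edge of the first waiting-period bin strictly above threshold;
curves that never cross return an explicit missing value, and a first
crossing in the answer period is reported separately, never as a
waiting-period latency. Numerical details that were open: the baseline SD is
taken on the *smoothed* binned curve (the same object the threshold is
compared against, ddof = 1); the span default is 5 bins and is exposed in
the API; when bisquare reweighting leaves fewer than 3 usable points in a
window the local fit degrades to linear/constant rather than falling back to
the raw (possibly outlying) point; and a vanishing median residual falls
back to the mean absolute residual so lone outliers still lose weight. The
loess implementation is written here because the robust *quadratic* variant
(which reproduces an exactly quadratic curve to machine precision) is not
available in the installed stack.

Latency is computed per session on the trial-averaged curve, not on
session-averaged grand means.

## Motion-energy control

Motion energy is the element-wise |intensity difference| of consecutive
frames; PCA (pixels as variables) is computed by SVD of the mean-centered
frame × pixel matrix, components signed so their largest-magnitude loading
is positive (deterministic output). Energy frame k is timestamped midway
between its two source frames. The per-trial ROC statistic is the *mean* PC
score over waiting-period frames (an integral would differ only by a
constant factor and leave the rank-based ROC unchanged unless frame counts
differ across trials; the mean is robust to that).

## Synthetic-data generator

The generator produces the statistical structure the analyses assume, at the
study's task geometry: 0.5-s waiting / 2.5-s answer periods, i.i.d. Go/No-Go
interleaving (p_go = 0.5), alternating 20-trial laser blocks always starting
OFF (a fixed convention for testability), 150-pulse/5-s-ITI tagging
protocol, 200-Hz photometry, 30-Hz face video. Defaults represent a trained
animal: hit rate 0.9, FA rate 0.38, waiting-lick probability 0.2, first-lick
latency log-normal (median 0.25 s, log-sd 0.5, truncated to the answer
period) — positive and right-skewed like real lick data.

Spiking is an inhomogeneous Poisson process: baseline 5 Hz everywhere,
plus an evoked 20 Hz during `[onset_latency, 0.5)` s of No-Go trials,
multiplied by `choice_gain` on FA trials (gain 1 ⇒ no choice signal) and by
`laser_rate_effect` on laser-ON trials. Photometry convolves the relative
latent drive with a unit-area double-exponential kernel (τ_rise = 50 ms,
τ_decay = 400 ms, GCaMP6f-like; the indicator's kinetics are not otherwise
specified) on a positive baseline with additive Gaussian noise
(SD 0.02 ΔF/F). Cohorts map a session's target CR rate to its generative
choice gain linearly (`gain = 1 + slope·CR`), which is the structure the
correlation-recovery analysis is meant to detect.

Everything is deterministic given the config seed; independent deterministic
substreams are derived per stage so adding one output type never perturbs
another.

**What the generator does not emulate**: adaptation and history effects
(satiety, impulsivity drifts), bursting/refractory spike statistics,
photobleaching and hemodynamic artifacts, correlated noise across trials,
realistic video. Passing tests therefore demonstrate that the *estimators
recover what they claim from data satisfying their assumptions* — an
internal-consistency and calibration result — not that real M2/DS recordings
satisfy those assumptions.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen so the full suite
completes in a couple of minutes: 500 ROC oracle instances, 1000-unit null
calibrations, 20-seed cohorts of 5 CR levels × 15 units × 200 trials,
500-unit tagging null, 2000-trial laser-effect sessions, 60-trial photometry
sessions. These sizes put 3-SE statistical bands well inside the effect
sizes being recovered.

## Known limitations

- Group-level statistics across mice (ANOVAs and the like) are out of scope;
  the pipeline emits per-session/per-unit tables from which they are one
  `scipy`/`statsmodels` call away.
- The NWB container format is not read or written; the canonical formats are
  plain CSV.
- The motion module implements only motion energy + PCA + ROC, not a full
  videography feature suite (no SVD masks, pupil, or keypoints).
- The rate-change screen's 14% null flag rate is inherent to its
  any-of-three rule; downstream users should treat the flag as a screen, not
  an inference.
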