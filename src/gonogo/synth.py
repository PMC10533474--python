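"""Synthetic cohort generator for the Go/No-Go analysis pipeline.

Emulates the statistical structure the analysis assumes: randomly
interleaved Go/No-Go trials with a 0.5-s waiting and 2.5-s answer
period; alternating 20-trial laser-OFF/laser-ON blocks (always starting
with an OFF block); lick behavior with configurable Hit/FA rates,
waiting-lick probability and a truncated log-normal first-lick latency;
choice-modulated (FA vs CR) stimulus-evoked Poisson spiking; photometry
built by convolving the same latent rate with a GCaMP-like
double-exponential kernel; short-latency laser-evoked spikes for
optogenetic tagging; and a moving-blob face video for the motion-energy
control.

Everything is deterministic given the config seed (``numpy`` Generator
seeded explicitly; no implicit entropy).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import behavior
from .core import (
    Laser,
    OutcomeValue,
    PhotometryTrace,
    Session,
    SpikeUnit,
    Stimulus,
    TaskTiming,
    Trial,
)

__all__ = [
    "SimConfig",
    "CohortSpec",
    "generate_session",
    "generate_spikes",
    "generate_photometry",
    "generate_tagging_data",
    "generate_face_video",
    "generate_cohort",
    "make_cohort_spec",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SimConfig:
    """Full generative parameterization of one synthetic session.

    Behavioral parameters
    ---------------------
    n_trials : trials per session (must be >= 2 * block_len).
    p_go : probability a trial is a GO trial (i.i.d. interleaving).
    block_len : trials per laser block; blocks alternate OFF, ON, ...
    hit_rate / fa_rate_off / fa_rate_on : probability of an answer-period
        lick on GO trials, and on NOGO trials in laser-OFF / laser-ON
        blocks respectively.
    p_wait_lick : probability of >=1 waiting-period lick per trial,
        independent of the answer-period choice.
    lick_latency_loc, lick_latency_scale : median (s) and log-sd of the
        log-normal first answer-period lick latency, truncated to the
        answer period.

    Neural parameters
    -----------------
    baseline_rate : spontaneous Poisson rate, Hz.
    evoked_rate : added rate during [onset_latency, waiting end) of
        NOGO-CR trials, Hz.
    choice_gain : multiplier on the evoked term on NOGO-FA trials (1 =
        no choice signal).
    onset_latency : visual response onset after stimulus onset, s.
    laser_rate_effect : multiplicative firing change applied to the
        stimulus-window rate on laser-ON trials (1 = no laser effect).

    Photometry
    ----------
    gcamp_tau_rise, gcamp_tau_decay : double-exponential kernel time
        constants, s (GCaMP6f-like defaults).
    phot_noise_sd : i.i.d. Gaussian noise, in dF/F units.

    Tagging
    -------
    tag_latency, tag_jitter : laser-evoked spike latency mean / sd, s.
    tag_prob : probability of one laser-evoked spike per pulse.
    wf_corr : target Pearson correlation between the laser-evoked and
        spontaneous mean waveforms.

    Face video
    ----------
    motion_amp : blob displacement amplitude in pixels during trials.
    motion_amp_fa_gain : multiplier on motion_amp during FA trials.

    ``seed`` is mandatory; identical config => bit-identical outputs.
    """

    n_trials: int
    seed: int
    p_go: float = 0.5
    block_len: int = 20
    hit_rate: float = 0.9
    fa_rate_off: float = 0.38
    fa_rate_on: float = 0.38
    p_wait_lick: float = 0.2
    lick_latency_loc: float = 0.25
    lick_latency_scale: float = 0.5
    baseline_rate: float = 5.0
    evoked_rate: float = 20.0
    choice_gain: float = 1.5
    onset_latency: float = 0.05
    gcamp_tau_rise: float = 0.05
    gcamp_tau_decay: float = 0.4
    phot_noise_sd: float = 0.02
    tag_latency: float = 0.003
    tag_jitter: float = 0.0005
    tag_prob: float = 0.9
    laser_rate_effect: float = 1.0
    wf_corr: float = 0.99
    motion_amp: float = 2.0
    motion_amp_fa_gain: float = 1.0
    trial_spacing: float = 6.0
    first_onset: float = 2.0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        for name in ("p_go", "hit_rate", "fa_rate_off", "fa_rate_on",
                     "p_wait_lick", "tag_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("baseline_rate", "evoked_rate", "laser_rate_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.choice_gain > 0:
            raise ValueError("choice_gain must be > 0")
        if self.trial_spacing <= TaskTiming().answer_end:
            raise ValueError("trial_spacing must exceed the stimulus period")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of sessions spanning several CR-rate levels.

    ``cr_to_choice_slope`` maps each session's target CR rate (``1 -
    fa_rate_off``, a proportion) to its generative choice gain via
    ``choice_gain = 1 + slope * cr_rate``, so a positive slope yields
    stronger choice signals in better-performing sessions.
    """

    sessions: tuple[SimConfig, ...]
    cr_to_choice_slope: float = 0.0

    def __post_init__(self) -> None:
        levels = {round(1.0 - c.fa_rate_off, 9) for c in self.sessions}
        if len(levels) < 2:
            raise ValueError("cohort needs >=2 distinct CR-rate levels")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent deterministic streams per generator stage
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


def generate_session(config: SimConfig, timing: TaskTiming | None = None) -> Session:
    """Generate one session of interleaved Go/No-Go trials with licks.

    Laser state alternates in ``block_len``-trial blocks starting OFF.
    Outcomes are left unclassified (run ``behavior.classify_outcomes``).
    """
    timing = timing or TaskTiming()
    n = config.n_trials
    if n < 2 * config.block_len:
        raise ValueError(
            "n_trials must be >= 2 * block_len so that the laser block "
            "design contains both an OFF and an ON block"
        )
    rng = _rng(config.seed, 0)
    is_go = rng.random(n) < config.p_go
    block = np.arange(n) // config.block_len
    laser_on = block % 2 == 1
    onsets = config.first_onset + np.arange(n) * config.trial_spacing

    p_answer = np.where(
        is_go,
        config.hit_rate,
        np.where(laser_on, config.fa_rate_on, config.fa_rate_off),
    )
    answer_lick = rng.random(n) < p_answer
    # truncated log-normal first-lick latency within the answer period
    lat = config.lick_latency_loc * np.exp(
        config.lick_latency_scale * rng.standard_normal(n)
    )
    lat = np.minimum(lat, timing.answer_dur - 1e-3)
    wait_lick = rng.random(n) < config.p_wait_lick
    wait_time = rng.uniform(0.0, timing.waiting_dur, size=n)

    trials = []
    for i in range(n):
        licks = []
        if wait_lick[i]:
            licks.append(wait_time[i])
        if answer_lick[i]:
            licks.append(timing.waiting_dur + lat[i])
        trials.append(
            Trial(
                index=i,
                stimulus=Stimulus.GO if is_go[i] else Stimulus.NOGO,
                laser=Laser.ON if laser_on[i] else Laser.OFF,
                block_index=int(block[i]),
                onset=float(onsets[i]),
                lick_times=np.sort(licks),
            )
        )
    return Session(
        session_id=f"sim-{config.seed}",
        mouse_id=f"mouse-{config.seed}",
        timing=timing,
        trials=trials,
    )


def _trial_rate_segments(
    session: Session, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-constant latent rate: (starts, ends, rates).

    Baseline everywhere; during a trial's stimulus waiting window the
    rate is ``(baseline + evoked_term) * laser_factor`` where the evoked
    term is ``evoked_rate`` on NOGO-CR trials, ``evoked_rate *
    choice_gain`` on NOGO-FA trials, and 0 on GO trials, switched on at
    ``onset_latency``.
    """
    if session.outcomes is None:
        behavior.classify_outcomes(session)
    timing = session.timing
    duration = session.trials[-1].onset + config.trial_spacing
    prev_end = 0.0
    starts, ends, rates = [], [], []
    for trial, outcome in zip(session.trials, session.outcomes):
        t0, t_on = trial.onset, trial.onset + config.onset_latency
        t_w = trial.onset + timing.waiting_dur
        laser = config.laser_rate_effect if trial.laser is Laser.ON else 1.0
        if outcome.value is OutcomeValue.FA:
            evoked = config.evoked_rate * config.choice_gain
        elif outcome.value is OutcomeValue.CR:
            evoked = config.evoked_rate
        else:
            evoked = 0.0
        # gap before trial
        starts.append(prev_end); ends.append(t0); rates.append(config.baseline_rate)
        # pre-onset-latency part of the stimulus window
        starts.append(t0); ends.append(min(t_on, t_w)); rates.append(config.baseline_rate * laser)
        if t_on < t_w:
            starts.append(t_on); ends.append(t_w)
            rates.append((config.baseline_rate + evoked) * laser)
        prev_end = t_w
    starts.append(prev_end); ends.append(duration); rates.append(config.baseline_rate)
    s, e, r = np.array(starts), np.array(ends), np.array(rates)
    keep = e > s
    return s[keep], e[keep], r[keep]


def generate_spikes(session: Session, config: SimConfig) -> SpikeUnit:
    """Inhomogeneous-Poisson spike train for one unit over the session."""
    rng = _rng(config.seed, 1)
    starts, ends, rates = _trial_rate_segments(session, config)
    durs = ends - starts
    counts = rng.poisson(rates * durs)
    total = int(counts.sum())
    u = rng.random(total)
    seg_start = np.repeat(starts, counts)
    seg_dur = np.repeat(durs, counts)
    times = np.sort(seg_start + u * seg_dur)
    return SpikeUnit(
        unit_id=f"unit-{config.seed}",
        spike_times=times,
        mean_waveform_spont=_canonical_waveform(),
    )


def _gcamp_kernel(config: SimConfig, dt: float) -> np.ndarray:
    # unit-area double exponential, so a sustained relative drive D
    # converges to a dF/F plateau of D
    t = np.arange(0.0, 5.0 * config.gcamp_tau_decay, dt)
    k = np.exp(-t / config.gcamp_tau_decay) - np.exp(-t / config.gcamp_tau_rise)
    total = k.sum()
    return k / total if total > 0 else k


def generate_photometry(session: Session, config: SimConfig) -> PhotometryTrace:
    """Calcium-kernel photometry trace sampled at the task's 200 Hz.

    The relative latent drive ``(rate(t) - baseline) / baseline`` from
    the spiking model is convolved with a unit-area double-exponential
    kernel, giving the fractional fluorescence response on a positive
    baseline of 1.0; Gaussian noise (``phot_noise_sd``, dF/F units) is
    added on top.
    """
    rng = _rng(config.seed, 2)
    timing = session.timing
    rate = timing.phot_rate
    dt = 1.0 / rate
    starts, ends, seg_rates = _trial_rate_segments(session, config)
    duration = ends[-1]
    n_samp = int(np.ceil(duration * rate))
    t = np.arange(n_samp) * dt
    base = max(config.baseline_rate, 1e-12)
    idx = np.clip(np.searchsorted(ends, t, side="right"), 0, len(seg_rates) - 1)
    drive = (seg_rates[idx] - config.baseline_rate) / base
    kernel = _gcamp_kernel(config, dt)
    signal = np.convolve(drive, kernel)[:n_samp]
    f0 = 1.0
    values = f0 * (1.0 + signal)
    if config.phot_noise_sd > 0:
        values = values + f0 * config.phot_noise_sd * rng.standard_normal(n_samp)
    return PhotometryTrace(t0=0.0, rate=rate, values=values)


def _canonical_waveform(n: int = 40) -> np.ndarray:
    # biphasic extracellular spike shape
    t = np.linspace(-1.0, 2.0, n)
    return -np.exp(-((t - 0.0) ** 2) / 0.05) + 0.45 * np.exp(-((t - 0.7) ** 2) / 0.3)


def _waveform_with_corr(w: np.ndarray, target: float, rng: np.random.Generator) -> np.ndarray:
    """A perturbed copy of ``w`` whose Pearson correlation with ``w`` is
    ``target`` (to floating-point accuracy)."""
    wz = (w - w.mean()) / w.std()
    noise = rng.standard_normal(w.size)
    noise = noise - noise.mean()
    noise = noise - wz * (noise @ wz) / (wz @ wz)
    nz = noise / noise.std()
    vz = target * wz + np.sqrt(max(0.0, 1.0 - target**2)) * nz
    return w.mean() + w.std() * vz


def generate_tagging_data(
    config: SimConfig,
    n_pulses: int = 150,
    iti: float = 5.0,
    tagged: bool = True,
    pulse_dur: float = 0.1,
) -> tuple[SpikeUnit, np.ndarray]:
    """Laser-tagging protocol: background spikes plus (optionally)
    short-latency laser-evoked spikes, with spontaneous and laser-evoked
    mean waveforms.

    Defaults follow the standard protocol: 150 pulses of 100-ms laser
    with a 5-s inter-pulse interval.  Returns the unit and the laser
    onset times.
    """
    rng = _rng(config.seed, 3)
    onsets = iti * (np.arange(n_pulses) + 1.0)
    duration = iti * (n_pulses + 1)
    n_bg = rng.poisson(config.baseline_rate * duration)
    spikes = rng.uniform(0.0, duration, size=n_bg)
    if tagged:
        evoked_mask = rng.random(n_pulses) < config.tag_prob
        jitter = config.tag_jitter * rng.standard_normal(n_pulses)
        evoked = onsets + np.maximum(config.tag_latency + jitter, 1e-4)
        spikes = np.concatenate([spikes, evoked[evoked_mask]])
    spikes = np.sort(spikes)
    spont = _canonical_waveform()
    laser_wf = _waveform_with_corr(spont, config.wf_corr, rng)
    return (
        SpikeUnit(
            unit_id=f"tag-{config.seed}",
            spike_times=spikes,
            mean_waveform_spont=spont,
            mean_waveform_laser=laser_wf,
        ),
        onsets,
    )


def generate_face_video(
    session: Session,
    config: SimConfig,
    frame_shape: tuple[int, int] = (32, 32),
    frame_rate: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic grayscale face video: a Gaussian blob that oscillates
    during trials with a per-trial motion amplitude.

    The blob displacement during a trial's stimulus period is
    ``motion_amp`` pixels (times ``motion_amp_fa_gain`` on FA trials)
    and zero between trials.  Returns ``(frames, frame_times)`` with
    frames of shape ``(n_frames, H, W)``.
    """
    if session.outcomes is None:
        behavior.classify_outcomes(session)
    timing = session.timing
    duration = session.trials[-1].onset + config.trial_spacing
    n_frames = int(np.floor(duration * frame_rate))
    times = np.arange(n_frames) / frame_rate
    amp = np.zeros(n_frames)
    for trial, outcome in zip(session.trials, session.outcomes):
        in_trial = (times >= trial.onset) & (times < trial.onset + timing.answer_end)
        a = config.motion_amp
        if outcome.value is OutcomeValue.FA:
            a *= config.motion_amp_fa_gain
        amp[in_trial] = a
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy, sigma = w / 2.0, h / 2.0, 3.0
    dx = amp * np.sin(2.0 * np.pi * 2.0 * times)
    frames = np.exp(
        -(
            (xx[None, :, :] - (cx + dx[:, None, None])) ** 2
            + (yy[None, :, :] - cy) ** 2
        )
        / (2.0 * sigma**2)
    ).astype(np.float32)
    return frames, times


def make_cohort_spec(
    cr_levels: list[float],
    units_per_level: int,
    slope: float,
    base: SimConfig,
    seed: int,
) -> CohortSpec:
    """Build a :class:`CohortSpec` with one independent session per unit.

    ``cr_levels`` are target CR rates (proportions); each level gets
    ``units_per_level`` sessions whose ``fa_rate_off`` is ``1 - level``
    and whose seeds are spawned deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for level in cr_levels:
        for _ in range(units_per_level):
            configs.append(
                dataclasses.replace(
                    base,
                    fa_rate_off=1.0 - level,
                    fa_rate_on=1.0 - level,
                    seed=int(rng.integers(0, _MAX_SEED)),
                )
            )
    return CohortSpec(sessions=tuple(configs), cr_to_choice_slope=slope)


def generate_cohort(
    spec: CohortSpec,
    timing: TaskTiming | None = None,
    include_photometry: bool = False,
) -> list[tuple[Session, SpikeUnit, PhotometryTrace | None]]:
    """Generate (session, unit, trace) triples across CR-rate levels.

    The generative choice gain of each session is ``1 +
    cr_to_choice_slope * target_cr_rate``.  Photometry traces are
    generated only on request (they dominate memory for large cohorts).
    """
    out = []
    for cfg in spec.sessions:
        cr_target = 1.0 - cfg.fa_rate_off
        gain = max(1e-6, 1.0 + spec.cr_to_choice_slope * cr_target)
        cfg_i = dataclasses.replace(cfg, choice_gain=gain)
        session = generate_session(cfg_i, timing)
        behavior.classify_outcomes(session)
        unit = generate_spikes(session, cfg_i)
        trace = generate_photometry(session, cfg_i) if include_photometry else None
        out.append((session, unit, trace))
    return out
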