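"""Unit-level spike-train analyses.

PSTHs (25-ms bins), responsiveness screening against the pre-stimulus
baseline, optogenetic-tagging classification (short-latency laser-evoked
firing plus a waveform-similarity gate), and laser firing-rate
modulation testing across outcome classes.

Statistical conventions
-----------------------
* The responsiveness screen is a one-sided Wilcoxon signed-rank test of
  per-trial waiting-window rates against the 0.5-s pre-stimulus baseline
  rates (paired within trial); zero differences are dropped.
* Tagging compares per-pulse firing *rates* (counts normalized by
  window length) in a 1-s pre-laser versus 6-ms post-laser window by a
  one-sided paired t test; raw counts over such unequal windows would
  carry a built-in null bias.
* The laser modulation test compares waiting-window rates between
  laser-OFF and laser-ON trials of each outcome class with a two-sided
  rank-sum test: OFF and ON are distinct trials of generally unequal
  number, so no pairing exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .core import (
    Laser,
    OutcomeValue,
    Session,
    SpikeUnit,
    Stimulus,
    Trial,
    trial_window_counts,
)

__all__ = [
    "PSTH",
    "TaggingCriteria",
    "TaggingResult",
    "RateChangeResult",
    "build_psth",
    "smooth_psth_for_display",
    "responsiveness_test",
    "optotag_classify",
    "rate_change_test",
]


@dataclass(frozen=True)
class PSTH:
    bin_edges: np.ndarray  # trial-relative seconds, len(rate) + 1
    rate: np.ndarray  # spikes/s per bin, averaged over trials
    n_trials: int
    condition_label: str = ""


@dataclass(frozen=True)
class TaggingCriteria:
    """Windows and thresholds for optogenetic-tagging classification."""

    pre_window: float = 1.0
    post_window: float = 0.006
    alpha: float = 0.01
    min_waveform_corr: float = 0.95

    def __post_init__(self) -> None:
        if not self.post_window < self.pre_window:
            raise ValueError("post_window must be shorter than pre_window")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TaggingResult:
    unit_id: str
    p_value: float
    waveform_corr: float
    tagged: bool
    reason: str = ""


@dataclass(frozen=True)
class RateChangeResult:
    """Laser OFF-vs-ON firing-rate test per outcome class.

    ``significant`` iff the smallest available p value is < 0.05 (one
    test per outcome class; classes with too few trials carry NaN).
    """

    unit_id: str
    p_cr: float
    p_fa: float
    p_hit: float
    significant: bool


def build_psth(
    unit: SpikeUnit,
    session: Session,
    condition: Callable[[Trial], bool] | Sequence[bool] | None = None,
    window: tuple[float, float] = (-0.5, 3.0),
    bin_width: float | None = None,
    condition_label: str = "",
) -> PSTH:
    """Trial-averaged PSTH over a trial-relative window, 25-ms bins.

    The returned rates are raw (unsmoothed); analysis code must use
    these.  Gaussian smoothing for figures is a separate step,
    :func:`smooth_psth_for_display`.
    """
    bin_width = bin_width or session.timing.psth_bin
    a, b = window
    n_bins = int(round((b - a) / bin_width))
    if n_bins < 1 or abs(n_bins * bin_width - (b - a)) > 1e-9:
        raise ValueError("bin width must tile the window")
    edges = a + bin_width * np.arange(n_bins + 1)

    if condition is None:
        trials = session.trials
    elif callable(condition):
        trials = [t for t in session.trials if condition(t)]
    else:
        mask = np.asarray(condition, dtype=bool)
        trials = [t for t, m in zip(session.trials, mask) if m]
    if not trials:
        raise ValueError("no trials match the PSTH condition")

    counts = np.zeros(n_bins)
    for t in trials:
        rel = unit.spike_times - t.onset
        rel = rel[(rel >= a) & (rel < b)]
        # half-open bins: right edge belongs to the next bin
        idx = np.floor((rel - a) / bin_width).astype(int)
        idx = idx[idx < n_bins]
        counts += np.bincount(idx, minlength=n_bins)
    rate = counts / (len(trials) * bin_width)
    return PSTH(bin_edges=edges, rate=rate, n_trials=len(trials),
                condition_label=condition_label)


def smooth_psth_for_display(psth: PSTH, sigma_bins: float = 1.0) -> np.ndarray:
    """Gaussian-smoothed copy of the PSTH rates, for plotting only."""
    return gaussian_filter1d(psth.rate, sigma=sigma_bins, truncate=3.0)


def _wilcoxon_one_sided_greater(x: np.ndarray, y: np.ndarray) -> float:
    """Signed-rank p for H1: x > y.  Zero differences are dropped; exact
    null distribution for n <= 25, otherwise the normal approximation
    with tie and continuity correction."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not has_ties:
        method = "exact"
        res = stats.wilcoxon(d, alternative="greater", method=method)
    else:
        res = stats.wilcoxon(d, alternative="greater", method="approx",
                             correction=True)
    return float(res.pvalue)


def responsiveness_test(
    unit: SpikeUnit,
    session: Session,
    alpha: float = 0.05,
    condition: Callable[[Trial], bool] | Sequence[bool] | None = None,
) -> tuple[float, bool]:
    """Visual responsiveness screen: waiting-window vs baseline rates.

    Per-trial firing rates in the waiting period ``[0, waiting_dur)``
    are compared with the 0.5-s pre-stimulus baseline by a one-sided
    Wilcoxon signed-rank test (evoked > baseline).  Returns ``(p_value,
    responsive)``.  Requires >= 6 analyzable trials (the exact test
    cannot reach p < 0.05 below that).
    """
    timing = session.timing
    if condition is None:
        mask = np.ones(session.n_trials, dtype=bool)
    elif callable(condition):
        mask = np.array([bool(condition(t)) for t in session.trials])
    else:
        mask = np.asarray(condition, dtype=bool)
    evoked = trial_window_counts(unit, session, (0.0, timing.waiting_dur))[mask]
    base = trial_window_counts(
        unit, session, (-timing.spike_baseline, 0.0)
    )[mask]
    if evoked.size < 6:
        raise ValueError("responsiveness test needs >= 6 trials")
    evoked_rate = evoked / timing.waiting_dur
    base_rate = base / timing.spike_baseline
    p = _wilcoxon_one_sided_greater(evoked_rate, base_rate)
    return p, bool(p < alpha)


def optotag_classify(
    unit: SpikeUnit,
    laser_onsets: np.ndarray,
    criteria: TaggingCriteria = TaggingCriteria(),
) -> TaggingResult:
    """Optogenetic-tagging classification for one unit.

    Per laser pulse, firing rates in ``[-pre_window, 0)`` and
    ``[0, post_window)`` around the onset are compared by a one-sided
    paired t test (post > pre).  A unit is tagged iff p < alpha *and*
    the Pearson correlation between its mean spontaneous and
    laser-evoked waveforms exceeds ``min_waveform_corr``.
    """
    onsets = np.asarray(laser_onsets, dtype=float)
    if onsets.size < 2:
        raise ValueError("tagging needs at least 2 laser pulses")
    if unit.mean_waveform_laser is None or unit.mean_waveform_spont is None:
        return TaggingResult(unit.unit_id, np.nan, np.nan, False,
                             reason="missing_laser_waveform")
    times = unit.spike_times
    pre = (
        np.searchsorted(times, onsets, "left")
        - np.searchsorted(times, onsets - criteria.pre_window, "left")
    ) / criteria.pre_window
    post = (
        np.searchsorted(times, onsets + criteria.post_window, "left")
        - np.searchsorted(times, onsets, "left")
    ) / criteria.post_window
    diff = post - pre
    if np.std(diff) == 0.0:
        # degenerate: constant difference carries no t statistic
        p = 1.0 if diff[0] <= 0 else 0.0
    else:
        p = float(stats.ttest_rel(post, pre, alternative="greater").pvalue)
    corr = float(np.corrcoef(unit.mean_waveform_spont, unit.mean_waveform_laser)[0, 1])
    tagged = bool(p < criteria.alpha and corr > criteria.min_waveform_corr)
    reason = ""
    if not tagged:
        reason = "latency_test" if p >= criteria.alpha else "waveform_corr"
    return TaggingResult(unit.unit_id, p, corr, tagged, reason=reason)


def _ranksum_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0  # all values identical: no evidence either way
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def rate_change_test(
    unit: SpikeUnit,
    session: Session,
    window: tuple[float, float] | None = None,
    min_trials: int = 3,
) -> RateChangeResult:
    """Laser OFF-vs-ON firing-rate comparison in CR, FA and Hit trials.

    Waiting-window rates (or rates in an explicit trial-relative
    ``window``) are compared between laser-OFF and laser-ON trials of
    each outcome class with a two-sided rank-sum test.  Classes with
    fewer than ``min_trials`` trials in either laser condition yield a
    missing (NaN) p value; the unit is flagged significant iff any
    available p is < 0.05.  Raises if no class is testable.
    """
    timing = session.timing
    window = window or (0.0, timing.waiting_dur)
    outcomes = session.require_outcomes()
    counts = trial_window_counts(unit, session, window)
    rates = counts / (window[1] - window[0])
    laser_on = np.array([t.laser is Laser.ON for t in session.trials])
    p_by_class = {}
    for cls in (OutcomeValue.CR, OutcomeValue.FA, OutcomeValue.HIT):
        in_cls = np.array([o.value is cls for o in outcomes])
        off = rates[in_cls & ~laser_on]
        on = rates[in_cls & laser_on]
        if off.size < min_trials or on.size < min_trials:
            p_by_class[cls] = np.nan
        else:
            p_by_class[cls] = _ranksum_two_sided(off, on)
    ps = np.array(list(p_by_class.values()), dtype=float)
    if np.all(np.isnan(ps)):
        raise ValueError("no outcome class has enough OFF and ON trials")
    significant = bool(np.nanmin(ps) < 0.05)
    return RateChangeResult(
        unit_id=unit.unit_id,
        p_cr=p_by_class[OutcomeValue.CR],
        p_fa=p_by_class[OutcomeValue.FA],
        p_hit=p_by_class[OutcomeValue.HIT],
        significant=significant,
    )
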