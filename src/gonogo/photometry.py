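"""Fiber-photometry analysis: dF/F, choice preference inputs, latency.

dF/F is ``(F - F0) / F0`` with F0 the per-trial mean fluorescence over
the 1 s before stimulus onset, so it is exactly invariant to a global
gain on the raw trace.

The response latency of the trial-averaged dF/F curve is estimated by
binning the curve at 25 ms, smoothing it with robust local quadratic
regression (loess with bisquare reweighting, the MATLAB 'rloess'
procedure), taking the mean and SD of the smoothed 0.5-s pre-stimulus
baseline, and finding the first 25-ms bin at or after stimulus onset
whose smoothed value exceeds ``mean + 3 * SD``.  The search is
restricted to the waiting period; a crossing that first happens in the
answer period is reported separately, and a curve that never crosses
yields an explicit missing latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import PhotometryTrace, Session, Trial

__all__ = [
    "DffTrials",
    "LatencyResult",
    "extract_dff",
    "waiting_mean_response",
    "loess_smooth",
    "response_latency",
]


@dataclass
class DffTrials:
    """Trial-aligned dF/F matrix (trials x samples).

    ``time_axis`` is seconds relative to stimulus onset, covering
    ``[-phot_baseline, waiting + answer)`` at the trace's native rate.
    Trials whose baseline F0 was not positive are listed in
    ``bad_trials`` and carry NaN rows.
    """

    trial_matrix: np.ndarray
    time_axis: np.ndarray
    baseline_window: tuple[float, float]
    bad_trials: list[tuple[int, str]] = field(default_factory=list)


@dataclass(frozen=True)
class LatencyResult:
    """Threshold-crossing latency of the smoothed dF/F curve.

    ``latency`` is None when the smoothed curve never exceeds
    ``baseline_mean + 3 * baseline_sd`` within the waiting period;
    ``answer_crossing`` reports a first crossing in the answer period,
    which is never a waiting-period latency.
    """

    latency: float | None
    threshold: float
    baseline_mean: float
    baseline_sd: float
    smoothed_curve: np.ndarray
    bin_times: np.ndarray
    answer_crossing: float | None = None


def extract_dff(trace: PhotometryTrace, session: Session) -> DffTrials:
    """Per-trial dF/F, each trial normalized by its own 1-s baseline."""
    timing = session.timing
    rate = trace.rate
    pre = timing.phot_baseline
    post = timing.answer_end
    n_pre = int(round(pre * rate))
    n_post = int(round(post * rate))
    n_samp = n_pre + n_post
    time_axis = (np.arange(n_samp) - n_pre) / rate
    mat = np.full((session.n_trials, n_samp), np.nan)
    bad: list[tuple[int, str]] = []
    for i, trial in enumerate(session.trials):
        i0 = int(round((trial.onset - trace.t0) * rate)) - n_pre
        if i0 < 0 or i0 + n_samp > trace.values.size:
            raise ValueError(
                f"trace does not cover trial {trial.index} "
                f"([{i0}, {i0 + n_samp}) outside [0, {trace.values.size}))"
            )
        seg = trace.values[i0 : i0 + n_samp]
        f0 = seg[:n_pre].mean()
        if not f0 > 0:
            bad.append((i, f"non-positive baseline F0={f0:g}"))
            continue
        mat[i] = (seg - f0) / f0
    return DffTrials(
        trial_matrix=mat,
        time_axis=time_axis,
        baseline_window=(-pre, 0.0),
        bad_trials=bad,
    )


def _trial_mask(session: Session, predicate) -> np.ndarray:
    if predicate is None:
        return np.ones(session.n_trials, dtype=bool)
    if callable(predicate):
        return np.array([bool(predicate(t)) for t in session.trials])
    mask = np.asarray(predicate)
    if mask.dtype == bool:
        return mask
    out = np.zeros(session.n_trials, dtype=bool)
    out[np.asarray(mask, dtype=int)] = True
    return out


def waiting_mean_response(
    dff: DffTrials,
    session: Session | None = None,
    predicate: Callable[[Trial], bool] | Sequence[int] | Sequence[bool] | None = None,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-trial mean dF/F over the waiting period ``[0, 0.5)``.

    Returns one scalar per selected trial (NaN for bad-baseline trials);
    with no predicate, all trials.  These scalars feed
    :func:`gonogo.choice.unit_choice_result` directly.
    """
    a, b = window if window is not None else (0.0, 0.5)
    cols = (dff.time_axis >= a) & (dff.time_axis < b)
    if not np.any(cols):
        raise ValueError("window lies outside the dF/F time axis")
    values = dff.trial_matrix[:, cols].mean(axis=1)
    if predicate is None or session is None:
        return values
    return values[_trial_mask(session, predicate)]


def loess_smooth(curve: Sequence[float], span: int = 5, iterations: int = 5) -> np.ndarray:
    """Robust local quadratic regression (MATLAB-style 'rloess').

    Each point is re-estimated from its ``span`` nearest neighbours with
    tricube distance weights and a quadratic local fit; ``iterations``
    rounds of bisquare reweighting (scale 6x the median absolute
    residual) suppress outliers.  Endpoints use truncated,
    nearest-neighbour windows.  A constant or exactly quadratic input is
    reproduced to numerical precision.
    """
    y = np.asarray(curve, dtype=float)
    n = y.size
    if span < 4:
        raise ValueError("loess span must be >= 4")
    if n < span:
        raise ValueError(f"need at least span={span} points, got {n}")
    x = np.arange(n, dtype=float)
    half = span // 2

    windows = []
    for i in range(n):
        lo = min(max(0, i - half), n - span)
        windows.append(np.arange(lo, lo + span))

    robust_w = np.ones(n)
    smoothed = y.copy()
    for _ in range(iterations + 1):
        for i, idx in enumerate(windows):
            xi, yi = x[idx], y[idx]
            d = np.abs(xi - x[i])
            dmax = d.max()
            w = (1.0 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
            w = w * robust_w[idx]
            n_use = int(np.count_nonzero(w))
            if n_use == 0:
                smoothed[i] = yi[np.argmin(d)]
                continue
            # weighted local fit at x[i]; drop to a lower degree when
            # robust reweighting leaves too few usable points
            degree = min(2, n_use - 1)
            X = np.vander(xi - x[i], degree + 1)
            W = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X * W[:, None], yi * W, rcond=None)
            smoothed[i] = coef[-1]
        resid = y - smoothed
        abs_resid = np.abs(resid)
        s = 6.0 * np.median(abs_resid)
        if s <= 1e-8 * abs_resid.max():
            # an exact fit at most points collapses the median scale;
            # fall back to the mean so lone outliers still lose weight
            s = 6.0 * abs_resid.mean()
        if s <= 0:
            break  # perfect fit everywhere
        r = np.clip(resid / s, -1.0, 1.0)
        robust_w = (1.0 - r**2) ** 2
    return smoothed


def response_latency(
    dff: DffTrials,
    session: Session | None = None,
    predicate: Callable[[Trial], bool] | Sequence[int] | Sequence[bool] | None = None,
    span: int = 5,
    bin_width: float = 0.025,
    baseline_dur: float = 0.5,
) -> LatencyResult:
    """Threshold-crossing latency of the trial-averaged dF/F response.

    The selected trials' mean curve is binned at ``bin_width`` (25 ms),
    smoothed with :func:`loess_smooth`, and compared against a threshold
    of 3 SD above the mean of the smoothed ``[-baseline_dur, 0)`` bins.
    The latency is the left edge of the first waiting-period bin whose
    smoothed value strictly exceeds the threshold.
    """
    if predicate is not None and session is not None:
        rows = dff.trial_matrix[_trial_mask(session, predicate)]
    else:
        rows = dff.trial_matrix
    rows = rows[~np.isnan(rows).all(axis=1)]
    if rows.shape[0] < 1:
        raise ValueError("latency needs at least one usable trial")
    curve = np.nanmean(rows, axis=0)
    t = dff.time_axis
    waiting_end = 0.5 if session is None else session.timing.waiting_dur
    answer_end = t[-1] + (t[1] - t[0])

    keep = t >= -baseline_dur
    t = t[keep]
    curve = curve[keep]
    dt = t[1] - t[0]
    per_bin = int(round(bin_width / dt))
    n_bins = curve.size // per_bin
    binned = curve[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    bin_times = t[0] + bin_width * np.arange(n_bins)

    smoothed = loess_smooth(binned, span=span)
    base = (bin_times >= -baseline_dur) & (bin_times < 0.0)
    base_mean = float(smoothed[base].mean())
    base_sd = float(smoothed[base].std(ddof=1))
    threshold = base_mean + 3.0 * base_sd

    def first_crossing(lo: float, hi: float) -> float | None:
        sel = np.flatnonzero((bin_times >= lo) & (bin_times < hi) & (smoothed > threshold))
        return float(bin_times[sel[0]]) if sel.size else None

    latency = first_crossing(0.0, waiting_end)
    answer_crossing = None
    if latency is None:
        answer_crossing = first_crossing(waiting_end, answer_end)
    return LatencyResult(
        latency=latency,
        threshold=threshold,
        baseline_mean=base_mean,
        baseline_sd=base_sd,
        smoothed_curve=smoothed,
        bin_times=bin_times,
        answer_crossing=answer_crossing,
    )
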