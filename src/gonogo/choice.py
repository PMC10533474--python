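"""ROC-based choice preference and its correlation with performance.

The choice signal for the No-Go stimulus is estimated by comparing the
distribution of waiting-period responses (spike counts, dF/F means, or
motion-energy PC means) between FA and CR trials with ROC analysis:

    choice preference = 2 * (ROC_area - 0.5)   in [-1, 1],

positive when FA-trial responses exceed CR-trial responses.  The ROC
area is computed by the rank (Mann-Whitney) identity with ties counted
as half, which is exactly the all-pairs statistic

    (1 / (n_fa * n_cr)) * sum[ 1(x_fa > x_cr) + 0.5 * 1(x_fa = x_cr) ].

To limit lick-movement contamination, only No-Go trials without any
waiting-period lick enter the analysis, and a session contributes only
if it has at least ``min_fa`` (default 10) such FA trials.

Neurons are pooled by their session's CR rate into 10-percentage-point
bins, ``(20, 30], (30, 40], ...``; Pearson's correlation is computed
between the bin centers and the per-bin mean choice preference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import Session, SpikeUnit, Stimulus, trial_window_counts

__all__ = [
    "ChoiceResult",
    "BinnedChoiceCorrelation",
    "SessionEligibility",
    "SessionIneligibleError",
    "eligible_nogo_trials",
    "session_eligibility",
    "roc_area",
    "choice_preference",
    "unit_choice_result",
    "spike_window_values",
    "binned_correlation",
    "delta_choice_preference",
    "WINDOW_FULL",
    "WINDOW_EARLY",
]

WINDOW_FULL = "FULL_WAITING"
WINDOW_EARLY = "EARLY_300MS"


@dataclass(frozen=True)
class ChoiceResult:
    roc_area: float
    choice_pref: float
    n_fa: int
    n_cr: int
    window_label: str = WINDOW_FULL


@dataclass(frozen=True)
class SessionEligibility:
    """Session-inclusion record for the choice analysis."""

    n_eligible_fa: int
    eligible: bool
    min_fa: int = 10


class SessionIneligibleError(ValueError):
    """Raised when a session fails the >= min_fa eligible-FA-trial rule.

    Carries the :class:`SessionEligibility` record so callers can log an
    explicit exclusion rather than silently dropping the session.
    """

    def __init__(self, eligibility: SessionEligibility):
        self.eligibility = eligibility
        super().__init__(
            f"session ineligible for choice analysis: "
            f"{eligibility.n_eligible_fa} eligible FA trials "
            f"(needs >= {eligibility.min_fa})"
        )


@dataclass(frozen=True)
class BinnedChoiceCorrelation:
    bin_edges: np.ndarray  # CR-rate percent edges of occupied bins
    bin_centers: np.ndarray  # percent
    bin_means: np.ndarray  # mean choice preference per occupied bin
    bin_ns: np.ndarray  # neurons per occupied bin
    r: float
    p_value: float


def eligible_nogo_trials(session: Session) -> tuple[np.ndarray, np.ndarray]:
    """Indices of FA and CR trials with no waiting-period lick.

    Returns ``(fa_idx, cr_idx)``; either may be empty — downstream
    operations enforce their own minima.
    """
    outcomes = session.require_outcomes()
    fa, cr = [], []
    for i, (t, o) in enumerate(zip(session.trials, outcomes)):
        if t.stimulus is not Stimulus.NOGO or o.licked_in_waiting:
            continue
        (fa if o.value.value == "FA" else cr).append(i)
    return np.array(fa, dtype=int), np.array(cr, dtype=int)


def session_eligibility(session: Session, min_fa: int = 10) -> SessionEligibility:
    fa_idx, _ = eligible_nogo_trials(session)
    return SessionEligibility(
        n_eligible_fa=int(fa_idx.size),
        eligible=bool(fa_idx.size >= min_fa),
        min_fa=min_fa,
    )


def roc_area(values_fa: Sequence[float], values_cr: Sequence[float]) -> float:
    """Area under the empirical ROC with FA as the signal class.

    Computed through the rank identity ``AUC = (R_fa - n_fa(n_fa+1)/2) /
    (n_fa * n_cr)`` with mid-ranks for ties, which equals the all-pairs
    count of ``1(x_fa > x_cr) + 0.5 * 1(x_fa = x_cr)`` exactly.
    """
    u, n_pairs = _mann_whitney_u(values_fa, values_cr)
    return float(u / n_pairs)


def _mann_whitney_u(values_fa, values_cr) -> tuple[float, int]:
    fa = np.asarray(values_fa, dtype=float)
    cr = np.asarray(values_cr, dtype=float)
    if fa.size == 0 or cr.size == 0:
        raise ValueError("roc_area needs at least one value in each class")
    ranks = stats.rankdata(np.concatenate([fa, cr]))
    r_fa = ranks[: fa.size].sum()
    u = r_fa - fa.size * (fa.size + 1) / 2.0
    return float(u), int(fa.size * cr.size)


def choice_preference(values_fa: Sequence[float], values_cr: Sequence[float]) -> float:
    """``2 * (roc_area - 0.5)``: positive when FA responses exceed CR.

    Evaluated as ``(2U - n_pairs) / n_pairs`` so that swapping the two
    classes negates the value exactly in floating point.
    """
    u, n_pairs = _mann_whitney_u(values_fa, values_cr)
    return float((2.0 * u - n_pairs) / n_pairs)


def spike_window_values(
    unit: SpikeUnit, session: Session, window_label: str = WINDOW_FULL
) -> np.ndarray:
    """Per-trial spike counts in the waiting (or early-waiting) window."""
    timing = session.timing
    if window_label == WINDOW_FULL:
        window = (0.0, timing.waiting_dur)
    elif window_label == WINDOW_EARLY:
        window = (0.0, timing.early_window)
    else:
        raise ValueError(f"unknown window label {window_label!r}")
    return trial_window_counts(unit, session, window).astype(float)


def unit_choice_result(
    values: Sequence[float],
    session: Session,
    window_label: str = WINDOW_FULL,
    min_fa: int = 10,
) -> ChoiceResult:
    """Choice preference of one unit/signal from per-trial responses.

    ``values`` holds one scalar response per trial of the session (the
    waiting- or early-window response).  Only lick-free No-Go trials are
    used; raises :class:`SessionIneligibleError` if the session has
    fewer than ``min_fa`` eligible FA trials.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (session.n_trials,):
        raise ValueError("values must hold one scalar per trial")
    elig = session_eligibility(session, min_fa=min_fa)
    if not elig.eligible:
        raise SessionIneligibleError(elig)
    fa_idx, cr_idx = eligible_nogo_trials(session)
    if cr_idx.size == 0:
        raise ValueError("no eligible CR trials")
    auc = roc_area(values[fa_idx], values[cr_idx])
    return ChoiceResult(
        roc_area=auc,
        choice_pref=choice_preference(values[fa_idx], values[cr_idx]),
        n_fa=int(fa_idx.size),
        n_cr=int(cr_idx.size),
        window_label=window_label,
    )


def binned_correlation(
    results: Iterable[tuple[ChoiceResult | float, float]],
    bin_width_pct: float = 10.0,
) -> BinnedChoiceCorrelation:
    """Pearson correlation of per-bin mean choice preference vs CR rate.

    ``results`` pairs each neuron's choice result (or bare preference
    value) with its session's CR rate as a proportion in [0, 1].  Bins
    are half-open on the left in percent, ``(k*w, (k+1)*w]``, with
    centers at ``k*w + w/2``; unoccupied bins are excluded, and at least
    3 occupied bins are required.  The p value is the two-sided
    t-distribution test with ``df = bins - 2``.
    """
    prefs, crs = [], []
    for res, cr in results:
        prefs.append(res.choice_pref if isinstance(res, ChoiceResult) else float(res))
        crs.append(100.0 * float(cr))
    prefs_arr = np.asarray(prefs)
    crs_arr = np.asarray(crs)
    # (k*w, (k+1)*w] membership: the right edge belongs to the bin
    bin_idx = np.ceil(crs_arr / bin_width_pct).astype(int) - 1
    bin_idx = np.clip(bin_idx, 0, int(100.0 / bin_width_pct) - 1)
    occupied = np.unique(bin_idx)
    if occupied.size < 3:
        raise ValueError(
            f"binned correlation needs >= 3 occupied CR-rate bins, "
            f"got {occupied.size}"
        )
    means = np.array([prefs_arr[bin_idx == b].mean() for b in occupied])
    ns = np.array([(bin_idx == b).sum() for b in occupied])
    centers = occupied * bin_width_pct + bin_width_pct / 2.0
    r, p = stats.pearsonr(centers, means)
    edges = np.concatenate([occupied * bin_width_pct, [(occupied[-1] + 1) * bin_width_pct]])
    return BinnedChoiceCorrelation(
        bin_edges=edges,
        bin_centers=centers,
        bin_means=means,
        bin_ns=ns,
        r=float(r),
        p_value=float(p),
    )


def delta_choice_preference(results_off: ChoiceResult, results_on: ChoiceResult) -> float:
    """Laser-ON minus laser-OFF choice preference for the same unit."""
    if results_off.window_label != results_on.window_label:
        raise ValueError(
            "cannot difference choice preferences from different windows"
        )
    return results_on.choice_pref - results_off.choice_pref
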