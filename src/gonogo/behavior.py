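"""Trial classification and behavioral performance metrics.

Outcomes follow the standard Go/No-Go convention: an answer-period lick
on a GO trial is a HIT (no lick: MISS); on a NOGO trial it is a false
alarm, FA (no lick: correct rejection, CR).  Waiting-period licks are
recorded but never alter the outcome.

Rates are the printed proportions
``Hit rate = n_HIT / (n_HIT + n_MISS)`` and
``FA rate = n_FA / (n_FA + n_CR)``, and behavioral discriminability is

    d' = Phi^-1(Hit rate) - Phi^-1(FA rate)

with each rate clipped to ``[1/(2n), 1 - 1/(2n)]`` of its own trial
count before the inverse-normal transform, so d' stays finite (and
n-aware) at 0% or 100% rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import Laser, Outcome, OutcomeValue, Session, Stimulus, Trial

__all__ = [
    "BehaviorSummary",
    "DeltaMetrics",
    "LickLatencySummary",
    "classify_outcomes",
    "compute_rates",
    "compute_dprime",
    "delta_metrics",
    "lick_latency",
    "no_lick_waiting_fraction",
    "block_position_metrics",
]

TrialPredicate = Callable[[Trial], bool]


@dataclass(frozen=True)
class BehaviorSummary:
    hit_rate: float
    miss_rate: float
    fa_rate: float
    cr_rate: float
    dprime: float
    n_go: int
    n_nogo: int
    subset_label: str = "ALL"


@dataclass(frozen=True)
class DeltaMetrics:
    """Laser-ON metric minus laser-OFF metric, within one session."""

    d_hit: float
    d_fa: float
    d_dprime: float


@dataclass(frozen=True)
class LickLatencySummary:
    median_latency: float
    per_trial_latencies: np.ndarray


def classify_outcomes(session: Session) -> Session:
    """Fill ``session.outcomes`` from answer-period licks (in place).

    Waiting-period licks set ``licked_in_waiting`` but never change the
    outcome: they are neither rewarded nor punished in the task.
    """
    timing = session.timing
    w_end = timing.waiting_dur
    a_end = timing.answer_end
    outcomes: list[Outcome] = []
    for trial in session.trials:
        licks = trial.lick_times
        in_waiting = bool(np.any((licks >= 0.0) & (licks < w_end)))
        in_answer = bool(np.any((licks >= w_end) & (licks < a_end)))
        if trial.stimulus is Stimulus.GO:
            value = OutcomeValue.HIT if in_answer else OutcomeValue.MISS
        else:
            value = OutcomeValue.FA if in_answer else OutcomeValue.CR
        outcomes.append(Outcome(value=value, licked_in_waiting=in_waiting))
    session.outcomes = outcomes
    return session


def _subset_mask(session: Session, subset: TrialPredicate | Sequence[bool] | None) -> np.ndarray:
    if subset is None:
        return np.ones(session.n_trials, dtype=bool)
    if callable(subset):
        return np.array([bool(subset(t)) for t in session.trials])
    mask = np.asarray(subset, dtype=bool)
    if mask.shape != (session.n_trials,):
        raise ValueError("boolean subset mask must have one entry per trial")
    return mask


def compute_rates(
    session: Session,
    subset: TrialPredicate | Sequence[bool] | None = None,
    subset_label: str = "ALL",
) -> BehaviorSummary:
    """Hit/Miss/FA/CR rates and d' over a trial subset.

    Raises ``ValueError`` if the subset contains no GO or no NOGO trials
    (the rates are undefined there).
    """
    outcomes = session.require_outcomes()
    mask = _subset_mask(session, subset)
    counts = {v: 0 for v in OutcomeValue}
    for i, outcome in enumerate(outcomes):
        if mask[i]:
            counts[outcome.value] += 1
    n_go = counts[OutcomeValue.HIT] + counts[OutcomeValue.MISS]
    n_nogo = counts[OutcomeValue.FA] + counts[OutcomeValue.CR]
    if n_go == 0 or n_nogo == 0:
        raise ValueError(
            f"rates undefined for subset {subset_label!r}: "
            f"{n_go} GO and {n_nogo} NOGO trials"
        )
    hit = counts[OutcomeValue.HIT] / n_go
    fa = counts[OutcomeValue.FA] / n_nogo
    return BehaviorSummary(
        hit_rate=hit,
        miss_rate=1.0 - hit,
        fa_rate=fa,
        cr_rate=1.0 - fa,
        dprime=compute_dprime(hit, fa, n_go, n_nogo),
        n_go=n_go,
        n_nogo=n_nogo,
        subset_label=subset_label,
    )


def compute_dprime(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int) -> float:
    """Signal-detection d' with 1/(2n) rate clipping.

    ``d' = Phi^-1(hit') - Phi^-1(fa')`` where each rate is clipped to
    ``[1/(2n), 1 - 1/(2n)]`` of its respective trial count.
    """
    if n_go <= 0 or n_nogo <= 0:
        raise ValueError("n_go and n_nogo must be positive")
    for r in (hit_rate, fa_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    hit = float(np.clip(hit_rate, 1.0 / (2 * n_go), 1.0 - 1.0 / (2 * n_go)))
    fa = float(np.clip(fa_rate, 1.0 / (2 * n_nogo), 1.0 - 1.0 / (2 * n_nogo)))
    return float(norm.ppf(hit) - norm.ppf(fa))


def _laser_subset(state: Laser) -> TrialPredicate:
    return lambda t: t.laser is state


def delta_metrics(
    session: Session, subset: TrialPredicate | Sequence[bool] | None = None
) -> DeltaMetrics:
    """Laser-ON minus laser-OFF Hit rate, FA rate and d'.

    An optional extra ``subset`` restricts both laser subsets (used for
    block-position analyses).
    """
    base = _subset_mask(session, subset)
    off = base & np.array([t.laser is Laser.OFF for t in session.trials])
    on = base & np.array([t.laser is Laser.ON for t in session.trials])
    s_off = compute_rates(session, off, subset_label="LASER_OFF")
    s_on = compute_rates(session, on, subset_label="LASER_ON")
    return DeltaMetrics(
        d_hit=s_on.hit_rate - s_off.hit_rate,
        d_fa=s_on.fa_rate - s_off.fa_rate,
        d_dprime=s_on.dprime - s_off.dprime,
    )


def lick_latency(session: Session) -> LickLatencySummary:
    """First-lick latency on No-Go trials, capped at ``lick_latency_cap``.

    The latency of a trial is the time of the first lick within the cap
    window after stimulus onset (waiting-period licks count); trials
    without such a lick carry exactly the cap value.  The session value
    is the median across No-Go trials.
    """
    cap = session.timing.lick_latency_cap
    lat = []
    for trial in session.trials:
        if trial.stimulus is not Stimulus.NOGO:
            continue
        licks = trial.lick_times
        early = licks[(licks >= 0.0) & (licks < cap)]
        lat.append(float(early[0]) if early.size else cap)
    if not lat:
        raise ValueError("lick latency requires at least one No-Go trial")
    lat_arr = np.array(lat)
    return LickLatencySummary(
        median_latency=float(np.median(lat_arr)), per_trial_latencies=lat_arr
    )


def no_lick_waiting_fraction(session: Session) -> float:
    """Fraction of No-Go trials with no lick in the waiting period."""
    outcomes = session.require_outcomes()
    flags = [
        not o.licked_in_waiting
        for t, o in zip(session.trials, outcomes)
        if t.stimulus is Stimulus.NOGO
    ]
    if not flags:
        raise ValueError("no No-Go trials in session")
    return float(np.mean(flags))


def block_position_metrics(session: Session) -> pd.DataFrame:
    """Laser delta-metrics by block tercile and by within-block position.

    Rows: ``blocks_first`` / ``blocks_middle`` / ``blocks_last`` (first,
    middle and last third of the session's blocks; with 12 blocks this is
    the 4/4/4 split) and ``within_first10`` / ``within_last10`` (first
    vs last 10 trials of every block).  A partition whose delta cannot be
    computed (too few trials in some cell) gets NaN values and
    ``flag='insufficient_trials'``; generalized partitions (block count
    not 12, or block length not 20) are flagged ``'generalized'``.
    """
    block_idx = np.array([t.block_index for t in session.trials])
    blocks = np.unique(block_idx)
    n_blocks = blocks.size
    if n_blocks < 3:
        raise ValueError("block-position analysis needs at least 3 blocks")
    terciles = np.array_split(blocks, 3)
    block_lens = np.array([(block_idx == b).sum() for b in blocks])
    block_len = int(block_lens.max())
    n_pos = min(10, max(1, block_len // 2))
    pos_in_block = np.zeros(session.n_trials, dtype=int)
    for b in blocks:
        sel = np.flatnonzero(block_idx == b)
        pos_in_block[sel] = np.arange(sel.size)

    generalized = n_blocks != 12 or block_len != 20

    rows = []

    def add_row(label: str, mask: np.ndarray, flag: str) -> None:
        try:
            d = delta_metrics(session, mask)
            rows.append((label, d.d_hit, d.d_fa, d.d_dprime, flag))
        except ValueError:
            rows.append((label, np.nan, np.nan, np.nan, "insufficient_trials"))

    base_flag = "generalized" if generalized else ""
    for label, group in zip(("blocks_first", "blocks_middle", "blocks_last"), terciles):
        add_row(label, np.isin(block_idx, group), base_flag)
    add_row("within_first10", pos_in_block < n_pos, base_flag)
    len_of_block = {int(b): int(n) for b, n in zip(blocks, block_lens)}
    trial_block_len = np.array([len_of_block[int(b)] for b in block_idx])
    add_row("within_last10", pos_in_block >= trial_block_len - n_pos, base_flag)

    return pd.DataFrame(
        rows, columns=["partition", "d_hit", "d_fa", "d_dprime", "flag"]
    )
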