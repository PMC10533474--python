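"""Orofacial motion-energy control analysis.

Motion energy is the element-wise absolute intensity difference of
consecutive video frames; its first three principal components (pixels
as variables, frames as observations) summarize orofacial movement.
Applying the same ROC choice-preference statistic to the PCs over the
waiting period tests whether an apparent neural choice signal could be
explained by differential facial movement in FA vs CR trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .choice import ChoiceResult, unit_choice_result
from .core import Session

__all__ = ["MotionEnergyPCs", "motion_energy", "motion_pcs", "motion_choice_roc"]


@dataclass(frozen=True)
class MotionEnergyPCs:
    """PCA of the motion-energy stack.

    ``pc_timeseries`` is (n_components x n_energy_frames); components
    (rows of ``components``) are orthonormal in pixel space with
    non-increasing explained variance, each signed so its
    largest-magnitude pixel loading is positive.  Energy frame ``k``
    (difference of frames k and k+1) is timestamped at ``t0 + (k + 0.5)
    / frame_rate``.
    """

    pc_timeseries: np.ndarray
    explained_variance: np.ndarray
    components: np.ndarray
    pixel_mean: np.ndarray
    frame_rate: float = 30.0
    t0: float = 0.0

    def frame_times(self) -> np.ndarray:
        k = np.arange(self.pc_timeseries.shape[1])
        return self.t0 + (k + 0.5) / self.frame_rate


def motion_energy(frames: np.ndarray) -> np.ndarray:
    """|frame[t+1] - frame[t]| for a (T, H, W) grayscale stack."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (T, H, W) stack")
    if frames.shape[0] < 2:
        raise ValueError("motion energy needs at least 2 frames")
    return np.abs(np.diff(frames, axis=0))


def motion_pcs(
    energy: np.ndarray,
    n_components: int = 3,
    frame_rate: float = 30.0,
    t0: float = 0.0,
) -> MotionEnergyPCs:
    """Principal components of the motion-energy stack via SVD.

    The (frames x pixels) matrix is mean-centered per pixel and
    decomposed; scores are ``U * S``.  Requires at least 4 energy frames
    and at least ``n_components`` pixels.
    """
    energy = np.asarray(energy, dtype=float)
    t = energy.shape[0]
    if t < 4:
        raise ValueError("PCA needs at least 4 energy frames")
    x = energy.reshape(t, -1)
    if x.shape[1] < n_components:
        raise ValueError("fewer pixels than requested components")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, s.size)
    scores = (u[:, :k] * s[:k]).T
    comps = vt[:k]
    # deterministic sign: largest-|loading| pixel positive
    for j in range(k):
        i_max = np.argmax(np.abs(comps[j]))
        if comps[j, i_max] < 0:
            comps[j] = -comps[j]
            scores[j] = -scores[j]
    total = (s**2).sum()
    explained = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return MotionEnergyPCs(
        pc_timeseries=scores,
        explained_variance=explained,
        components=comps,
        pixel_mean=mean,
        frame_rate=frame_rate,
        t0=t0,
    )


def motion_choice_roc(
    pcs: MotionEnergyPCs,
    session: Session,
    min_fa: int = 10,
) -> list[ChoiceResult]:
    """Choice preference of each motion-energy PC over the waiting period.

    The per-trial statistic is the mean PC score over energy frames
    whose timestamps fall in the waiting window (nearest frame if the
    window contains none).  Same eligibility rules as the neural choice
    analysis.
    """
    times = pcs.frame_times()
    timing = session.timing
    results = []
    for pc in pcs.pc_timeseries:
        values = np.empty(session.n_trials)
        for i, trial in enumerate(session.trials):
            sel = (times >= trial.onset) & (times < trial.onset + timing.waiting_dur)
            if np.any(sel):
                values[i] = pc[sel].mean()
            else:  # nearest-frame fallback at window edges
                values[i] = pc[np.argmin(np.abs(times - trial.onset))]
        results.append(
            unit_choice_result(values, session, min_fa=min_fa)
        )
    return results
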