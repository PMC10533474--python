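import numpy as np
import pytest

from gonogo import behavior
from gonogo.core import Laser, Session, Stimulus, TaskTiming, Trial


def make_session(
    specs,
    timing: TaskTiming | None = None,
    spacing: float = 6.0,
    first_onset: float = 2.0,
    classify: bool = True,
) -> Session:
    """Build a session from (stimulus, laser, lick_times) triples.

    ``specs`` items may also carry a 4th element, the block index
    (defaults to 0).  Lick times are trial-relative seconds.
    """
    trials = []
    for i, spec in enumerate(specs):
        stim, laser, licks = spec[:3]
        block = spec[3] if len(spec) > 3 else 0
        trials.append(
            Trial(
                index=i,
                stimulus=Stimulus(stim),
                laser=Laser(laser),
                block_index=block,
                onset=first_onset + i * spacing,
                lick_times=np.sort(np.asarray(licks, dtype=float)),
            )
        )
    session = Session("test", "m0", timing or TaskTiming(), trials)
    if classify:
        behavior.classify_outcomes(session)
    return session


@pytest.fixture
def nogo_session():
    """60 No-Go trials, alternating FA (answer lick at 0.7 s) and CR,
    no waiting-period licks — a clean substrate for choice analyses."""
    specs = [("NOGO", "OFF", [0.7] if i % 2 == 0 else []) for i in range(60)]
    return make_session(specs)


@pytest.fixture
def mixed_session():
    """8 HIT, 2 MISS, 3 FA, 7 CR with assorted waiting licks."""
    specs = (
        [("GO", "OFF", [0.8])] * 8
        + [("GO", "OFF", [])] * 2
        + [("NOGO", "OFF", [0.2, 0.9])] * 3  # FA with a waiting lick
        + [("NOGO", "OFF", [])] * 7
    )
    return make_session(specs)
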