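"""Shared fixtures: hand-built segments and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from somnalert.synth import (AWAKE, DEEP, LIGHT, OUT_OF_BED, REM, RawSegment,
                             SimConfig, simulate_dataset)


def make_segment(pid: str, start: str, hours: float, epoch_seconds: int = 30,
                 pattern: str = "sleepy", toss_times=None) -> RawSegment:
    """Build a segment whose hypnogram follows a simple repeating pattern."""
    n = int(hours * 3600 / epoch_seconds)
    if pattern == "sleepy":
        # 10 min awake, then light/deep/rem cycles
        states = np.full(n, LIGHT, dtype=np.int8)
        states[:20] = AWAKE
        cycle = np.array([LIGHT] * 40 + [DEEP] * 20 + [REM] * 20, dtype=np.int8)
        body = np.tile(cycle, n // len(cycle) + 1)[:max(n - 20, 0)]
        states[20:] = body
    elif pattern == "awake":
        states = np.full(n, AWAKE, dtype=np.int8)
    else:
        raise ValueError(pattern)
    toss = (np.array(sorted(toss_times), dtype="datetime64[ns]")
            if toss_times is not None else np.array([], dtype="datetime64[ns]"))
    return RawSegment(
        participant_id=pid,
        segment_start=pd.Timestamp(start),
        epoch_seconds=epoch_seconds,
        epoch_states=states,
        toss_event_times=toss,
        mean_heart_rate=62.0,
        mean_respiration_rate=14.5,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Event-level cohort: 6 participants x 30 nights, no missingness."""
    config = SimConfig(n_participants=6, nights_per_participant=30,
                       missing_night_prob=0.0, nap_prob=0.0,
                       duplicate_prob=0.0, short_segment_prob=0.0,
                       episode_prob_per_night=0.0, seed=21)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def messy_cohort():
    """Cohort with naps, duplicates, fragments, missingness and episodes."""
    config = SimConfig(n_participants=5, nights_per_participant=40,
                       missing_night_prob=0.15, nap_prob=0.1,
                       duplicate_prob=0.05, short_segment_prob=0.08,
                       episode_prob_per_night=0.02, seed=33)
    return simulate_dataset(config)
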