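"""Per-night sleep-parameter extraction.

Computes the 20 nightly sleep parameters used throughout the pipeline from a
night's hypnogram, toss-and-turn event stream and vitals: total/in-bed/state
durations, sleep onset delay, bed exits, awakenings, toss-and-turn count,
sleep efficiency, stage percentages, average heart/respiration rate and
normalized LF/HF heart-rate-variability band powers.

Conventions
-----------
* Durations come from epoch run lengths, so the conservation identities
  (in bed + out of bed = total; asleep + awake = in bed; stage percentages
  sum to sleep efficiency) hold exactly.
* Percentages and sleep efficiency use the *total* recording duration as
  denominator (efficiency = time asleep / total duration).
* An awakening is any awake-in-bed run after sleep onset of at least
  ``min_awakening_epochs`` epochs (default 1, i.e. 30 s).
* HRV band powers are computed from a periodogram of the interbeat-interval
  tachogram resampled to a uniform 4 Hz grid; LF = 0.04-0.15 Hz,
  HF = 0.15-0.40 Hz, each reported as 100 * band / (LF + HF).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import NightRecord
from .synth import AWAKE, OUT_OF_BED, SLEEP_STATES, DEEP, LIGHT, REM

#: Canonical order of the 20 nightly sleep parameters.
FEATURE_NAMES = [
    "duration_total",
    "duration_in_bed",
    "avg_heart_rate",
    "avg_respiration_rate",
    "n_bed_exits",
    "n_toss_turns",
    "duration_asleep",
    "duration_rem",
    "duration_light",
    "duration_deep",
    "duration_awake",
    "sleep_onset_delay",
    "duration_out_of_bed",
    "hrv_hf_norm",
    "hrv_lf_norm",
    "n_awakenings",
    "pct_deep",
    "pct_rem",
    "pct_light",
    "sleep_efficiency",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
MIN_IBI_DURATION_S = 300.0


@dataclass
class SleepFeatureVector:
    duration_total: float
    duration_in_bed: float
    avg_heart_rate: float
    avg_respiration_rate: float
    n_bed_exits: int
    n_toss_turns: int
    duration_asleep: float
    duration_rem: float
    duration_light: float
    duration_deep: float
    duration_awake: float
    sleep_onset_delay: float
    duration_out_of_bed: float
    hrv_hf_norm: float
    hrv_lf_norm: float
    n_awakenings: int
    pct_deep: float
    pct_rem: float
    pct_light: float
    sleep_efficiency: float
    flags: tuple = ()

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("flags")
        return d


def hrv_band_powers(interbeat_intervals: np.ndarray, fs: float = 4.0
                    ) -> tuple[float, float]:
    """Normalized (LF, HF) spectral powers of an interbeat-interval series.

    The tachogram is resampled to a uniform ``fs`` grid by linear
    interpolation, mean-detrended, and a periodogram integrated over
    0.04-0.15 Hz (LF) and 0.15-0.40 Hz (HF); outputs are
    ``100 * band / (LF + HF)``.  Series spanning less than 5 minutes yield
    ``(nan, nan)`` so the night's HRV features propagate as missing.
    """
    ibi = np.asarray(interbeat_intervals, dtype=float)
    if len(ibi) < 2 or ibi.sum() < MIN_IBI_DURATION_S:
        return (np.nan, np.nan)
    t = np.cumsum(ibi)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    x = np.interp(grid, t, ibi)
    x = x - x.mean()
    freqs, psd = signal.periodogram(x, fs=fs)
    lf = float(np.trapezoid(psd[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])],
                            freqs[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])]))
    hf = float(np.trapezoid(psd[(freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])],
                            freqs[(freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])]))
    total = lf + hf
    if total <= 0:
        return (np.nan, np.nan)
    return (100.0 * lf / total, 100.0 * hf / total)


def extract_features(night: NightRecord, min_awakening_epochs: int = 1) -> SleepFeatureVector:
    """All 20 sleep parameters for one quality-controlled night."""
    seg = night.segment
    epoch_s = float(seg.epoch_seconds)
    states = seg.epoch_states
    runs = seg.state_runs()

    def dur(state: int) -> float:
        return float(np.count_nonzero(states == state)) * epoch_s

    duration_total = len(states) * epoch_s
    duration_out = dur(OUT_OF_BED)
    duration_in_bed = duration_total - duration_out
    duration_light, duration_deep, duration_rem = dur(LIGHT), dur(DEEP), dur(REM)
    duration_asleep = duration_light + duration_deep + duration_rem
    duration_awake = duration_in_bed - duration_asleep

    flags = []
    sleep_mask = np.isin(states, SLEEP_STATES)
    if sleep_mask.any():
        onset_epoch = int(np.flatnonzero(sleep_mask)[0])
        sleep_onset_delay = onset_epoch * epoch_s
    else:
        onset_epoch = len(states)
        sleep_onset_delay = duration_total
        flags.append("no_sleep")

    n_bed_exits = sum(1 for st, _, _ in runs if st == OUT_OF_BED)
    n_awakenings = sum(1 for st, a, n in runs
                       if st == AWAKE and a > onset_epoch and n >= min_awakening_epochs)

    lf_norm, hf_norm = hrv_band_powers(seg.interbeat_intervals)
    if np.isnan(hf_norm):
        flags.append("hrv_undefined")

    return SleepFeatureVector(
        duration_total=duration_total,
        duration_in_bed=duration_in_bed,
        avg_heart_rate=seg.mean_heart_rate,
        avg_respiration_rate=seg.mean_respiration_rate,
        n_bed_exits=n_bed_exits,
        n_toss_turns=int(len(seg.toss_event_times)),
        duration_asleep=duration_asleep,
        duration_rem=duration_rem,
        duration_light=duration_light,
        duration_deep=duration_deep,
        duration_awake=duration_awake,
        sleep_onset_delay=sleep_onset_delay,
        duration_out_of_bed=duration_out,
        hrv_hf_norm=hf_norm,
        hrv_lf_norm=lf_norm,
        n_awakenings=n_awakenings,
        pct_deep=duration_deep / duration_total,
        pct_rem=duration_rem / duration_total,
        pct_light=duration_light / duration_total,
        sleep_efficiency=duration_asleep / duration_total,
        flags=tuple(flags),
    )


def feature_table(nights: Sequence[NightRecord],
                  min_awakening_epochs: int = 1) -> pd.DataFrame:
    """One row per night: participant, slot date, the 20 parameters, flags."""
    rows = []
    for rec in nights:
        fv = extract_features(rec, min_awakening_epochs=min_awakening_epochs)
        row = {"participant_id": rec.participant_id,
               "night_slot_date": rec.night_slot_date}
        row.update(fv.as_dict())
        row["flags"] = ";".join(fv.flags)
        rows.append(row)
    cols = ["participant_id", "night_slot_date"] + FEATURE_NAMES + ["flags"]
    return pd.DataFrame(rows, columns=cols)
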