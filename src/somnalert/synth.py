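"""Synthetic longitudinal bed-sensor cohort generator.

Emulates the data an under-mattress ballistocardiographic sleep sensor
produces when deployed for months in the homes of community-dwelling older
adults (ages 70-101), together with the weekly self-rated health reports
(EQ-VAS, 0-100) collected by visiting nurses.  The generator provides
ground-truth labels (health episodes, per-night toss-and-turn counts) so the
whole downstream pipeline -- preprocessing, sleep-parameter extraction,
mixed-model ranking and restlessness anomaly detection -- can be exercised
and power-tested without any real cohort data.

Generative structure
--------------------
* Each participant has a random EQ-VAS intercept (between-participant SD
  ``eqvas_intercept_sd``) and a personal baseline toss-and-turn rate drawn
  from a lognormal around ``base_toss_rate_per_30min``.
* A night's hypnogram is a semi-Markov chain over
  {awake-in-bed, light, deep, REM, out-of-bed} with exponential dwell times,
  calibrated so the long-run nightly means land near a realistic elderly
  sleep profile (total ~8.8 h, sleep efficiency ~0.84, ~3 bed exits,
  ~57.6 toss-and-turn events per night).
* Toss-and-turn events are a Poisson process at the participant's rate per
  30-minute in-bed bin, thinned to zero while out of bed, and multiplied by
  ``rate_multiplier`` while a health episode is active.
* Weekly EQ-VAS reports are generated from the single night preceding the
  report: participant intercept + slope * z(toss count) + optional age/sex
  terms + noise, minus a decrement while an episode is active, clamped to
  [0, 100].
* Nights go missing completely at random (sensor connectivity), independent
  of health -- the report stream is unaffected.

Three granularities are exposed: :func:`simulate_dataset` (full event-level
segments), :func:`simulate_matched_cohort` (night-summary feature table for
model-recovery experiments) and :func:`simulate_restlessness_weeks`
(per-30-minute-bin counts for chi-square calibration/power experiments).
They share the same generative parameters.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from datetime import timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

# Hypnogram state codes (shared with features/preprocess).
OUT_OF_BED = 0
AWAKE = 1
LIGHT = 2
DEEP = 3
REM = 4

STATE_NAMES = {
    OUT_OF_BED: "out_of_bed",
    AWAKE: "awake",
    LIGHT: "light",
    DEEP: "deep",
    REM: "rem",
}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}

SLEEP_STATES = (LIGHT, DEEP, REM)

# Semi-Markov defaults (seconds); calibrated against the target nightly
# profile: light ~15500 s, deep ~4600 s, REM ~6550 s, mid-night awake
# ~2600 s over ~2.2 awakenings, ~3 bed exits totalling ~1000 s, sleep onset
# delay ~1450 s, efficiency ~0.84.
_ONSET_MEAN_S = 1446.0
_DWELL_MEAN_S = {LIGHT: 1020.0, DEEP: 1090.0, REM: 1300.0, AWAKE: 1290.0, OUT_OF_BED: 375.0}
_TRANSITIONS = {
    AWAKE: ((LIGHT,), (1.0,)),
    OUT_OF_BED: ((LIGHT,), (1.0,)),
    DEEP: ((LIGHT,), (1.0,)),
    REM: ((LIGHT,), (1.0,)),
    LIGHT: ((DEEP, REM, AWAKE, OUT_OF_BED), (0.30, 0.36, 0.144, 0.196)),
}


class SimConfigError(ValueError):
    """Raised when a :class:`SimConfig` field fails validation."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the statistical scale of a two-cohort Swiss study of
    alone-living older adults: mean age 87 (SD 7, range 70-101), ~67%
    female, EQ-VAS mean ~75, ~57.6 toss-and-turn events per night and ~22%
    of nights lost to connectivity.
    """

    n_participants: int = 45
    nights_per_participant: int = 160
    epoch_seconds: int = 30
    night_window_start: str = "18:00"
    night_window_end: str = "11:00"
    # Toss-and-turn Poisson process: events per 30-minute in-bed bin while
    # healthy.  The pooled nightly mean including the default episode
    # process (stationary episode fraction ~0.087 at multiplier 3.5, i.e. a
    # 1.22x uplift) lands at ~57.6 events over ~17.1 in-bed bins:
    # 57.6 / (17.1 * 1.22) ~= 2.77.
    base_toss_rate_per_30min: float = 2.77
    toss_rate_dispersion: float = 0.6  # between-participant lognormal SD
    toss_night_sd: float = 0.0  # optional between-night lognormal SD
    toss_ar1: float = 0.0  # optional AR(1) coefficient for night effects
    episode_prob_per_night: float = 0.01
    episode_duration_nights: tuple[int, int] = (5, 14)
    episode_rate_multiplier: float = 3.5
    episode_eqvas_decrement: float = 20.0
    eqvas_mean: float = 75.0
    eqvas_slope_per_sd_toss: float = -2.5
    eqvas_intercept_sd: float = 8.0
    eqvas_noise_sd: float = 10.0
    eqvas_age_slope: float = 0.0
    eqvas_sex_effect: float = 0.0
    missing_night_prob: float = 0.22
    nap_prob: float = 0.05
    duplicate_prob: float = 0.02
    short_segment_prob: float = 0.03
    age_mean: float = 87.0
    age_sd: float = 7.0
    age_range: tuple[float, float] = (70.0, 101.0)
    female_fraction: float = 0.67
    start_date: str = "2017-03-01"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = (
            "episode_prob_per_night", "missing_night_prob", "nap_prob",
            "duplicate_prob", "short_segment_prob", "female_fraction",
        )
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        nonneg = (
            "base_toss_rate_per_30min", "toss_rate_dispersion", "toss_night_sd",
            "eqvas_intercept_sd", "eqvas_noise_sd", "episode_eqvas_decrement",
            "age_sd",
        )
        for name in nonneg:
            v = getattr(self, name)
            if v < 0:
                raise SimConfigError(f"{name} must be >= 0, got {v}")
        for name in ("n_participants", "nights_per_participant"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise SimConfigError(f"{name} must be a nonnegative integer, got {v}")
        if self.epoch_seconds <= 0:
            raise SimConfigError(f"epoch_seconds must be positive, got {self.epoch_seconds}")
        if self.episode_rate_multiplier < 1.0:
            raise SimConfigError(
                f"episode_rate_multiplier must be >= 1, got {self.episode_rate_multiplier}")
        lo, hi = self.episode_duration_nights
        if not (1 <= lo <= hi):
            raise SimConfigError(
                f"episode_duration_nights must satisfy 1 <= lo <= hi, got {(lo, hi)}")
        if not (-1.0 < self.toss_ar1 < 1.0):
            raise SimConfigError(f"toss_ar1 must be in (-1, 1), got {self.toss_ar1}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SimConfigError(f"unknown config fields: {sorted(unknown)}")
        for tup in ("episode_duration_nights", "age_range"):
            if tup in raw and isinstance(raw[tup], list):
                raw[tup] = tuple(raw[tup])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["episode_duration_nights"] = list(d["episode_duration_nights"])
        d["age_range"] = list(d["age_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class ParticipantProfile:
    participant_id: str
    age: float
    sex: int  # 0 = female, 1 = male
    eqvas_intercept: float  # grand mean + random intercept u_i
    toss_rate_base: float  # events per 30-minute in-bed bin
    habitual_bedtime: str  # "HH:MM"
    habitual_risetime: str
    hr_base: float = 61.8
    rr_base: float = 14.6
    hrv_lf_scale: float = 1.0


@dataclass
class HealthEpisode:
    participant_id: str
    start_night: pd.Timestamp
    duration_nights: int
    rate_multiplier: float
    eqvas_decrement: float
    label: str = "episode"

    @property
    def end_night(self) -> pd.Timestamp:
        return self.start_night + timedelta(days=self.duration_nights)

    def active_on(self, night: pd.Timestamp) -> bool:
        return self.start_night <= night < self.end_night


@dataclass
class RawSegment:
    """One continuous bed-activity recording.

    ``epoch_states`` covers [segment_start, segment_end) at
    ``epoch_seconds`` resolution; toss events lie inside the segment.
    """

    participant_id: str
    segment_start: pd.Timestamp
    epoch_seconds: int
    epoch_states: np.ndarray  # int8 codes, see STATE_NAMES
    toss_event_times: np.ndarray  # datetime64[ns], sorted
    mean_heart_rate: float
    mean_respiration_rate: float
    interbeat_intervals: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def segment_end(self) -> pd.Timestamp:
        return self.segment_start + timedelta(seconds=int(len(self.epoch_states)) * self.epoch_seconds)

    @property
    def duration_s(self) -> float:
        return len(self.epoch_states) * float(self.epoch_seconds)

    @property
    def segment_id(self) -> str:
        return f"{self.participant_id}:{self.segment_start.isoformat()}"

    def state_runs(self) -> list[tuple[int, int, int]]:
        """Maximal runs of equal state as (state, start_epoch, n_epochs)."""
        s = self.epoch_states
        if len(s) == 0:
            return []
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(s)]))
        return [(int(s[a]), int(a), int(b - a)) for a, b in zip(starts, ends)]

    def in_bed_intervals(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        """Intervals where the person is in bed (any state but out-of-bed)."""
        out: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        for state, a, n in self.state_runs():
            if state != OUT_OF_BED:
                t0 = self.segment_start + timedelta(seconds=a * self.epoch_seconds)
                t1 = t0 + timedelta(seconds=n * self.epoch_seconds)
                if out and out[-1][1] == t0:
                    out[-1] = (out[-1][0], t1)
                else:
                    out.append((t0, t1))
        return out


@dataclass
class HealthReport:
    participant_id: str
    report_date: pd.Timestamp
    eqvas: int
    incident_flag: bool = False
    incident_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.eqvas <= 100:
            raise ValueError(f"eqvas must be in [0, 100], got {self.eqvas}")


@dataclass
class SimDataset:
    """All tables produced by one simulation run."""

    config: SimConfig
    profiles: list[ParticipantProfile]
    episodes: list[HealthEpisode]
    segments: list[RawSegment]
    reports: list[HealthReport]
    nightly_toss: pd.DataFrame  # ground truth: participant_id, night_date, toss_count

    def profiles_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(p) for p in self.profiles])

    def episodes_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.episodes:
            rows.append({
                "participant_id": e.participant_id,
                "start_night": e.start_night.date().isoformat(),
                "duration_nights": e.duration_nights,
                "rate_multiplier": e.rate_multiplier,
                "eqvas_decrement": e.eqvas_decrement,
                "label": e.label,
            })
        cols = ["participant_id", "start_night", "duration_nights",
                "rate_multiplier", "eqvas_decrement", "label"]
        return pd.DataFrame(rows, columns=cols)

    def reports_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.append({
                "participant_id": r.participant_id,
                "report_date": r.report_date.date().isoformat(),
                "eqvas": r.eqvas,
                "incident_flag": r.incident_flag,
                "incident_label": r.incident_label or "",
            })
        cols = ["participant_id", "report_date", "eqvas", "incident_flag", "incident_label"]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# cohort construction


def _participant_rng(seed: int, p_idx: int, n_idx: int = -1) -> np.random.Generator:
    # Stable per-(participant, night) streams: output is independent of the
    # order in which nights are simulated.
    return np.random.default_rng(np.random.SeedSequence([seed, 7919 + p_idx, 104729 + n_idx]))


def make_cohort(config: SimConfig) -> tuple[list[ParticipantProfile], list[HealthEpisode]]:
    """Draw participant profiles and non-overlapping health episodes."""
    config.validate()
    start = pd.Timestamp(config.start_date)
    profiles: list[ParticipantProfile] = []
    episodes: list[HealthEpisode] = []
    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, i)
        pid = f"P{i:03d}"
        lo, hi = config.age_range
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), lo, hi))
        sex = int(rng.random() > config.female_fraction)  # 0=female
        intercept = config.eqvas_mean + rng.normal(0.0, config.eqvas_intercept_sd)
        disp = config.toss_rate_dispersion
        # lognormal with unit mean so the population-average rate is preserved
        rate = config.base_toss_rate_per_30min * float(
            np.exp(rng.normal(-0.5 * disp ** 2, disp))) if disp > 0 else config.base_toss_rate_per_30min
        bed_min = int(np.clip(rng.normal(22 * 60, 25), 20 * 60 + 30, 23 * 60 + 30))
        rise_min = int(np.clip(rng.normal(6 * 60 + 50, 25), 5 * 60 + 30, 9 * 60))
        profiles.append(ParticipantProfile(
            participant_id=pid,
            age=age,
            sex=sex,
            eqvas_intercept=float(intercept),
            toss_rate_base=float(rate),
            habitual_bedtime=f"{bed_min // 60:02d}:{bed_min % 60:02d}",
            habitual_risetime=f"{rise_min // 60:02d}:{rise_min % 60:02d}",
            hr_base=float(np.clip(rng.normal(61.8, 6.0), 45, 90)),
            rr_base=float(np.clip(rng.normal(14.6, 2.6), 8, 25)),
            hrv_lf_scale=float(np.exp(rng.normal(0.0, 0.2))),
        ))
        # episodes: scan nights, skip past an active episode so none overlap
        night = 0
        while night < config.nights_per_participant:
            if rng.random() < config.episode_prob_per_night:
                dur = int(rng.integers(config.episode_duration_nights[0],
                                       config.episode_duration_nights[1] + 1))
                episodes.append(HealthEpisode(
                    participant_id=pid,
                    start_night=start + timedelta(days=night),
                    duration_nights=dur,
                    rate_multiplier=config.episode_rate_multiplier,
                    eqvas_decrement=config.episode_eqvas_decrement,
                    label="episode",
                ))
                night += dur
            else:
                night += 1
    return profiles, episodes


# ---------------------------------------------------------------------------
# night-level simulation


def _draw_hypnogram(rng: np.random.Generator, n_epochs: int, epoch_s: int) -> np.ndarray:
    """Semi-Markov hypnogram: exponential dwell times, fixed transitions."""
    states = np.empty(n_epochs, dtype=np.int8)
    pos = 0
    # sleep onset: initial awake-in-bed run
    dwell = max(1, int(round(rng.exponential(_ONSET_MEAN_S) / epoch_s)))
    take = min(dwell, n_epochs)
    states[:take] = AWAKE
    pos = take
    state = AWAKE
    while pos < n_epochs:
        nxt_states, probs = _TRANSITIONS[state]
        state = nxt_states[rng.choice(len(nxt_states), p=probs)] if len(nxt_states) > 1 else nxt_states[0]
        dwell = max(1, int(round(rng.exponential(_DWELL_MEAN_S[state]) / epoch_s)))
        take = min(dwell, n_epochs - pos)
        states[pos:pos + take] = state
        pos += take
    return states


def _draw_toss_events(rng: np.random.Generator, states: np.ndarray, start: pd.Timestamp,
                      epoch_s: int, rate_per_30min: float) -> np.ndarray:
    """Poisson toss events at the given per-30-min rate, zero out of bed."""
    in_bed = states != OUT_OF_BED
    lam = rate_per_30min / 1800.0 * epoch_s
    counts = rng.poisson(lam, size=len(states)) * in_bed
    total = int(counts.sum())
    if total == 0:
        return np.array([], dtype="datetime64[ns]")
    epoch_idx = np.repeat(np.arange(len(states)), counts)
    offs = (epoch_idx + rng.random(total)) * epoch_s
    offs.sort()
    return (np.datetime64(start) + (offs * 1e9).astype("timedelta64[ns]")).astype("datetime64[ns]")


def _draw_ibis(rng: np.random.Generator, hr_bpm: float, lf_scale: float,
               duration_s: float = 600.0) -> np.ndarray:
    """Interbeat-interval sample with sinusoidal LF (0.1 Hz) and HF (0.25 Hz)
    modulation so normalized band powers are recoverable downstream."""
    rr0 = 60.0 / hr_bpm
    n = int(duration_s / rr0)
    t = np.arange(n) * rr0
    # HF amplitude pre-boosted: the ~1 Hz tachogram low-passes 0.25 Hz more
    # than 0.10 Hz under linear resampling, and the target normalized powers
    # (LF ~44, HF ~56) refer to the extracted spectrum
    a_hf = 0.0355
    a_lf = 0.0265 * lf_scale
    ph1, ph2 = rng.random(2) * 2 * np.pi
    rr = (rr0 + a_lf * np.sin(2 * np.pi * 0.10 * t + ph1)
          + a_hf * np.sin(2 * np.pi * 0.25 * t + ph2)
          + rng.normal(0.0, 0.004, n))
    return np.clip(rr, 0.3, 2.5)


def _hhmm_to_minutes(s: str) -> int:
    h, m = s.split(":")
    return int(h) * 60 + int(m)


def simulate_night(profile: ParticipantProfile, date: pd.Timestamp,
                   active_episode: Optional[HealthEpisode], config: SimConfig,
                   rng: Optional[np.random.Generator] = None,
                   rate_factor: float = 1.0) -> list[RawSegment]:
    """Simulate all recordings assigned to the night ending on ``date``.

    The main recording runs from the participant's (jittered) habitual
    bedtime on the evening before ``date`` to the habitual risetime on
    ``date``.  With the configured probabilities the output additionally
    contains a daytime nap, an exact duplicate of the main recording, or a
    morning re-entry fragment shorter than 5 h; with
    ``short_segment_prob`` the main recording may itself be truncated below
    5 h (sensor dropout).  These extras exist to exercise preprocessing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    date = pd.Timestamp(date).normalize()
    epoch_s = config.epoch_seconds
    mult = active_episode.rate_multiplier if active_episode is not None else 1.0
    rate = profile.toss_rate_base * mult * rate_factor

    bed_min = _hhmm_to_minutes(profile.habitual_bedtime) + int(rng.normal(0, 35))
    rise_min = _hhmm_to_minutes(profile.habitual_risetime) + int(rng.normal(0, 35))
    bed_start = date - timedelta(days=1) + timedelta(minutes=bed_min)
    rise = date + timedelta(minutes=rise_min)
    n_epochs = max(1, int((rise - bed_start).total_seconds() // epoch_s))

    truncated = rng.random() < config.short_segment_prob
    if truncated:
        n_epochs = max(1, int(rng.uniform(2.5, 4.5) * 3600 / epoch_s))

    states = _draw_hypnogram(rng, n_epochs, epoch_s)
    hr = float(np.clip(profile.hr_base + rng.normal(0, 1.5) + (1.5 if active_episode else 0.0), 40, 110))
    rr_rate = float(np.clip(profile.rr_base + rng.normal(0, 0.7) + (0.8 if active_episode else 0.0), 6, 35))
    main = RawSegment(
        participant_id=profile.participant_id,
        segment_start=bed_start,
        epoch_seconds=epoch_s,
        epoch_states=states,
        toss_event_times=_draw_toss_events(rng, states, bed_start, epoch_s, rate),
        mean_heart_rate=hr,
        mean_respiration_rate=rr_rate,
        interbeat_intervals=_draw_ibis(rng, hr, profile.hrv_lf_scale),
    )
    out = [main]

    if rng.random() < config.nap_prob:
        nap_start = date + timedelta(minutes=int(rng.uniform(13 * 60, 14 * 60 + 30)))
        nap_epochs = max(1, int(rng.uniform(0.7, 2.5) * 3600 / epoch_s))
        nap_states = _draw_hypnogram(rng, nap_epochs, epoch_s)
        out.append(RawSegment(
            participant_id=profile.participant_id,
            segment_start=nap_start,
            epoch_seconds=epoch_s,
            epoch_states=nap_states,
            toss_event_times=_draw_toss_events(rng, nap_states, nap_start, epoch_s, rate),
            mean_heart_rate=hr,
            mean_respiration_rate=rr_rate,
            interbeat_intervals=_draw_ibis(rng, hr, profile.hrv_lf_scale, 420.0),
        ))
    if not truncated and rng.random() < config.short_segment_prob:
        # morning re-entry to bed, > 2 h after rising so it stays a separate
        # segment, < 5 h so the duration rule removes it
        frag_start = main.segment_end + timedelta(minutes=int(rng.uniform(125, 160)))
        frag_epochs = max(1, int(rng.uniform(0.5, 1.2) * 3600 / epoch_s))
        if frag_start + timedelta(seconds=frag_epochs * epoch_s) < date + timedelta(hours=11):
            frag_states = _draw_hypnogram(rng, frag_epochs, epoch_s)
            out.append(RawSegment(
                participant_id=profile.participant_id,
                segment_start=frag_start,
                epoch_seconds=epoch_s,
                epoch_states=frag_states,
                toss_event_times=_draw_toss_events(rng, frag_states, frag_start, epoch_s, rate),
                mean_heart_rate=hr,
                mean_respiration_rate=rr_rate,
                interbeat_intervals=_draw_ibis(rng, hr, profile.hrv_lf_scale, 420.0),
            ))
    if rng.random() < config.duplicate_prob:
        out.append(dataclasses.replace(main))
    return out


# ---------------------------------------------------------------------------
# reports and missingness


def clamp_eqvas(x: float) -> int:
    return int(np.clip(round(x), 0, 100))


def simulate_reports(profiles: Sequence[ParticipantProfile],
                     episodes: Sequence[HealthEpisode],
                     nightly_toss_counts: pd.DataFrame,
                     config: SimConfig,
                     rng: Optional[np.random.Generator] = None) -> list[HealthReport]:
    """Weekly EQ-VAS reports driven by the preceding night's toss count.

    ``nightly_toss_counts`` must have columns ``participant_id``,
    ``night_date`` (date of the morning the night ends) and ``toss_count``.
    The toss count is standardized against the pooled simulated counts; a
    report whose preceding night is unavailable gets no sleep term.
    """
    counts = nightly_toss_counts
    if len(counts):
        mu = float(counts["toss_count"].mean())
        sd = float(counts["toss_count"].std(ddof=1))
        sd = sd if sd > 0 else 1.0
        lookup = {(r.participant_id, pd.Timestamp(r.night_date).normalize()): r.toss_count
                  for r in counts.itertuples()}
    else:
        mu, sd, lookup = 0.0, 1.0, {}

    start = pd.Timestamp(config.start_date)
    eps_by_pid: dict[str, list[HealthEpisode]] = {}
    for e in episodes:
        eps_by_pid.setdefault(e.participant_id, []).append(e)

    mean_age = config.age_mean
    reports: list[HealthReport] = []
    for i, prof in enumerate(profiles):
        prng = _participant_rng(config.seed, i, 999_983) if rng is None else rng
        n_weeks = max(1, config.nights_per_participant // 7)
        for w in range(n_weeks):
            jitter = int(prng.integers(-1, 2))
            rdate = start + timedelta(days=7 * w + 3 + jitter)
            active = next((e for e in eps_by_pid.get(prof.participant_id, [])
                           if e.active_on(rdate - timedelta(days=1))), None)
            c = lookup.get((prof.participant_id, rdate.normalize()))
            sleep_term = config.eqvas_slope_per_sd_toss * (c - mu) / sd if c is not None else 0.0
            val = (prof.eqvas_intercept
                   + sleep_term
                   + config.eqvas_age_slope * (prof.age - mean_age)
                   + config.eqvas_sex_effect * prof.sex
                   + prng.normal(0.0, config.eqvas_noise_sd)
                   - (active.eqvas_decrement if active is not None else 0.0))
            reports.append(HealthReport(
                participant_id=prof.participant_id,
                report_date=rdate,
                eqvas=clamp_eqvas(val),
                incident_flag=active is not None,
                incident_label=active.label if active is not None else None,
            ))
    return reports


def night_slot_date(segment_start: pd.Timestamp, window_start: str = "18:00") -> pd.Timestamp:
    """Date of the morning a recording's night slot ends on."""
    start_min = _hhmm_to_minutes(window_start)
    minute = segment_start.hour * 60 + segment_start.minute
    d = segment_start.normalize()
    return d + timedelta(days=1) if minute >= start_min else d


def apply_missingness(segments: Sequence[RawSegment], config: SimConfig,
                      rng: Optional[np.random.Generator] = None) -> list[RawSegment]:
    """Drop whole nights completely at random (connectivity loss).

    The drop decision is a deterministic function of (seed, participant,
    night slot) and never consults health state, so missingness is MCAR.
    """
    if config.missing_night_prob <= 0:
        return list(segments)
    if config.missing_night_prob >= 1:
        return []
    keep: list[RawSegment] = []
    decisions: dict[tuple[str, pd.Timestamp], bool] = {}
    for seg in segments:
        key = (seg.participant_id, night_slot_date(seg.segment_start))
        if key not in decisions:
            if rng is None:
                digest = zlib.crc32(f"{key[0]}|{key[1].isoformat()}".encode())
                h = np.random.default_rng(np.random.SeedSequence(
                    [config.seed, 15485863, digest]))
                decisions[key] = h.random() >= config.missing_night_prob
            else:
                decisions[key] = rng.random() >= config.missing_night_prob
        if decisions[key]:
            keep.append(seg)
    return keep


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Full event-level simulation of a cohort (deterministic in the seed)."""
    profiles, episodes = make_cohort(config)
    eps_by_pid: dict[str, list[HealthEpisode]] = {}
    for e in episodes:
        eps_by_pid.setdefault(e.participant_id, []).append(e)
    start = pd.Timestamp(config.start_date)

    segments: list[RawSegment] = []
    toss_rows = []
    for i, prof in enumerate(profiles):
        # optional AR(1) night effect on the log rate (defaults off)
        factors = np.ones(config.nights_per_participant)
        if config.toss_night_sd > 0:
            arng = _participant_rng(config.seed, i, 999_979)
            rho, sd = config.toss_ar1, config.toss_night_sd
            innov_sd = sd * np.sqrt(1 - rho ** 2) if abs(rho) > 0 else sd
            x = 0.0
            logs = np.empty(config.nights_per_participant)
            for n in range(config.nights_per_participant):
                x = rho * x + arng.normal(0.0, innov_sd) if n else arng.normal(0.0, sd)
                logs[n] = x
            factors = np.exp(logs - 0.5 * config.toss_night_sd ** 2)
        for n in range(config.nights_per_participant):
            date = start + timedelta(days=n + 1)
            active = next((e for e in eps_by_pid.get(prof.participant_id, [])
                           if e.active_on(date - timedelta(days=1))), None)
            rng = _participant_rng(config.seed, i, n)
            segs = simulate_night(prof, date, active, config, rng, rate_factor=float(factors[n]))
            segments.extend(segs)
            toss_rows.append({
                "participant_id": prof.participant_id,
                "night_date": date,
                "toss_count": int(len(segs[0].toss_event_times)),
            })
    nightly = pd.DataFrame(toss_rows, columns=["participant_id", "night_date", "toss_count"])
    reports = simulate_reports(profiles, episodes, nightly, config)
    segments = apply_missingness(segments, config)
    return SimDataset(config=config, profiles=profiles, episodes=episodes,
                      segments=segments, reports=reports, nightly_toss=nightly)


# ---------------------------------------------------------------------------
# fast night-summary paths


#: Means and SDs used for the 19 non-toss nightly sleep parameters in the
#: summary-level generator (realistic elderly-cohort scale).
SUMMARY_FEATURES = {
    "duration_total": (31823.0, 5776.0),
    "duration_in_bed": (30788.0, 5607.0),
    "avg_heart_rate": (61.83, 6.32),
    "avg_respiration_rate": (14.60, 2.78),
    "n_bed_exits": (3.01, 2.50),
    "duration_asleep": (26730.0, 5474.0),
    "duration_rem": (6546.0, 2059.0),
    "duration_light": (15575.0, 3227.0),
    "duration_deep": (4608.0, 1665.0),
    "duration_awake": (4959.0, 2041.0),
    "sleep_onset_delay": (1446.0, 763.0),
    "duration_out_of_bed": (1034.0, 914.0),
    "hrv_hf_norm": (56.00, 11.35),
    "hrv_lf_norm": (43.62, 11.13),
    "n_awakenings": (2.22, 1.44),
    "pct_deep": (0.14, 0.04),
    "pct_rem": (0.21, 0.05),
    "pct_light": (0.49, 0.06),
    "sleep_efficiency": (0.84, 0.07),
}

#: Expected number of in-bed 30-minute bins per night under the defaults.
EXPECTED_BINS_PER_NIGHT = 30788.0 / 1800.0


def simulate_matched_cohort(config: SimConfig,
                            reports_per_participant: int = 26,
                            rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Night-summary cohort for model-recovery experiments.

    Returns one row per weekly report with the participant's age/sex, the
    EQ-VAS response and the 20 raw (unstandardized) sleep parameters of the
    preceding night.  Only the toss-and-turn count carries signal: the 19
    other parameters are drawn as independent noise on a realistic scale, so
    the ranking stage can be power-tested for recovering the true driver.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    lo, hi = config.age_range
    disp = config.toss_rate_dispersion
    mean_bins = EXPECTED_BINS_PER_NIGHT
    for i in range(config.n_participants):
        pid = f"P{i:03d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), lo, hi))
        sex = int(rng.random() > config.female_fraction)
        intercept = config.eqvas_mean + rng.normal(0.0, config.eqvas_intercept_sd)
        rate = config.base_toss_rate_per_30min * (
            float(np.exp(rng.normal(-0.5 * disp ** 2, disp))) if disp > 0 else 1.0)
        toss = rng.poisson(rate * mean_bins, size=reports_per_participant)
        for w in range(reports_per_participant):
            row = {"participant_id": pid, "age": age, "sex": sex, "week": w,
                   "n_toss_turns": int(toss[w]), "_intercept": intercept}
            for name, (m, s) in SUMMARY_FEATURES.items():
                row[name] = rng.normal(m, s)
            rows.append(row)
    df = pd.DataFrame(rows)
    z = (df["n_toss_turns"] - df["n_toss_turns"].mean()) / df["n_toss_turns"].std(ddof=1)
    raw = (df["_intercept"]
           + config.eqvas_slope_per_sd_toss * z
           + config.eqvas_age_slope * (df["age"] - config.age_mean)
           + config.eqvas_sex_effect * df["sex"]
           + rng.normal(0.0, config.eqvas_noise_sd, len(df)))
    df["eqvas"] = np.clip(np.round(raw), 0, 100).astype(int)
    return df.drop(columns=["_intercept"])


def simulate_restlessness_weeks(config: SimConfig,
                                n_weeks: int = 16,
                                bins_per_night: int = 17,
                                rng: Optional[np.random.Generator] = None
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin toss counts plus weekly EQ-VAS, for restlessness experiments.

    Returns ``(bins, reports)``: ``bins`` has one row per (participant,
    night, bin) with the Poisson toss count; ``reports`` one weekly EQ-VAS
    row per participant.  Health episodes raise the Poisson rate by the
    configured multiplier on affected nights and subtract the configured
    EQ-VAS decrement from reports in affected weeks, tying restlessness
    nonstationarity to self-rated health exactly as the event-level
    generator does.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    disp = config.toss_rate_dispersion
    n_nights = n_weeks * 7
    bin_rows = []
    rep_rows = []
    for i in range(config.n_participants):
        pid = f"P{i:03d}"
        intercept = config.eqvas_mean + rng.normal(0.0, config.eqvas_intercept_sd)
        rate = config.base_toss_rate_per_30min * (
            float(np.exp(rng.normal(-0.5 * disp ** 2, disp))) if disp > 0 else 1.0)
        # episode nights
        mult = np.ones(n_nights)
        night = 0
        while night < n_nights:
            if rng.random() < config.episode_prob_per_night:
                dur = int(rng.integers(config.episode_duration_nights[0],
                                       config.episode_duration_nights[1] + 1))
                mult[night:night + dur] = config.episode_rate_multiplier
                night += dur
            else:
                night += 1
        counts = rng.poisson(np.repeat(rate * mult, bins_per_night)).reshape(n_nights, bins_per_night)
        for n in range(n_nights):
            for b in range(bins_per_night):
                bin_rows.append((pid, n, b, counts[n, b]))
        for w in range(n_weeks):
            wk = slice(7 * w, 7 * w + 7)
            episode_frac = float((mult[wk] > 1).mean())
            val = (intercept + rng.normal(0.0, config.eqvas_noise_sd)
                   - config.episode_eqvas_decrement * episode_frac)
            rep_rows.append((pid, w, clamp_eqvas(val), episode_frac > 0))
    bins = pd.DataFrame(bin_rows, columns=["participant_id", "night", "bin", "count"])
    reports = pd.DataFrame(rep_rows, columns=["participant_id", "week", "eqvas", "incident_flag"])
    return bins, reports
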