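"""Night preprocessing: segment assembly, filtering, standardization, matching.

A raw export contains many bed-activity recordings per participant:
genuine nights, daytime naps, duplicated uploads and short fragments.  This
module turns them into at most one quality-controlled ``NightRecord`` per
(participant, night slot) by applying, in order,

1. the night-window rule (recording must start between 18:00 and 11:00 the
   next morning and end by 11:00 -- excludes daytime naps),
2. the minimum-duration rule (> 5 h),
3. exact-duplicate removal (near-duplicates with > 90% overlap are removed
   too, logged separately),
4. longest-recording-per-slot selection,

and then matches each weekly health report to the night ending on the
report's calendar morning.  Feature standardization (pooled z-scaling used
by the cohort-level mixed models) also lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .synth import OUT_OF_BED, RawSegment, night_slot_date, _hhmm_to_minutes


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    night_window_start: str = "18:00"  # clock time, evening
    night_window_end: str = "11:00"  # clock time, next morning
    min_duration_h: float = 5.0
    max_out_of_bed_gap_h: float = 2.0
    overlap_duplicate_frac: float = 0.9
    morning_fallback_days: int = 0  # optional 1-day-back report matching

    def __post_init__(self) -> None:
        if self.min_duration_h <= 0:
            raise PreprocessError("min_duration_h must be positive")
        if self.max_out_of_bed_gap_h <= 0:
            raise PreprocessError("max_out_of_bed_gap_h must be positive")


@dataclass
class NightRecord:
    participant_id: str
    night_slot_date: pd.Timestamp  # date of the morning the night ends
    segment: RawSegment
    quality_flags: set = field(default_factory=set)


@dataclass
class ExclusionLog:
    """Per-rule exclusion tallies, in rule application order."""

    n_input: int = 0
    night_window: int = 0
    min_duration: int = 0
    duplicate: int = 0
    near_duplicate: int = 0
    longest_per_slot: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - (self.night_window + self.min_duration
                               + self.duplicate + self.near_duplicate
                               + self.longest_per_slot)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "night_window": self.night_window,
            "min_duration": self.min_duration,
            "duplicate": self.duplicate,
            "near_duplicate": self.near_duplicate,
            "longest_per_slot": self.longest_per_slot,
            "n_retained": self.n_retained,
        }


# ---------------------------------------------------------------------------
# segment assembly


def assemble_segments(epochs: pd.DataFrame, config: Optional[PreprocessConfig] = None,
                      events: Optional[pd.DataFrame] = None,
                      epoch_seconds: int = 30) -> list[RawSegment]:
    """Merge a per-epoch activity stream into continuous segments.

    ``epochs`` needs columns ``participant_id``, ``timestamp`` (epoch start)
    and ``state`` (names as in :data:`somnalert.synth.STATE_NAMES`); rows
    must be sorted by time within participant and non-overlapping.  Bed
    runs separated by more than ``max_out_of_bed_gap_h`` of out-of-bed time
    (or by a recording hole) start a new segment.  ``events`` optionally
    carries toss events (``participant_id``, ``event_time``) that are
    attached to the enclosing segment.
    """
    from .synth import STATE_CODES

    config = config or PreprocessConfig()
    max_gap = timedelta(hours=config.max_out_of_bed_gap_h)
    out: list[RawSegment] = []
    for pid, grp in epochs.groupby("participant_id", sort=True):
        ts = pd.to_datetime(grp["timestamp"]).to_numpy()
        if len(ts) > 1 and (np.diff(ts) < np.timedelta64(0, "s")).any():
            raise PreprocessError(f"epoch stream for {pid} is not sorted by time")
        if len(ts) > 1 and (np.diff(ts) < np.timedelta64(epoch_seconds, "s")).any():
            raise PreprocessError(f"overlapping epochs for {pid}")
        codes = grp["state"].map(STATE_CODES).to_numpy(dtype=np.int8)

        # split where the out-of-bed gap (recording hole or contiguous
        # out-of-bed run) exceeds the limit
        splits = [0]
        last_in_bed: Optional[np.datetime64] = None
        for k in range(len(ts)):
            if codes[k] != OUT_OF_BED:
                if last_in_bed is not None and (ts[k] - last_in_bed) > np.timedelta64(int(max_gap.total_seconds()), "s"):
                    splits.append(k)
                last_in_bed = ts[k] + np.timedelta64(epoch_seconds, "s")
        splits.append(len(ts))

        ev_times = None
        if events is not None:
            sub = events[events["participant_id"] == pid]
            ev_times = pd.to_datetime(sub["event_time"]).sort_values().to_numpy()

        for a, b in zip(splits[:-1], splits[1:]):
            # trim leading/trailing out-of-bed epochs: a segment is bed activity
            seg_codes = codes[a:b]
            nz = np.flatnonzero(seg_codes != OUT_OF_BED)
            if len(nz) == 0:
                continue
            a2, b2 = a + nz[0], a + nz[-1] + 1
            start = pd.Timestamp(ts[a2])
            n = b2 - a2
            # rebuild a dense state array; recording holes count as out-of-bed
            dense_len = int((ts[b2 - 1] - ts[a2]) / np.timedelta64(epoch_seconds, "s")) + 1
            dense = np.full(dense_len, OUT_OF_BED, dtype=np.int8)
            idx = ((ts[a2:b2] - ts[a2]) / np.timedelta64(epoch_seconds, "s")).astype(int)
            dense[idx] = codes[a2:b2]
            end = start + timedelta(seconds=dense_len * epoch_seconds)
            if ev_times is not None:
                mask = (ev_times >= np.datetime64(start)) & (ev_times < np.datetime64(end))
                toss = ev_times[mask].astype("datetime64[ns]")
            else:
                toss = np.array([], dtype="datetime64[ns]")
            out.append(RawSegment(
                participant_id=pid,
                segment_start=start,
                epoch_seconds=epoch_seconds,
                epoch_states=dense,
                toss_event_times=toss,
                mean_heart_rate=float(grp["mean_heart_rate"].iloc[0]) if "mean_heart_rate" in grp else np.nan,
                mean_respiration_rate=float(grp["mean_respiration_rate"].iloc[0]) if "mean_respiration_rate" in grp else np.nan,
            ))
    return out


# ---------------------------------------------------------------------------
# night filtering


def _in_night_window(seg: RawSegment, config: PreprocessConfig) -> bool:
    """Recording must start in [18:00 d, 11:00 d+1) and end by 11:00 d+1."""
    ws = _hhmm_to_minutes(config.night_window_start)
    we = _hhmm_to_minutes(config.night_window_end)
    start_min = seg.segment_start.hour * 60 + seg.segment_start.minute
    if start_min >= ws:
        slot_end = seg.segment_start.normalize() + timedelta(days=1, minutes=we)
    elif start_min < we:
        slot_end = seg.segment_start.normalize() + timedelta(minutes=we)
    else:
        return False  # daytime start
    return seg.segment_end <= slot_end


def filter_nights(segments: Sequence[RawSegment],
                  config: Optional[PreprocessConfig] = None
                  ) -> tuple[list[NightRecord], ExclusionLog]:
    """Apply the night-filtering rules in order; returns records + tallies."""
    config = config or PreprocessConfig()
    log = ExclusionLog(n_input=len(segments))

    stage = []
    for seg in segments:
        if _in_night_window(seg, config):
            stage.append(seg)
        else:
            log.night_window += 1

    min_s = config.min_duration_h * 3600.0
    stage2 = []
    for seg in stage:
        if seg.duration_s > min_s:
            stage2.append(seg)
        else:
            log.min_duration += 1

    # exact duplicates: identical (participant, start, end)
    seen: set[tuple] = set()
    stage3 = []
    for seg in sorted(stage2, key=lambda s: (s.participant_id, s.segment_start, s.segment_end)):
        key = (seg.participant_id, seg.segment_start, seg.segment_end)
        if key in seen:
            log.duplicate += 1
        else:
            seen.add(key)
            stage3.append(seg)

    # near-duplicates: > overlap_duplicate_frac of the shorter one overlaps
    # the longer; the shorter is discarded
    stage4 = []
    by_pid: dict[str, list[RawSegment]] = {}
    for seg in stage3:
        by_pid.setdefault(seg.participant_id, []).append(seg)
    for pid, segs in sorted(by_pid.items()):
        segs = sorted(segs, key=lambda s: (-s.duration_s, s.segment_start))
        kept: list[RawSegment] = []
        for seg in segs:
            dup = False
            for other in kept:
                o = (min(seg.segment_end, other.segment_end)
                     - max(seg.segment_start, other.segment_start)).total_seconds()
                if o > 0 and o / seg.duration_s > config.overlap_duplicate_frac:
                    dup = True
                    break
            if dup:
                log.near_duplicate += 1
            else:
                kept.append(seg)
        stage4.extend(kept)

    # longest per slot; ties broken by earlier start for determinism
    best: dict[tuple, RawSegment] = {}
    for seg in stage4:
        slot = (seg.participant_id, night_slot_date(seg.segment_start, config.night_window_start))
        cur = best.get(slot)
        if cur is None or (seg.duration_s, -seg.segment_start.value) > (cur.duration_s, -cur.segment_start.value):
            if cur is not None:
                log.longest_per_slot += 1
            best[slot] = seg
        else:
            log.longest_per_slot += 1

    records = [NightRecord(participant_id=pid, night_slot_date=slot, segment=seg)
               for (pid, slot), seg in sorted(best.items())]
    return records, log


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardization:
    """Pooled z-transform parameters (mean/SD per feature column)."""

    means: pd.Series
    sds: pd.Series
    constant_columns: list[str]

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.means.index:
            if col in self.constant_columns:
                out[col] = 0.0
            else:
                out[col] = (out[col] - self.means[col]) / self.sds[col]
        return out


def standardize(table: pd.DataFrame,
                columns: Optional[Iterable[str]] = None) -> tuple[pd.DataFrame, Standardization]:
    """Z-scale feature columns to zero mean / unit SD pooled over all nights.

    Constant columns become all-zeros and are flagged rather than erroring.
    Non-numeric columns are passed through untouched.
    """
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c]) and c not in ("age", "sex", "eqvas")]
    columns = list(columns)
    if len(table) < 2:
        raise PreprocessError("standardization needs at least 2 rows")
    means = table[columns].mean()
    sds = table[columns].std(ddof=1)
    constant = [c for c in columns if not np.isfinite(sds[c]) or sds[c] == 0.0]
    sds = sds.replace(0.0, 1.0).fillna(1.0)
    params = Standardization(means=means, sds=sds, constant_columns=constant)
    return params.apply(table), params


# ---------------------------------------------------------------------------
# report matching


def match_reports(features: pd.DataFrame, reports: pd.DataFrame,
                  config: Optional[PreprocessConfig] = None) -> tuple[pd.DataFrame, dict]:
    """Match each weekly report to the night ending on its calendar morning.

    ``features`` must carry ``participant_id`` and ``night_slot_date``;
    ``reports`` must carry ``participant_id``, ``report_date`` and
    ``eqvas``.  A report without a record for its morning (optionally
    falling back ``morning_fallback_days`` days) stays unmatched and is
    only counted.  Returns the matched table plus counts.
    """
    config = config or PreprocessConfig()
    feats = features.copy()
    feats["night_slot_date"] = pd.to_datetime(feats["night_slot_date"]).dt.normalize()
    reps = reports.copy()
    reps["report_date"] = pd.to_datetime(reps["report_date"]).dt.normalize()

    index = {(r.participant_id, r.night_slot_date): i
             for i, r in enumerate(feats.itertuples())}
    rows = []
    n_unmatched = 0
    for rep in reps.itertuples():
        hit = None
        for back in range(config.morning_fallback_days + 1):
            hit = index.get((rep.participant_id, rep.report_date - timedelta(days=back)))
            if hit is not None:
                break
        if hit is None:
            n_unmatched += 1
            continue
        row = feats.iloc[hit].to_dict()
        row["report_date"] = rep.report_date
        row["eqvas"] = rep.eqvas
        rows.append(row)
    matched = pd.DataFrame(rows)
    stats = {
        "n_reports": len(reps),
        "n_matched": len(matched),
        "n_unmatched": n_unmatched,
        "n_participants_retained": matched["participant_id"].nunique() if len(matched) else 0,
    }
    return matched, stats
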