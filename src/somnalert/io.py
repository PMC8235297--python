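"""CSV serialization of datasets (long-format epochs, events, tables).

All timestamps are written as timezone-naive local ISO-8601 strings.  The
segment stream is split across three files so users can substitute real
sensor exports for the simulator:

* ``epochs.csv`` — participant_id, segment_id, timestamp, state
* ``toss_events.csv`` — participant_id, segment_id, event_time
* ``segments_meta.csv`` — per-segment vitals
* ``ibis.csv`` — participant_id, segment_id, ibi_s (interbeat intervals)
"""

from __future__ import annotations

from datetime import timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import STATE_CODES, STATE_NAMES, RawSegment, SimDataset


def segments_to_frames(segments: Sequence[RawSegment]) -> dict[str, pd.DataFrame]:
    ep_rows, ev_rows, meta_rows, ibi_rows = [], [], [], []
    seen: dict[str, int] = {}
    for seg in segments:
        sid = seg.segment_id
        # exact duplicates share a natural id; disambiguate for round-trip
        k = seen.get(sid, 0)
        seen[sid] = k + 1
        if k:
            sid = f"{sid}#dup{k}"
        ts = pd.date_range(seg.segment_start, periods=len(seg.epoch_states),
                           freq=f"{seg.epoch_seconds}s")
        ep_rows.append(pd.DataFrame({
            "participant_id": seg.participant_id,
            "segment_id": sid,
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
            "state": [STATE_NAMES[s] for s in seg.epoch_states],
        }))
        if len(seg.toss_event_times):
            ev_rows.append(pd.DataFrame({
                "participant_id": seg.participant_id,
                "segment_id": sid,
                "event_time": pd.DatetimeIndex(seg.toss_event_times).strftime(
                    "%Y-%m-%dT%H:%M:%S.%f"),
            }))
        meta_rows.append({
            "participant_id": seg.participant_id,
            "segment_id": sid,
            "segment_start": seg.segment_start.isoformat(),
            "epoch_seconds": seg.epoch_seconds,
            "n_epochs": len(seg.epoch_states),
            "mean_heart_rate": seg.mean_heart_rate,
            "mean_respiration_rate": seg.mean_respiration_rate,
        })
        if len(seg.interbeat_intervals):
            ibi_rows.append(pd.DataFrame({
                "participant_id": seg.participant_id,
                "segment_id": sid,
                "ibi_s": np.round(seg.interbeat_intervals, 6),
            }))
    empty_ep = pd.DataFrame(columns=["participant_id", "segment_id", "timestamp", "state"])
    empty_ev = pd.DataFrame(columns=["participant_id", "segment_id", "event_time"])
    empty_ibi = pd.DataFrame(columns=["participant_id", "segment_id", "ibi_s"])
    return {
        "epochs": pd.concat(ep_rows, ignore_index=True) if ep_rows else empty_ep,
        "toss_events": pd.concat(ev_rows, ignore_index=True) if ev_rows else empty_ev,
        "segments_meta": pd.DataFrame(meta_rows),
        "ibis": pd.concat(ibi_rows, ignore_index=True) if ibi_rows else empty_ibi,
    }


def segments_from_frames(frames: dict[str, pd.DataFrame]) -> list[RawSegment]:
    epochs = frames["epochs"]
    events = frames.get("toss_events")
    ibis = frames.get("ibis")
    meta = frames["segments_meta"].set_index("segment_id")
    segs: list[RawSegment] = []
    ev_by_sid = dict(tuple(events.groupby("segment_id"))) if events is not None and len(events) else {}
    ibi_by_sid = dict(tuple(ibis.groupby("segment_id"))) if ibis is not None and len(ibis) else {}
    for sid, grp in epochs.groupby("segment_id", sort=False):
        m = meta.loc[sid]
        codes = grp["state"].map(STATE_CODES).to_numpy(dtype=np.int8)
        ev = ev_by_sid.get(sid)
        toss = (pd.to_datetime(ev["event_time"]).sort_values().to_numpy().astype("datetime64[ns]")
                if ev is not None else np.array([], dtype="datetime64[ns]"))
        ib = ibi_by_sid.get(sid)
        segs.append(RawSegment(
            participant_id=str(m["participant_id"]),
            segment_start=pd.Timestamp(m["segment_start"]),
            epoch_seconds=int(m["epoch_seconds"]),
            epoch_states=codes,
            toss_event_times=toss,
            mean_heart_rate=float(m["mean_heart_rate"]),
            mean_respiration_rate=float(m["mean_respiration_rate"]),
            interbeat_intervals=ib["ibi_s"].to_numpy(dtype=float) if ib is not None else np.empty(0),
        ))
    segs.sort(key=lambda s: (s.participant_id, s.segment_start))
    return segs


def write_dataset(dataset: SimDataset, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = segments_to_frames(dataset.segments)
    frames["profiles"] = dataset.profiles_frame()
    frames["episodes"] = dataset.episodes_frame()
    frames["reports"] = dataset.reports_frame()
    nightly = dataset.nightly_toss.copy()
    nightly["night_date"] = pd.to_datetime(nightly["night_date"]).dt.strftime("%Y-%m-%d")
    frames["nightly_toss"] = nightly
    paths = []
    for name, df in frames.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


def read_segments(datadir) -> list[RawSegment]:
    datadir = Path(datadir)
    frames = {"epochs": pd.read_csv(datadir / "epochs.csv"),
              "segments_meta": pd.read_csv(datadir / "segments_meta.csv")}
    for opt in ("toss_events", "ibis"):
        p = datadir / f"{opt}.csv"
        if p.exists():
            frames[opt] = pd.read_csv(p)
    return segments_from_frames(frames)
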