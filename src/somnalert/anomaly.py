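"""Toss-and-turn restlessness anomaly layer.

Treats nightly toss-and-turn events as a Poisson process.  Under stable
health the process is homogeneous; health changes make it nonstationary.
Weekly, per participant, events are counted in 30-minute in-bed bins, the
rate lambda is estimated by maximum likelihood (the bin-count mean) and a
chi-square goodness-of-fit statistic compares the observed histogram of
per-bin counts f_o with the Poisson expectation f_e.  A homogeneous week
gives a small statistic; mixtures of calm and restless nights inflate it,
so a raw threshold (default 1000) drives automated alerts.

Screening rules used in case review are also provided: a fixed per-night
count threshold (default 200 toss-and-turns), local-peak detection against
a trailing 14-night moving average, and sustained-trend detection against a
baseline median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import RawSegment


class AnomalyError(ValueError):
    pass


@dataclass
class AnomalyConfig:
    ma_window: int = 14  # nights, moving average
    point_threshold: float = 200.0  # toss-and-turns per night
    peak_multiple: float = 3.0  # local peak = count > multiple * trailing MA
    bin_width_s: float = 1800.0  # 30-minute bins
    week_nights: int = 7
    chisq_alert_threshold: float = 1000.0
    min_bins_per_week: int = 100
    min_bin_coverage: float = 0.5  # drop bins with < 50% in-bed coverage
    trend_baseline_nights: int = 28
    trend_rel_increase: float = 0.5
    dispersion_variant: bool = False  # sum (n_i - lam)^2 / lam instead of GOF

    def __post_init__(self) -> None:
        if self.ma_window < 2:
            raise AnomalyError("ma_window must be >= 2")
        if self.chisq_alert_threshold <= 0:
            raise AnomalyError("chisq_alert_threshold must be positive")
        if self.bin_width_s <= 0:
            raise AnomalyError("bin_width_s must be positive")


@dataclass
class RestlessnessStat:
    participant_id: str
    week_start: pd.Timestamp
    lambda_hat: float
    f_obs: np.ndarray
    f_exp: np.ndarray
    chisq: float
    log_chisq: float
    dof: int
    n_bins: int
    alert: bool
    defined: bool = True
    flags: tuple = ()


# ---------------------------------------------------------------------------
# binning


def bin_counts(toss_event_times: np.ndarray,
               in_bed_intervals: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
               config: Optional[AnomalyConfig] = None) -> tuple[np.ndarray, int]:
    """Per-bin toss counts over a night's in-bed time.

    Bins of ``bin_width_s`` are anchored at the first in-bed instant; bins
    covered less than ``min_bin_coverage`` by in-bed time are dropped.
    Bins are half-open, so an event on an edge belongs to the later bin.
    Returns (counts, n_events_outside_intervals).
    """
    config = config or AnomalyConfig()
    if not in_bed_intervals:
        return np.empty(0, dtype=int), int(len(toss_event_times))
    t0 = min(a for a, _ in in_bed_intervals)
    t1 = max(b for _, b in in_bed_intervals)
    width = config.bin_width_s
    span = (t1 - t0).total_seconds()
    n_bins = int(np.ceil(span / width)) if span > 0 else 0
    if n_bins == 0:
        return np.empty(0, dtype=int), int(len(toss_event_times))

    edges = np.arange(n_bins + 1) * width
    coverage = np.zeros(n_bins)
    for a, b in in_bed_intervals:
        lo = (a - t0).total_seconds()
        hi = (b - t0).total_seconds()
        left = np.clip(hi, edges[:-1], edges[1:]) - np.clip(lo, edges[:-1], edges[1:])
        coverage += np.maximum(left, 0.0)
    keep = coverage / width >= config.min_bin_coverage

    ev = np.asarray(toss_event_times)
    if len(ev):
        offs = (ev - np.datetime64(t0)) / np.timedelta64(1, "s")
        inside = np.zeros(len(ev), dtype=bool)
        for a, b in in_bed_intervals:
            lo = (a - t0).total_seconds()
            hi = (b - t0).total_seconds()
            inside |= (offs >= lo) & (offs < hi)
        n_outside = int((~inside).sum())
        idx = np.floor(offs[inside] / width).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts = np.bincount(idx, minlength=n_bins)
    else:
        counts = np.zeros(n_bins, dtype=int)
        n_outside = 0
    return counts[keep].astype(int), n_outside


def night_bin_counts(segment: RawSegment, config: Optional[AnomalyConfig] = None) -> np.ndarray:
    counts, _ = bin_counts(segment.toss_event_times, segment.in_bed_intervals(), config)
    return counts


# ---------------------------------------------------------------------------
# the restlessness statistic


def poisson_chisq(per_bin_counts: np.ndarray,
                  config: Optional[AnomalyConfig] = None,
                  participant_id: str = "", week_start=None,
                  enforce_min_bins: bool = True) -> RestlessnessStat:
    """Poisson goodness-of-fit chi-square for one week of bin counts.

    lambda is the MLE (mean count); observed frequencies f_o of each count
    value are compared with n_bins * Poisson pmf, the upper tail pooled
    until every cell expects at least one observation; dof = cells - 2.
    All-zero weeks define chi-square as 0 (flagged); weeks with fewer than
    ``min_bins_per_week`` bins yield an undefined-statistic marker.
    """
    config = config or AnomalyConfig()
    counts = np.asarray(per_bin_counts, dtype=int)
    n_bins = len(counts)
    week_start = pd.Timestamp(week_start) if week_start is not None else pd.NaT

    def marker(flag: str) -> RestlessnessStat:
        return RestlessnessStat(participant_id=participant_id, week_start=week_start,
                                lambda_hat=np.nan, f_obs=np.empty(0), f_exp=np.empty(0),
                                chisq=np.nan, log_chisq=np.nan, dof=0, n_bins=n_bins,
                                alert=False, defined=False, flags=(flag,))

    if enforce_min_bins and n_bins < config.min_bins_per_week:
        return marker("too_few_bins")
    if n_bins == 0:
        return marker("no_bins")

    lam = float(counts.mean())
    if lam == 0.0:
        return RestlessnessStat(participant_id=participant_id, week_start=week_start,
                                lambda_hat=0.0, f_obs=np.array([n_bins]),
                                f_exp=np.array([float(n_bins)]), chisq=0.0,
                                log_chisq=-np.inf, dof=0, n_bins=n_bins,
                                alert=False, defined=True, flags=("all_zero",))

    if config.dispersion_variant:
        chisq = float(((counts - lam) ** 2 / lam).sum())
        f_obs = np.bincount(counts)
        f_exp = n_bins * stats.poisson.pmf(np.arange(len(f_obs)), lam)
        dof = n_bins - 1
    else:
        kmax = int(counts.max())
        f_obs = np.bincount(counts, minlength=kmax + 1).astype(float)
        pmf = stats.poisson.pmf(np.arange(kmax + 1), lam)
        f_exp = n_bins * pmf
        f_exp[-1] = n_bins * float(stats.poisson.sf(kmax - 1, lam))  # tail mass >= kmax
        # pool the upper tail until each remaining cell expects >= 1
        while len(f_exp) > 1 and f_exp[-1] < 1.0:
            f_exp[-2] += f_exp[-1]
            f_obs[-2] += f_obs[-1]
            f_exp = f_exp[:-1]
            f_obs = f_obs[:-1]
        chisq = float(((f_obs - f_exp) ** 2 / f_exp).sum())
        dof = max(len(f_obs) - 2, 0)

    return RestlessnessStat(
        participant_id=participant_id, week_start=week_start, lambda_hat=lam,
        f_obs=f_obs, f_exp=f_exp, chisq=chisq,
        log_chisq=float(np.log(chisq)) if chisq > 0 else -np.inf,
        dof=dof, n_bins=n_bins, alert=chisq > config.chisq_alert_threshold,
        defined=True,
    )


def weekly_restlessness_series(nights: pd.DataFrame,
                               config: Optional[AnomalyConfig] = None
                               ) -> list[RestlessnessStat]:
    """Weekly restlessness statistics for every participant.

    ``nights`` needs one row per (participant, night) with columns
    ``participant_id``, ``night_slot_date`` and ``bin_counts`` (sequence of
    per-bin toss counts for that night).  Weeks are non-overlapping 7-night
    windows aligned to each participant's first measured night; weeks with
    fewer than ``min_bins_per_week`` measured bins emit undefined markers.
    """
    config = config or AnomalyConfig()
    out: list[RestlessnessStat] = []
    for pid, grp in nights.groupby("participant_id", sort=True):
        grp = grp.sort_values("night_slot_date")
        dates = pd.to_datetime(grp["night_slot_date"]).dt.normalize()
        first = dates.iloc[0]
        last = dates.iloc[-1]
        n_weeks = int((last - first).days // config.week_nights) + 1
        for w in range(n_weeks):
            w0 = first + timedelta(days=w * config.week_nights)
            w1 = w0 + timedelta(days=config.week_nights)
            mask = (dates >= w0) & (dates < w1)
            if mask.any():
                counts = np.concatenate([np.asarray(c, dtype=int)
                                         for c in grp.loc[mask.to_numpy(), "bin_counts"]])
            else:
                counts = np.empty(0, dtype=int)
            out.append(poisson_chisq(counts, config, participant_id=pid, week_start=w0))
    return out


def restlessness_frame(statistics: Sequence[RestlessnessStat]) -> pd.DataFrame:
    rows = [{
        "participant_id": s.participant_id,
        "week_start": s.week_start,
        "lambda_hat": s.lambda_hat,
        "chisq": s.chisq,
        "log_chisq": s.log_chisq,
        "dof": s.dof,
        "n_bins": s.n_bins,
        "alert": s.alert,
        "defined": s.defined,
        "flags": ";".join(s.flags),
    } for s in statistics]
    cols = ["participant_id", "week_start", "lambda_hat", "chisq", "log_chisq",
            "dof", "n_bins", "alert", "defined", "flags"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# screening rules


def detect_point_anomalies(nightly: pd.DataFrame,
                           config: Optional[AnomalyConfig] = None) -> pd.DataFrame:
    """Flag nights above the absolute threshold or far above the trailing MA.

    ``nightly`` needs ``participant_id``, ``night_date`` and ``toss_count``.
    Adds boolean columns ``above_threshold`` (count > point_threshold) and
    ``local_peak`` (count > peak_multiple * trailing ``ma_window``-night
    moving average, excluding the night itself).
    """
    config = config or AnomalyConfig()
    out = []
    for pid, grp in nightly.groupby("participant_id", sort=True):
        grp = grp.sort_values("night_date").copy()
        c = grp["toss_count"].astype(float)
        trailing = c.shift(1).rolling(config.ma_window, min_periods=max(2, config.ma_window // 2)).mean()
        grp["above_threshold"] = c > config.point_threshold
        grp["local_peak"] = (trailing.notna() & (c > config.peak_multiple * trailing))
        out.append(grp)
    return pd.concat(out, ignore_index=True) if out else nightly.assign(
        above_threshold=pd.Series(dtype=bool), local_peak=pd.Series(dtype=bool))


def moving_average(counts: pd.Series, window: int = 14) -> pd.Series:
    """Centered moving average over measured nights (window shrinks at edges)."""
    return counts.rolling(window, center=True, min_periods=1).mean()


def detect_trends(nightly: pd.DataFrame,
                  config: Optional[AnomalyConfig] = None) -> pd.DataFrame:
    """Sustained elevations of the centered moving average over baseline.

    The participant baseline is the median of the first
    ``trend_baseline_nights`` measured nights; a trend interval is a
    maximal run of nights whose ``ma_window``-night centered moving average
    exceeds baseline * (1 + ``trend_rel_increase``).  Missing nights are
    simply absent from the series (the average runs over measured nights).
    Returns one row per interval: participant, start, end, peak MA.
    """
    config = config or AnomalyConfig()
    rows = []
    for pid, grp in nightly.groupby("participant_id", sort=True):
        grp = grp.sort_values("night_date")
        if len(grp) < config.ma_window:
            continue
        counts = grp["toss_count"].astype(float).reset_index(drop=True)
        dates = pd.to_datetime(grp["night_date"]).reset_index(drop=True)
        ma = moving_average(counts, config.ma_window)
        baseline = counts.iloc[:config.trend_baseline_nights].median()
        if not np.isfinite(baseline) or baseline <= 0:
            continue
        above = (ma > baseline * (1.0 + config.trend_rel_increase)).to_numpy()
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            rows.append({
                "participant_id": pid,
                "start": dates.iloc[a],
                "end": dates.iloc[b - 1],
                "n_nights": int(b - a),
                "peak_ma": float(ma.iloc[a:b].max()),
                "baseline": float(baseline),
            })
    cols = ["participant_id", "start", "end", "n_nights", "peak_ma", "baseline"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# association with self-rated health


def correlate_with_eqvas(weekly: pd.DataFrame, reports: pd.DataFrame,
                         config: Optional[AnomalyConfig] = None
                         ) -> tuple[float, float, int]:
    """Spearman rho between weekly log chi-square and weekly mean EQ-VAS.

    ``weekly`` is a :func:`restlessness_frame`; ``reports`` needs
    ``participant_id``, ``report_date`` and ``eqvas``.  Reports falling in
    [week_start, week_start + 7 d) are averaged per week; matched weeks are
    pooled across participants.  Returns (nan, nan, n) when fewer than 3
    weeks match.
    """
    from .ranking import spearman

    config = config or AnomalyConfig()
    reps = reports.copy()
    reps["report_date"] = pd.to_datetime(reps["report_date"]).dt.normalize()
    xs, ys = [], []
    for row in weekly.itertuples():
        if not row.defined or not np.isfinite(row.log_chisq):
            continue
        w0 = pd.Timestamp(row.week_start)
        w1 = w0 + timedelta(days=config.week_nights)
        sel = reps[(reps["participant_id"] == row.participant_id)
                   & (reps["report_date"] >= w0) & (reps["report_date"] < w1)]
        if len(sel) == 0:
            continue
        xs.append(row.log_chisq)
        ys.append(float(sel["eqvas"].mean()))
    n = len(xs)
    if n < 3:
        return (np.nan, np.nan, n)
    rho, p = spearman(xs, ys)
    return (rho, p, n)
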