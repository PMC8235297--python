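"""Restlessness statistic, binning, screening rules, EQ-VAS association."""

from datetime import timedelta

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somnalert.anomaly import (AnomalyConfig, bin_counts, correlate_with_eqvas,
                               detect_point_anomalies, detect_trends,
                               moving_average, poisson_chisq,
                               restlessness_frame, weekly_restlessness_series)


def _events(ts):
    return np.array(sorted(np.datetime64(t) for t in ts), dtype="datetime64[ns]")


T0 = pd.Timestamp("2017-03-01 22:00")


class TestBinning:
    def test_no_events_gives_zeros(self):
        counts, outside = bin_counts(_events([]), [(T0, T0 + timedelta(hours=5))])
        assert len(counts) == 10 and not counts.any() and outside == 0

    def test_edge_event_goes_to_later_bin(self):
        counts, _ = bin_counts(_events(["2017-03-01T22:30:00"]),
                               [(T0, T0 + timedelta(hours=5))])
        assert counts[0] == 0 and counts[1] == 1

    def test_uniform_rate_recovers_analytic_mean(self):
        rng = np.random.default_rng(0)
        rate_per_s = 4.0 / 1800.0
        dur = 300 * 3600  # 600 bins so the Monte-Carlo error is ~2%
        n = rng.poisson(rate_per_s * dur)
        offs = np.sort(rng.uniform(0, dur, n))
        ev = np.datetime64(T0) + (offs * 1e9).astype("timedelta64[ns]")
        counts, _ = bin_counts(ev.astype("datetime64[ns]"), [(T0, T0 + timedelta(seconds=dur))])
        assert counts.mean() == pytest.approx(4.0, rel=0.05)

    def test_low_coverage_bins_dropped_and_outside_events_tallied(self):
        intervals = [(T0, T0 + timedelta(minutes=40))]  # bins: full, 10/30 covered
        counts, outside = bin_counts(_events(["2017-03-01T22:10:00",
                                              "2017-03-02T01:00:00"]), intervals)
        assert len(counts) == 1  # second bin has 33% coverage -> dropped
        assert outside == 1  # the 01:00 event lies outside in-bed time


def brute_force_poisson_gof(counts):
    """Independent evaluation of the pooled-histogram chi-square."""
    counts = np.asarray(counts)
    n = len(counts)
    lam = counts.mean()
    kmax = counts.max()
    cells = []  # (obs, exp) per count value, tail cell holds >= kmax
    for k in range(kmax + 1):
        obs = int((counts == k).sum())
        if k < kmax:
            exp = n * stats.poisson.pmf(k, lam)
        else:
            exp = n * (1.0 - stats.poisson.cdf(kmax - 1, lam))
        cells.append([obs, exp])
    while len(cells) > 1 and cells[-1][1] < 1.0:
        cells[-2][0] += cells[-1][0]
        cells[-2][1] += cells[-1][1]
        cells.pop()
    return sum((o - e) ** 2 / e for o, e in cells)


class TestPoissonChisq:
    def test_all_zero_week_defined_as_zero(self):
        s = poisson_chisq(np.zeros(168, dtype=int))
        assert s.chisq == 0.0 and not s.alert and "all_zero" in s.flags

    def test_matches_bruteforce_on_constant_counts(self):
        counts = np.full(168, 4)
        s = poisson_chisq(counts)
        assert s.lambda_hat == 4.0
        assert s.chisq == pytest.approx(brute_force_poisson_gof(counts), rel=1e-10)

    @pytest.mark.parametrize("lam", [0.5, 3.0, 8.0])
    def test_matches_bruteforce_on_random_weeks(self, lam):
        rng = np.random.default_rng(int(lam * 10))
        for _ in range(20):
            counts = rng.poisson(lam, 168)
            s = poisson_chisq(counts)
            assert s.chisq == pytest.approx(brute_force_poisson_gof(counts), rel=1e-10)

    def test_mle_is_bin_mean(self):
        counts = np.array([0, 1, 2, 3] * 42)
        assert poisson_chisq(counts).lambda_hat == counts.mean()

    def test_expected_histogram_mass_conserved(self):
        rng = np.random.default_rng(1)
        s = poisson_chisq(rng.poisson(3.0, 168))
        assert s.f_obs.sum() == 168
        assert s.f_exp.sum() == pytest.approx(168.0, abs=1e-8)

    def test_large_statistic_raises_alert(self):
        counts = np.concatenate([np.zeros(100, dtype=int), np.full(68, 25)])
        s = poisson_chisq(counts)
        assert s.chisq > 1000 and s.alert

    def test_too_few_bins_gives_marker(self):
        s = poisson_chisq(np.ones(50, dtype=int))
        assert not s.defined and "too_few_bins" in s.flags

    def test_invariant_to_bin_relabeling(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(4.0, 168)
        a = poisson_chisq(counts)
        b = poisson_chisq(rng.permutation(counts))
        assert a.chisq == pytest.approx(b.chisq, rel=1e-12)

    def test_dispersion_variant(self):
        counts = np.full(168, 4)
        cfg = AnomalyConfig(dispersion_variant=True)
        s = poisson_chisq(counts, cfg)
        assert s.chisq == pytest.approx(0.0)  # zero dispersion around the mean


class TestWeeklySeries:
    @staticmethod
    def nights_frame(days, bins_per_night=24, lam=3.0, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "participant_id": "P0",
            "night_slot_date": [pd.Timestamp("2017-03-01") + timedelta(days=d) for d in days],
            "bin_counts": [rng.poisson(lam, bins_per_night) for _ in days],
        })

    def test_21_nights_make_3_weeks(self):
        stats_ = weekly_restlessness_series(self.nights_frame(range(21)))
        assert len(stats_) == 3 and all(s.defined for s in stats_)

    def test_fully_missing_week_emits_marker(self):
        days = list(range(7)) + list(range(14, 21))
        stats_ = weekly_restlessness_series(self.nights_frame(days))
        assert len(stats_) == 3
        assert stats_[0].defined and stats_[2].defined
        assert not stats_[1].defined

    def test_sparse_week_emits_marker_not_small_chisq(self):
        days = list(range(7)) + [8, 9]  # second week: 2 nights = 48 bins < 100
        stats_ = weekly_restlessness_series(self.nights_frame(days))
        assert not stats_[1].defined and "too_few_bins" in stats_[1].flags

    def test_stationary_chisq_matches_null_simulation(self):
        """Mean weekly statistic agrees with its own null Monte Carlo."""
        stats_ = weekly_restlessness_series(self.nights_frame(range(140), lam=3.0, seed=3))
        observed = np.mean([s.chisq for s in stats_])
        rng = np.random.default_rng(4)
        null = [poisson_chisq(rng.poisson(3.0, 168)).chisq for _ in range(400)]
        se = np.std(null) / np.sqrt(len(stats_))
        assert abs(observed - np.mean(null)) < 4 * se + 0.5


class TestScreening:
    @staticmethod
    def series(counts, start="2017-03-01"):
        return pd.DataFrame({
            "participant_id": "P0",
            "night_date": pd.date_range(start, periods=len(counts)),
            "toss_count": counts,
        })

    def test_absolute_threshold_flag(self):
        out = detect_point_anomalies(self.series([57] * 20 + [250] + [57] * 10))
        assert out["above_threshold"].sum() == 1
        assert out.loc[out["above_threshold"], "toss_count"].iloc[0] == 250

    def test_baseline_night_not_flagged(self):
        out = detect_point_anomalies(self.series([57] * 30))
        assert not out["above_threshold"].any() and not out["local_peak"].any()

    def test_single_4x_spike_flagged_once(self):
        counts = [50] * 20 + [200] + [50] * 9
        out = detect_point_anomalies(self.series(counts))
        assert out["local_peak"].sum() == 1
        assert out.loc[out["local_peak"], "toss_count"].iloc[0] == 200

    def test_moving_average_of_constant_is_constant(self):
        ma = moving_average(pd.Series([42.0] * 50), 14)
        assert np.allclose(ma, 42.0)

    def test_flat_series_has_no_trends(self):
        rng = np.random.default_rng(5)
        out = detect_trends(self.series(rng.poisson(50, 80)))
        assert len(out) == 0

    def test_sustained_step_detected_as_one_interval(self):
        counts = [50] * 40 + [120] * 30 + [50] * 20
        out = detect_trends(self.series(counts))
        assert len(out) == 1
        row = out.iloc[0]
        # the step spans nights 40..69; MA smoothing blurs the edges
        assert abs((row["start"] - pd.Timestamp("2017-03-01")).days - 40) <= 7
        assert row["n_nights"] >= 20


class TestEqvasAssociation:
    def test_single_week_undefined(self):
        weekly = restlessness_frame([poisson_chisq(np.random.default_rng(0).poisson(3, 168),
                                                   participant_id="P0",
                                                   week_start="2017-03-01")])
        reports = pd.DataFrame({"participant_id": ["P0"],
                                "report_date": ["2017-03-03"], "eqvas": [70]})
        rho, p, n = correlate_with_eqvas(weekly, reports)
        assert np.isnan(rho) and n == 1

    def test_restless_weeks_rate_low_eqvas(self):
        """Weeks mixing calm and restless nights get high chi-square and
        low EQ-VAS; association comes out negative."""
        rng = np.random.default_rng(6)
        stats_, rep_rows = [], []
        for w in range(30):
            w0 = pd.Timestamp("2017-03-01") + timedelta(days=7 * w)
            episode = w % 3 == 0
            if episode:  # half the week at 4x the rate
                counts = np.concatenate([rng.poisson(3.0, 84), rng.poisson(12.0, 84)])
            else:
                counts = rng.poisson(3.0, 168)
            stats_.append(poisson_chisq(counts, participant_id="P0", week_start=w0))
            rep_rows.append({"participant_id": "P0",
                             "report_date": w0 + timedelta(days=3),
                             "eqvas": 55 if episode else 75})
        rho, p, n = correlate_with_eqvas(restlessness_frame(stats_), pd.DataFrame(rep_rows))
        assert n == 30 and rho < -0.8 and p < 0.001

    def test_shuffled_eqvas_kills_association(self):
        rng = np.random.default_rng(7)
        stats_ = [poisson_chisq(rng.poisson(3.0, 168), participant_id="P0",
                                week_start=pd.Timestamp("2017-03-01") + timedelta(days=7 * w))
                  for w in range(40)]
        rhos = []
        for rep_seed in range(10):
            rrng = np.random.default_rng(rep_seed)
            reports = pd.DataFrame({
                "participant_id": "P0",
                "report_date": [pd.Timestamp("2017-03-01") + timedelta(days=7 * w + 2)
                                for w in range(40)],
                "eqvas": rrng.permutation(np.linspace(50, 90, 40).round()),
            })
            rhos.append(correlate_with_eqvas(restlessness_frame(stats_), reports)[0])
        assert abs(np.mean(rhos)) < 0.15
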