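import numpy as np
import pandas as pd
import pytest

from wearcohort import ingest, metrics

from conftest import full_day, ledger_for, make_hr, make_sleep, make_steps


def _complete_day_setup(points, *, date="2017-03-06"):
    """A complete day plus extra HR points for metric-specific checks."""
    steps, hr = full_day(date)
    extra = make_hr(points)
    hr = pd.concat([hr, extra], ignore_index=True).sort_values("timestamp", ignore_index=True)
    return steps, hr


class TestRestingHR:
    def test_active_points_excluded_from_the_mean(self):
        # the 120-bpm point sits in a 500-step interval and must not count
        steps = make_steps(
            [("2017-03-06T08:00:00", 0), ("2017-03-06T09:00:00", 50), ("2017-03-06T10:00:00", 500)]
        )
        hr = make_hr(
            [
                ("2017-03-06T08:05:00", 70, 2),
                ("2017-03-06T09:05:00", 72, 2),
                ("2017-03-06T10:05:00", 120, 2),
            ]
        )
        timeline = ingest.merge_by_time(hr, steps)
        ledger = pd.DataFrame({"day": [pd.Timestamp("2017-03-06")], "valid_hours": [24],
                               "has_intraday_steps": [True], "complete": [True]})
        assert metrics.resting_hr(timeline, ledger) == pytest.approx(71.0)

    def test_interval_with_exactly_100_steps_included(self):
        steps, hr = full_day("2017-03-06", steps_per_bin=100, hr=70.0)
        timeline = ingest.merge_by_time(hr, steps)
        ledger = ledger_for(hr, steps)
        assert metrics.resting_hr(timeline, ledger) == pytest.approx(70.0)
        # 101 steps everywhere -> no qualifying point at all
        steps101 = steps.assign(steps=101)
        timeline101 = ingest.merge_by_time(hr, steps101)
        assert metrics.resting_hr(timeline101, ledger_for(hr, steps101)) is None

    def test_points_on_incomplete_days_ignored(self):
        steps, hr = full_day("2017-03-06")
        hr["confidence"] = -1  # day incomplete; nothing qualifies
        timeline = ingest.merge_by_time(hr, steps)
        assert metrics.resting_hr(timeline, ledger_for(hr, steps)) is None

    def test_order_invariance(self):
        steps, hr = full_day("2017-03-06", hr=68.0)
        shuffled = hr.sample(frac=1, random_state=3).reset_index(drop=True)
        ledger = ledger_for(hr, steps)
        a = metrics.resting_hr(ingest.merge_by_time(hr, steps), ledger)
        b = metrics.resting_hr(ingest.merge_by_time(shuffled, steps), ledger)
        assert a == pytest.approx(b)


class TestWindowedHR:
    def test_constant_day_gives_the_constant(self):
        steps, hr = full_day("2017-03-06", hr=60.0)
        timeline = ingest.merge_by_time(hr, steps)
        assert metrics.windowed_hr(timeline, ledger_for(hr, steps), (14.0, 16.0)) == pytest.approx(60.0)

    def test_active_point_in_window_fails_step_criterion(self):
        steps, hr = full_day("2017-03-06")
        steps.loc[steps["start"] == "2017-03-06T15:00:00", "steps"] = 600
        hr = hr[(hr["timestamp"].dt.hour < 14) | (hr["timestamp"].dt.hour >= 16)]
        extra = make_hr([("2017-03-06T15:00:00", 150, 2)])
        hr = pd.concat([hr, extra], ignore_index=True).sort_values("timestamp", ignore_index=True)
        timeline = ingest.merge_by_time(hr, steps)
        assert metrics.windowed_hr(timeline, ledger_for(hr, steps), (14.0, 16.0)) is None

    def test_night_window_mean(self):
        steps, hr = full_day("2017-03-06")
        hr = hr[(hr["timestamp"].dt.hour < 2) | (hr["timestamp"].dt.hour >= 4)]
        extra = make_hr([("2017-03-06T02:30:00", 58, 2), ("2017-03-06T03:30:00", 62, 2)])
        hr = pd.concat([hr, extra], ignore_index=True).sort_values("timestamp", ignore_index=True)
        timeline = ingest.merge_by_time(hr, steps)
        assert metrics.windowed_hr(timeline, ledger_for(hr, steps), (2.0, 4.0)) == pytest.approx(60.0)


class TestDailySteps:
    def test_mean_over_complete_days(self):
        s1, h1 = full_day("2017-03-06", steps_per_bin=8000 // 96 if False else 0)
        # two complete days totalling 8,000 and 12,000
        steps = pd.concat(
            [
                make_steps([("2017-03-06T00:00:00", 8000)]),
                full_day("2017-03-06")[0].iloc[1:].assign(steps=0),
                make_steps([("2017-03-07T00:00:00", 12000)]),
                full_day("2017-03-07")[0].iloc[1:].assign(steps=0),
            ],
            ignore_index=True,
        ).sort_values("start", ignore_index=True)
        hr = pd.concat([full_day("2017-03-06")[1], full_day("2017-03-07")[1]], ignore_index=True)
        assert metrics.daily_steps(steps, ledger_for(hr, steps)) == pytest.approx(10000.0)

    def test_incomplete_days_do_not_contribute(self):
        steps_a, hr_a = full_day("2017-03-06", steps_per_bin=9500 // 96 + 1)
        steps_a["steps"] = 0
        steps_a.loc[0, "steps"] = 9500
        steps_b, hr_b = full_day("2017-03-07", steps_per_bin=100)
        hr_b["confidence"] = -1  # second day invalid -> incomplete
        steps = pd.concat([steps_a, steps_b], ignore_index=True)
        hr = pd.concat([hr_a, hr_b], ignore_index=True)
        assert metrics.daily_steps(steps, ledger_for(hr, steps)) == pytest.approx(9500.0)


class TestDailyStepsAlt:
    def test_constant_intervals_give_96x(self):
        steps, hr = full_day("2017-03-06", steps_per_bin=100)
        timeline = ingest.merge_by_time(hr, steps)
        assert metrics.daily_steps_alt(timeline, ledger_for(hr, steps)) == pytest.approx(9600.0)

    def test_mixed_intervals_average_before_scaling(self):
        steps, hr = full_day("2017-03-06")
        steps["steps"] = np.where(np.arange(96) % 2 == 0, 0, 200)
        hr = full_day("2017-03-06")[1]
        # one valid HR point in every interval so each interval counts once
        hr = pd.DataFrame(
            {
                "timestamp": steps["start"] + pd.Timedelta(minutes=5),
                "hr_bpm": 70.0,
                "confidence": 2,
            }
        )
        timeline = ingest.merge_by_time(hr, steps)
        assert metrics.daily_steps_alt(timeline, ledger_for(hr, steps)) == pytest.approx(9600.0)

    def test_repeated_points_in_one_interval_count_once(self):
        steps, _ = full_day("2017-03-06")
        steps["steps"] = 0
        steps.loc[0, "steps"] = 960  # midnight interval only
        hr_rows = [("2017-03-06T00:01:00", 70, 2), ("2017-03-06T00:06:00", 70, 2),
                   ("2017-03-06T00:11:00", 70, 2)]
        hr_rows += [(f"2017-03-06T{h:02d}:20:00", 70, 2) for h in range(1, 24)]
        hr = make_hr(hr_rows)
        timeline = ingest.merge_by_time(hr, steps)
        # 24 distinct intervals observed, one with 960 steps: mean 40, x96
        assert metrics.daily_steps_alt(timeline, ledger_for(hr, steps)) == pytest.approx(40.0 * 96)
        per_point = metrics.daily_steps_alt(timeline, ledger_for(hr, steps), per_point=True)
        assert per_point == pytest.approx(960 * 3 / 26 * 96)


class TestSleepSummary:
    def _ledger(self, *dates):
        frames = [full_day(d) for d in dates]
        steps = pd.concat([f[0] for f in frames], ignore_index=True)
        hr = pd.concat([f[1] for f in frames], ignore_index=True)
        return ledger_for(hr, steps)

    def test_nightly_sessions(self):
        ledger = self._ledger("2017-03-06", "2017-03-07")
        sessions = make_sleep(
            [
                ("2017-03-06T23:00:00", "2017-03-07T07:00:00"),
                ("2017-03-07T23:00:00", "2017-03-08T07:00:00"),
            ]
        )
        dur, sleep_h, wake_h = metrics.sleep_summary(sessions, ledger)
        assert dur == pytest.approx(480.0)
        assert sleep_h == pytest.approx(23.0)
        assert wake_h == pytest.approx(7.0)

    def test_midnight_wrap_uses_plus24_mapping(self):
        ledger = self._ledger("2017-03-06", "2017-03-07")
        sessions = make_sleep(
            [
                ("2017-03-06T23:30:00", "2017-03-07T07:00:00"),
                ("2017-03-07T00:30:00", "2017-03-07T08:00:00"),
            ]
        )
        _, sleep_h, _ = metrics.sleep_summary(sessions, ledger)
        assert sleep_h == pytest.approx(0.0)  # mean of 23.5 and 24.5, mod 24

    def test_daytime_nap_counts_toward_duration_only(self):
        ledger = self._ledger("2017-03-06")
        sessions = make_sleep(
            [
                ("2017-03-06T13:00:00", "2017-03-06T14:00:00"),  # nap
                ("2017-03-06T23:00:00", "2017-03-07T07:00:00"),
            ]
        )
        dur, sleep_h, _ = metrics.sleep_summary(sessions, ledger)
        assert dur == pytest.approx(540.0)  # 60 + 480 on the same calendar day
        assert sleep_h == pytest.approx(23.0)  # nap start outside the onset window


class TestTwoSDFilter:
    def test_outlier_beyond_two_sd_excluded(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 200)
        v[0] = v[1:].mean() + 3.5 * v[1:].std()
        keep = metrics.two_sd_filter(pd.DataFrame({"m": v}))
        assert not keep.iloc[0]
        assert keep.iloc[1:].mean() > 0.9

    def test_constant_metric_retains_everyone(self):
        keep = metrics.two_sd_filter(pd.DataFrame({"m": np.ones(10)}))
        assert keep.all()

    def test_joint_rule_excludes_on_any_metric(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"dur": rng.normal(420, 30, 100), "sleep": rng.normal(23, 0.5, 100)})
        df.loc[0, "sleep"] = 23 + 5  # outlying sleep hour only
        keep = metrics.two_sd_filter(df)
        assert not keep.iloc[0]

    def test_missing_value_does_not_exclude(self):
        df = pd.DataFrame({"m": [np.nan, 0.1, -0.2, 0.05, 0.3]})
        assert metrics.two_sd_filter(df).iloc[0]


class TestSpearman:
    def test_monotone_transforms(self):
        x = np.linspace(-3, 3, 50)
        assert metrics.correlate_spearman(x, x**3) == pytest.approx(1.0)
        assert metrics.correlate_spearman(x, -x) == pytest.approx(-1.0)

    def test_independent_permutation_is_near_zero(self):
        rng = np.random.default_rng(4)
        x = np.arange(1000.0)
        y = rng.permutation(x)
        assert abs(metrics.correlate_spearman(x, y)) < 0.1

    def test_too_few_pairs_absent(self):
        assert metrics.correlate_spearman([1, 2], [2, 1]) is None


def test_sleep_hour_continuous_mapping():
    s = pd.Series([23.5, 0.5, 22.0, 3.9])
    out = metrics.sleep_hour_continuous(s)
    assert list(out) == [23.5, 24.5, 22.0, 27.9]
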