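import warnings
from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from dailygait.errors import EmptyInputError, FormatError, SamplingError
from dailygait.recording_io import (
    DayRecord,
    Recording,
    WearInterval,
    WearParams,
    day_wear_summary,
    detect_wear,
    read_recording,
    resample_recording,
    write_recording,
)


def make_recording(n=3000, rate=50.0, **kw):
    rng = np.random.default_rng(kw.pop("seed", 0))
    return Recording(
        subject_id=kw.pop("subject_id", "s01"),
        rate=rate,
        start_time=kw.pop("start_time", datetime(2021, 6, 1, 0, 0)),
        acc_v=1.0 + 0.1 * rng.standard_normal(n),
        acc_ap=0.05 * rng.standard_normal(n),
        acc_ml=0.05 * rng.standard_normal(n),
        **kw,
    )


class TestReadWrite:
    def test_round_trip(self, tmp_path):
        rec = make_recording(temperature=np.full(60, 31.5), temp_rate=1.0)
        path = write_recording(rec, tmp_path / "rec.csv")
        back = read_recording(path)
        assert back.subject_id == rec.subject_id
        assert back.rate == pytest.approx(rec.rate)
        assert back.start_time == rec.start_time
        np.testing.assert_allclose(back.acc_v, rec.acc_v, atol=1e-8)
        np.testing.assert_allclose(back.acc_ap, rec.acc_ap, atol=1e-8)
        np.testing.assert_allclose(back.acc_ml, rec.acc_ml, atol=1e-8)
        np.testing.assert_allclose(back.temperature, rec.temperature, atol=1e-7)

    def test_missing_column_named(self, tmp_path):
        frame = pd.DataFrame({"t": [0, 0.02], "acc_v": [1, 1], "acc_ap": [0, 0]})
        frame.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(FormatError, match="acc_ml"):
            read_recording(tmp_path / "bad.csv")

    def test_ten_minutes_at_50hz(self):
        rec = make_recording(n=30_000, rate=50.0)
        assert rec.n_samples == 30_000
        assert rec.duration == pytest.approx(600.0)

    def test_nonuniform_sampling_rejected(self, tmp_path):
        t = np.concatenate([np.arange(100) * 0.02, 2.0 + np.arange(100) * 0.05])
        frame = pd.DataFrame({"t": t, "acc_v": 1.0, "acc_ap": 0.0, "acc_ml": 0.0})
        frame.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SamplingError):
            read_recording(tmp_path / "bad.csv")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_recording(tmp_path / "nope.csv")


class TestResample:
    def test_constant_preserved(self):
        rec = Recording("s", 50.0, datetime(2021, 1, 1), np.ones(500), np.zeros(500), np.zeros(500))
        out = resample_recording(rec, 100.0)
        assert out.rate == 100.0
        np.testing.assert_allclose(out.acc_v, 1.0)
        assert abs(out.duration - rec.duration) <= 1.0 / 50.0

    def test_sine_against_analytic(self):
        # 2 Hz unit sine sampled at 50 Hz, resampled to 100 Hz
        t50 = np.arange(500) / 50.0
        rec = Recording("s", 50.0, datetime(2021, 1, 1), np.sin(2 * np.pi * 2 * t50),
                        np.zeros(500), np.zeros(500))
        out = resample_recording(rec, 100.0)
        t100 = np.arange(out.n_samples) / 100.0
        assert np.abs(out.acc_v - np.sin(2 * np.pi * 2 * np.minimum(t100, t50[-1]))).max() < 0.01

    def test_identity_when_same_rate(self):
        rec = make_recording()
        out = resample_recording(rec, rec.rate)
        np.testing.assert_array_equal(out.acc_v, rec.acc_v)

    def test_empty_rejected(self):
        rec = Recording("s", 50.0, datetime(2021, 1, 1), np.ones(1), np.ones(1), np.ones(1))
        rec.acc_v = np.array([])
        rec.acc_ap = np.array([])
        rec.acc_ml = np.array([])
        with pytest.raises(EmptyInputError):
            resample_recording(rec, 100.0)


class TestDetectWear:
    def test_constant_skin_temperature(self):
        iv = detect_wear(np.full(7200, 32.0), 1.0)
        assert len(iv) == 1 and iv[0].worn
        assert iv[0].start == 0.0 and iv[0].end == pytest.approx(7200.0)

    def test_constant_ambient(self):
        iv = detect_wear(np.full(7200, 21.0), 1.0)
        assert len(iv) == 1 and not iv[0].worn

    def test_step_change_boundary(self):
        # 21 -> 33 degC at t0 = 3600 s; boundary within the smoothing window
        params = WearParams()
        temp = np.where(np.arange(7200) < 3600, 21.0, 33.0)
        iv = detect_wear(temp, 1.0, params=params)
        assert [x.worn for x in iv] == [False, True]
        assert abs(iv[0].end - 3600.0) <= params.smooth_window_s

    def test_missing_temperature_falls_back(self):
        with pytest.warns(UserWarning, match="temperature"):
            iv = detect_wear(None, 1.0, duration=600.0)
        assert len(iv) == 1 and iv[0].worn and iv[0].end == 600.0

    def test_partition_covers_recording(self):
        rng = np.random.default_rng(1)
        temp = np.concatenate([np.full(3600, 32.0), np.full(1800, 21.0), np.full(3600, 32.0)])
        temp = temp + rng.normal(0, 0.05, temp.size)
        iv = detect_wear(temp, 1.0, duration=9000.0)
        total = sum(x.duration for x in iv)
        assert total == pytest.approx(9000.0, abs=1e-9)
        for a, b in zip(iv[:-1], iv[1:]):
            assert a.end == pytest.approx(b.start)
            assert a.worn != b.worn

    def test_short_segments_merged(self):
        temp = np.full(7200, 32.0)
        temp[3000:3120] = 21.0  # 2-min dip, below the 10-min minimum
        iv = detect_wear(temp, 1.0)
        assert len(iv) == 1 and iv[0].worn


class TestDayWearSummary:
    def test_full_day_worn(self):
        days = day_wear_summary(
            [WearInterval(0.0, 86400.0, True)], datetime(2021, 6, 1, 0, 0), 86400.0
        )
        assert len(days) == 1
        assert days[0].wear_hours == pytest.approx(24.0)
        assert days[0].is_valid

    def test_just_below_threshold_invalid(self):
        secs = 17.99 * 3600
        days = day_wear_summary(
            [WearInterval(0.0, secs, True), WearInterval(secs, 86400.0, False)],
            datetime(2021, 6, 1, 0, 0),
            86400.0,
        )
        assert not days[0].is_valid
        assert days[0].wear_hours == pytest.approx(17.99)

    def test_exactly_18h_valid(self):
        secs = 18 * 3600.0
        days = day_wear_summary(
            [WearInterval(0.0, secs, True), WearInterval(secs, 86400.0, False)],
            datetime(2021, 6, 1, 0, 0),
            86400.0,
        )
        assert days[0].is_valid

    def test_overnight_interval_split(self):
        # worn 22:00-02:00 starting from midnight day 0: 2 h to each day
        iv = [
            WearInterval(0.0, 79200.0, False),
            WearInterval(79200.0, 93600.0, True),
            WearInterval(93600.0, 172800.0, False),
        ]
        days = day_wear_summary(iv, datetime(2021, 6, 1, 0, 0), 172800.0)
        assert len(days) == 2
        assert days[0].wear_hours == pytest.approx(2.0)
        assert days[1].wear_hours == pytest.approx(2.0)

    def test_wear_hours_conservation(self):
        rng = np.random.default_rng(3)
        edges = np.sort(rng.uniform(0, 3 * 86400.0, 10))
        edges = np.concatenate([[0.0], edges, [3 * 86400.0]])
        iv = [
            WearInterval(a, b, bool(i % 2))
            for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
            if b > a
        ]
        days = day_wear_summary(iv, datetime(2021, 6, 1, 0, 0), 3 * 86400.0)
        worn_total = sum(x.duration for x in iv if x.worn)
        assert sum(d.wear_hours for d in days) * 3600 == pytest.approx(worn_total, abs=0.02)

    def test_offset_start_time(self):
        # start at 18:00: 12 h recording spans two calendar days
        days = day_wear_summary(
            [WearInterval(0.0, 43200.0, True)], datetime(2021, 6, 1, 18, 0), 43200.0
        )
        assert len(days) == 2
        assert days[0].wear_hours == pytest.approx(6.0)
        assert days[1].wear_hours == pytest.approx(6.0)

    def test_compressed_days_scale_threshold(self):
        days = day_wear_summary(
            [WearInterval(0.0, 1200.0, True)],
            datetime(2021, 6, 1, 0, 0),
            1200.0,
            day_seconds=600.0,
        )
        assert len(days) == 2
        assert all(d.is_valid for d in days)
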