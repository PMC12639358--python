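"""Circular time conversion, independence filtering and solar bands."""
import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trapdiel import (SolarTable, TimeBand, assign_band, band_availability,
                      filter_independent, to_circular)
from trapdiel.preprocess import daylight_fraction

from conftest import make_record


class TestToCircular:
    @pytest.mark.parametrize("time,angle", [
        (dt.time(0, 0), 0.0),
        (dt.time(12, 0), math.pi),
        (dt.time(18, 0), 1.5 * math.pi),
    ])
    def test_reference_times(self, time, angle):
        assert to_circular(time) == pytest.approx(angle)

    def test_out_of_range_minutes(self):
        with pytest.raises(ValueError):
            to_circular(1441.0)


class TestIndependenceFilter:
    def test_greedy_hour_rule(self):
        times = ["10:00", "10:30", "11:30", "13:00"]
        recs = [make_record(time=t) for t in times]
        kept = filter_independent(recs, 60)
        assert [r.timestamp.strftime("%H:%M") for r in kept] == [
            "10:00", "11:30", "13:00"]

    def test_single_record_kept(self):
        recs = [make_record()]
        assert filter_independent(recs) == recs

    def test_streams_are_per_species(self):
        recs = [make_record(species="deer", time="10:00"),
                make_record(species="coati", time="10:10")]
        assert filter_independent(recs, 60) == recs

    def test_unsorted_stream_rejected(self):
        recs = [make_record(time="11:00"), make_record(time="10:00")]
        with pytest.raises(ValueError, match="not sorted"):
            filter_independent(recs)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=1430), min_size=1,
                    max_size=40),
           st.integers(min_value=1, max_value=180))
    def test_idempotent_subsequence_keeps_first(self, minutes, interval):
        minutes = sorted(minutes)
        recs = [make_record(time=f"{m // 60:02d}:{m % 60:02d}")
                for m in minutes]
        once = filter_independent(recs, interval)
        assert filter_independent(once, interval) == once
        assert once[0] == recs[0]
        it = iter(recs)
        assert all(r in it for r in once)  # subsequence of the input


class TestBands:
    @pytest.mark.parametrize("time,band", [
        ("05:30", TimeBand.SUNRISE),
        ("12:00", TimeBand.DAY),
        ("23:00", TimeBand.NIGHT),
        ("17:00", TimeBand.SUNSET),   # boundary: sunset-1h is inside Sunset
        ("07:00", TimeBand.DAY),      # boundary: sunrise+1h leaves Sunrise
    ])
    def test_band_assignment(self, symmetric_solar, time, band):
        stamp = dt.datetime.fromisoformat(f"2019-02-01T{time}")
        assert assign_band(stamp, symmetric_solar) is band

    def test_bands_partition_the_cycle(self, symmetric_solar):
        counts = {b: 0 for b in TimeBand}
        for minute in range(0, 1440, 7):
            stamp = dt.datetime(2019, 3, 1, minute // 60, minute % 60)
            counts[assign_band(stamp, symmetric_solar)] += 1
        assert sum(counts.values()) == len(range(0, 1440, 7))
        assert all(v > 0 for v in counts.values())

    def test_degenerate_day_rejected(self):
        with pytest.raises(ValueError, match="crepuscular"):
            SolarTable(sunrise={1: 600.0}, sunset={1: 700.0})

    def test_missing_month_errors(self, symmetric_solar):
        solar = SolarTable(sunrise={1: 360.0}, sunset={1: 1080.0})
        with pytest.raises(KeyError, match="month"):
            assign_band(dt.datetime(2019, 5, 1, 12, 0), solar)


class TestAvailability:
    def test_symmetric_day(self, symmetric_solar):
        p = band_availability(symmetric_solar)
        assert p[TimeBand.SUNRISE] == pytest.approx(2 / 24)
        assert p[TimeBand.SUNSET] == pytest.approx(2 / 24)
        assert p[TimeBand.DAY] == pytest.approx(10 / 24)
        assert p[TimeBand.NIGHT] == pytest.approx(10 / 24)

    def test_off_centre_day(self):
        solar = SolarTable(sunrise={2: 330.0}, sunset={2: 1050.0})  # 05:30-17:30
        p = band_availability(solar)
        assert p[TimeBand.DAY] == pytest.approx(10 / 24)

    def test_proportions_sum_to_one(self):
        solar = SolarTable(sunrise={1: 358.0, 2: 355.0}, sunset={1: 1062, 2: 1071})
        p = band_availability(solar, month_weights={1: 3, 2: 7})
        assert sum(p.values()) == pytest.approx(1.0)

    def test_empirical_band_proportions_converge(self, symmetric_solar, rng):
        """Uniform times land in each band at its availability rate."""
        n = 40_000
        minutes = rng.uniform(0, 1440, n)
        p = band_availability(symmetric_solar)
        for band in TimeBand:
            hits = sum(
                assign_band((m / 1440 * 2 * math.pi, dt.date(2019, 2, 1)),
                            symmetric_solar) is band
                for m in minutes[:4000])
            se = math.sqrt(p[band] * (1 - p[band]) / 4000)
            assert abs(hits / 4000 - p[band]) < 3.5 * se

    def test_daylight_fraction(self, symmetric_solar):
        angles = [to_circular(dt.time(h, 0)) for h in (1, 7, 12, 17, 23)]
        dates = [dt.date(2019, 2, 1)] * 5
        assert daylight_fraction(angles, dates, symmetric_solar) == pytest.approx(3 / 5)
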