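import datetime as dt

import numpy as np
import pytest

from pbt.io_formats import MealEvent
from pbt.peaks import (
    ExclusionWindow,
    Peak,
    apply_exclusions,
    build_exclusion_windows,
    clean_days,
    detect_peaks,
    flag_meal_peaks,
    meal_based_windows,
    measure_width,
    smooth,
)
from pbt.simulate import SimConfig, simulate

from conftest import make_day
from peak_oracle import brute_force_peaks

D0 = dt.date(2023, 1, 1)


def ts(hhmm, day=D0):
    return dt.datetime.combine(day, dt.time.fromisoformat(hhmm))


def mkpeak(apex="12:00", height=30.0, width=1.0):
    t = ts(apex)
    return Peak(t, 150.0, height, width, t - dt.timedelta(hours=1), t + dt.timedelta(hours=1))


class TestSmooth:
    def test_constant_series_is_fixed_point(self):
        day = make_day([120] * 10)
        assert smooth(day).values.tolist() == [120.0] * 10

    def test_impulse_is_attenuated_neighbors_not_lowered(self):
        day = make_day([120, 120, 200, 120, 120])
        sm = smooth(day).values
        assert sm[2] < 200
        assert sm[1] >= 120 and sm[3] >= 120

    def test_linear_ramp_preserved_at_interior_points(self):
        # a 3-point centered average of an arithmetic sequence returns it
        day = make_day([100, 105, 110, 115, 120])
        sm = smooth(day).values
        assert sm[1:4].tolist() == [105.0, 110.0, 115.0]

    def test_short_day_passes_through(self):
        day = make_day([100, 200])
        assert smooth(day).values.tolist() == [100.0, 200.0]


class TestDetectPeaks:
    def test_monotone_day_has_no_peaks(self):
        assert detect_peaks(make_day(range(100, 200, 5))) == []

    def test_symmetric_triangle(self):
        peaks = detect_peaks(make_day([100, 150, 100], start="12:00"))
        assert len(peaks) == 1
        p = peaks[0]
        assert p.apex_value == 150 and p.height == 50
        assert p.t_apex == ts("12:05")
        assert p.t_left_base == ts("12:00") and p.t_right_base == ts("12:10")

    def test_height_measured_to_deeper_valley(self):
        # valleys at 100 (left) and 90 (right): height = 150 - 90
        peaks = detect_peaks(make_day([100, 150, 90, 140, 100]))
        assert [p.height for p in peaks] == [60.0, 50.0]

    def test_higher_base_option_gives_prominence_style_height(self):
        peaks = detect_peaks(make_day([100, 150, 90, 140, 100]), height_base="higher")
        assert [p.height for p in peaks] == [50.0, 40.0]

    def test_plateau_apex_is_center_sample(self):
        day = make_day([100, 150, 150, 150, 100], start="12:00")
        (p,) = detect_peaks(day)
        assert p.t_apex == ts("12:10")

    def test_noise_floor_drops_small_wiggles(self):
        day = make_day([120, 123, 120, 160, 120])
        assert [p.apex_value for p in detect_peaks(day)] == [160.0]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle_on_random_days(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 300))
        values = rng.integers(60, 260, size=n).astype(float)
        day = make_day(values)
        peaks = detect_peaks(day)
        oracle = brute_force_peaks(day.hours, values)
        assert len(peaks) == len(oracle)
        for p, (apex_i, h, w) in zip(peaks, oracle):
            assert p.t_apex == day.times[apex_i]
            assert p.height == h
            assert p.width == w


class TestMeasureWidth:
    def test_triangle_half_height_width_is_five_minutes(self):
        day = make_day([100, 150, 100])
        (p,) = detect_peaks(day)
        assert measure_width(day, p, 0.5) == pytest.approx(5 / 60)

    def test_plateau_width_includes_full_plateau(self):
        day = make_day([100, 150, 150, 150, 100])
        (p,) = detect_peaks(day)
        assert measure_width(day, p, 0.5) >= 2 * 5 / 60  # at least the plateau span

    def test_full_height_measures_at_deeper_valley_level(self):
        day = make_day([100, 150, 100])
        (p,) = detect_peaks(day)
        # level == valley value: crossings at the bases, width = 10 min
        assert measure_width(day, p, 1.0) == pytest.approx(10 / 60)

    def test_shallow_flank_clips_at_base_and_edge_peak_is_flagged(self):
        # right valley (110) above the half-height level from the deeper
        # left valley (60): right flank clips at its base, which is the
        # series edge here
        day = make_day([60, 150, 110])
        (p,) = detect_peaks(day)
        assert p.edge_truncated
        assert p.t_right_base == day.times[-1]


class TestFlagMealPeaks:
    def test_single_tall_peak_flagged_equal_widths_flag_all(self):
        peaks = [mkpeak(height=30) for _ in range(19)] + [mkpeak(height=100)]
        flagged = flag_meal_peaks(peaks, 95)
        # all widths equal -> the degenerate width rule flags every peak
        assert len(flagged) == 20
        widths = np.linspace(0.5, 2.0, 20)
        peaks = [mkpeak(height=h, width=w) for h, w in zip([30] * 19 + [100], widths)]
        flagged = flag_meal_peaks(peaks, 95)
        by_height = [p for p in flagged if p.height == 100]
        assert len(by_height) == 1
        # remaining flags come from the width tail only
        w95 = np.percentile(widths, 95)
        assert all(p.width >= w95 for p in flagged if p.height != 100)

    def test_identical_peaks_all_flagged(self):
        peaks = [mkpeak() for _ in range(5)]
        assert len(flag_meal_peaks(peaks, 95)) == 5

    def test_singleton_flagged(self):
        assert len(flag_meal_peaks([mkpeak()], 95)) == 1

    def test_empty_list(self):
        assert flag_meal_peaks([], 95) == []

    def test_raising_percentile_never_flags_more(self):
        rng = np.random.default_rng(1)
        peaks = [
            mkpeak(height=float(h), width=float(w))
            for h, w in zip(rng.uniform(5, 100, 40), rng.uniform(0.1, 3, 40))
        ]
        counts = [len(flag_meal_peaks(peaks, q)) for q in (50, 70, 90, 95, 99, 100)]
        assert counts == sorted(counts, reverse=True)


class TestExclusionWindows:
    def test_noon_peak_gives_four_hour_window(self):
        win = build_exclusion_windows([mkpeak("12:00")])
        assert win == {D0: [ExclusionWindow(ts("11:00"), ts("15:00"))]}

    def test_late_peak_splits_at_midnight(self):
        win = build_exclusion_windows([mkpeak("22:30")])
        next_day = D0 + dt.timedelta(days=1)
        assert win[D0] == [ExclusionWindow(ts("21:30"), ts("00:00", next_day))]
        assert win[next_day] == [
            ExclusionWindow(ts("00:00", next_day), ts("01:30", next_day))
        ]

    def test_overlapping_windows_merge(self):
        win = build_exclusion_windows([mkpeak("12:00"), mkpeak("13:00")])
        assert win == {D0: [ExclusionWindow(ts("11:00"), ts("16:00"))]}

    def test_window_start_clamped_to_midnight(self):
        win = build_exclusion_windows([mkpeak("00:30")])
        assert win[D0][0].start == ts("00:00")

    def test_meal_window_is_four_hours_after(self):
        win = meal_based_windows([MealEvent(ts("08:00"))])
        assert win == {D0: [ExclusionWindow(ts("08:00"), ts("12:00"))]}

    def test_meal_window_midnight_split_and_merge(self):
        win = meal_based_windows([MealEvent(ts("23:00"))])
        next_day = D0 + dt.timedelta(days=1)
        assert win[D0][0].end == ts("00:00", next_day)
        assert win[next_day][0].end == ts("03:00", next_day)
        merged = meal_based_windows([MealEvent(ts("08:00")), MealEvent(ts("09:00"))])
        assert merged == {D0: [ExclusionWindow(ts("08:00"), ts("13:00"))]}


class TestApplyExclusions:
    def test_no_windows_is_identity(self):
        day = make_day([120, 130, 125])
        cleaned = apply_exclusions(day, [])
        assert cleaned.samples == day.samples

    def test_window_covering_day_empties_it(self):
        day = make_day([120, 130, 125])
        next_day = dt.datetime.combine(D0 + dt.timedelta(days=1), dt.time())
        cleaned = apply_exclusions(day, [ExclusionWindow(ts("00:00"), next_day)])
        assert cleaned.samples == []

    def test_four_hour_window_removes_48_of_288_samples(self):
        day = make_day([120] * 288)
        cleaned = apply_exclusions(day, [ExclusionWindow(ts("11:00"), ts("15:00"))])
        assert len(cleaned) == 240

    def test_half_open_boundary(self):
        day = make_day([120] * 288)
        cleaned = apply_exclusions(day, [ExclusionWindow(ts("11:00"), ts("12:00"))])
        kept_ts = {s.ts for s in cleaned.samples}
        assert ts("11:00") not in kept_ts and ts("12:00") in kept_ts


@pytest.fixture(scope="module")
def sim():
    days, truth, meals = simulate(SimConfig(n_days=15, seed=11))
    cleaned, flagged, windows = clean_days(days)
    return days, cleaned, flagged, windows


class TestPipelineProperties:

    def test_sample_conservation(self, sim):
        days, cleaned, _, windows = sim
        for raw, cl in zip(days, cleaned):
            inside = sum(
                1
                for s in raw.samples
                if any(w.contains(s.ts) for w in windows.get(raw.date, []))
            )
            assert len(raw) == len(cl) + inside

    def test_exclusion_is_idempotent(self, sim):
        _, cleaned, _, windows = sim
        for cl in cleaned:
            again = apply_exclusions(cl, windows.get(cl.date, []))
            assert again.samples == cl.samples

    def test_cleaned_is_ordered_subset(self, sim):
        days, cleaned, _, _ = sim
        for raw, cl in zip(days, cleaned):
            raw_ts = [s.ts for s in raw.samples]
            cl_ts = [s.ts for s in cl.samples]
            assert cl_ts == [t for t in raw_ts if t in set(cl_ts)]

    def test_single_meal_excursion_is_flagged_and_excised(self):
        cfg = SimConfig(
            n_days=12,
            seed=5,
            meal_times=("12:00",),
            meal_amplitude_mean=40.0,
            meal_amplitude_sd=0.0,
            noise_sd=5.0,
            dropout_prob=0.0,
        )
        days, truth, meals = simulate(cfg)
        cleaned, flagged, windows = clean_days(days)
        meals_by_date = {m.ts.date(): m.ts for m in meals}
        for raw, cl in zip(days, cleaned):
            meal_ts = meals_by_date[raw.date]
            apexes = [
                p.t_apex
                for p in flagged
                if p.date == raw.date
                and meal_ts <= p.t_apex <= meal_ts + dt.timedelta(hours=3)
            ]
            assert apexes, f"no flagged apex after the meal on {raw.date}"
            apex = apexes[0]
            lo, hi = apex - dt.timedelta(hours=1), apex + dt.timedelta(hours=3)
            in_window = [s.ts for s in raw.samples if lo <= s.ts < hi]
            kept = {s.ts for s in cl.samples}
            excised = sum(1 for t in in_window if t not in kept)
            assert excised / len(in_window) >= 0.9
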