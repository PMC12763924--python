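"""Epoch processing: window restriction, non-wear, classification, validity."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvpatrial.accel import (
    AXES,
    DescriptorSpec,
    EpochSeries,
    aggregate_child,
    classify_epoch,
    detect_nonwear,
    read_epoch_csv,
    restrict_window,
    summarize_day,
)
from mvpatrial.synth import EpochSimConfig, epochs_to_csv, generate_epochs

MONDAY = dt.date(2021, 3, 1)
W0, W1 = dt.time(8, 30), dt.time(15, 30)


def make_series(start, n, fill=10, date=MONDAY, epoch_len=1):
    counts = np.full((n, 3), fill, dtype=np.int64)
    return EpochSeries("kid", date, start, counts, epoch_len)


class TestRestrictWindow:
    def test_full_day_capped_at_window_length(self):
        s = make_series(dt.time(0, 0), 24 * 3600)
        r = restrict_window(s, W0, W1)
        assert len(r) == 420 * 60  # 7 h of 1-s epochs

    def test_disjoint_window_is_empty(self):
        s = make_series(dt.time(16, 0), 2 * 3600)
        assert len(restrict_window(s, W0, W1)) == 0

    def test_partial_overlap_keeps_half_open_interval(self):
        # 08:00-09:00 recording, window from 08:30: 30 min = 1800 epochs kept
        s = make_series(dt.time(8, 0), 3600)
        r = restrict_window(s, W0, W1)
        assert len(r) == 1800
        assert r.start == dt.time(8, 30)

    def test_idempotent(self):
        s = make_series(dt.time(7, 45), 5 * 3600)
        once = restrict_window(s, W0, W1)
        twice = restrict_window(once, W0, W1)
        np.testing.assert_array_equal(once.counts, twice.counts)
        assert once.start == twice.start

    def test_invalid_window_rejected(self):
        s = make_series(dt.time(9, 0), 100)
        with pytest.raises(ValueError):
            restrict_window(s, W1, W0)


class TestNonwear:
    def test_twenty_minute_zero_run_flagged_inclusive(self):
        # 1200 zero 1-s epochs = exactly 20 min: all flagged non-wear
        counts = np.full((1300, 3), 30, dtype=np.int64)
        counts[50:1250] = 0
        s = EpochSeries("kid", MONDAY, dt.time(9, 0), counts)
        wear = detect_nonwear(s)
        assert not wear[50:1250].any()
        assert wear[:50].all() and wear[1250:].all()

    def test_just_below_threshold_not_flagged(self):
        counts = np.full((1300, 3), 30, dtype=np.int64)
        counts[50:1249] = 0  # 1199 s = 19 min 59 s
        s = EpochSeries("kid", MONDAY, dt.time(9, 0), counts)
        assert detect_nonwear(s).all()

    def test_alternating_counts_no_qualifying_run(self):
        counts = np.zeros((3600, 3), dtype=np.int64)
        counts[::2] = 50
        s = EpochSeries("kid", MONDAY, dt.time(9, 0), counts)
        wear = detect_nonwear(s)
        assert wear.all()
        assert wear.sum() * s.epoch_len / 60 == 60.0

    def test_vertical_axis_defines_nonwear(self):
        # zeros on vertical with activity on other axes still count as a run
        counts = np.zeros((1300, 3), dtype=np.int64)
        counts[:, 1] = 40
        s = EpochSeries("kid", MONDAY, dt.time(9, 0), counts)
        assert not detect_nonwear(s).any()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 40))
    def test_monotone_in_threshold(self, seed, thr):
        g = np.random.default_rng(seed)
        counts = np.repeat(
            g.integers(0, 2, 60) * g.integers(1, 50, 60), g.integers(30, 900, 60)
        )[:3600]
        s = EpochSeries("kid", MONDAY, dt.time(9, 0), np.column_stack([counts] * 3))
        lo = (~detect_nonwear(s, thr)).sum()
        hi = (~detect_nonwear(s, thr + 5)).sum()
        assert hi <= lo


class TestClassification:
    @pytest.mark.parametrize(
        "count,expected",
        [(1, 0), (38, 1), (39, 2), (66, 2), (67, 3)],  # 60/2280/2340/3960/4020 cpm
    )
    def test_traditional_cut_points_at_one_second(self, count, expected):
        spec = DescriptorSpec.traditional()
        assert classify_epoch(count, 1, spec) == expected

    @pytest.mark.parametrize(
        "rate,expected",
        [(0, 0), (99, 0), (100, 1), (999, 1), (1000, 2), (14999, 15), (15000, 16), (15600, 16)],
    )
    def test_spectrum_bin_edges(self, rate, expected):
        spec = DescriptorSpec.spectrum_uniaxial()
        assert spec.classify_rates(np.array([rate]))[0] == expected

    def test_printed_boundary_inconsistency_preserved(self):
        # exactly 100 cpm is sedentary in the traditional descriptor (<= 100)
        # but falls in bin 2 (100-999) of the spectrum descriptor ([0,100) below)
        trad = DescriptorSpec.traditional()
        spect = DescriptorSpec.spectrum_uniaxial()
        assert trad.classify_rates(np.array([100]))[0] == 0
        assert spect.classify_rates(np.array([100]))[0] == 1

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify_epoch(-1, 1, DescriptorSpec.traditional())


class TestSummarizeDay:
    def test_two_level_day(self):
        # 200 min at ~50 cpm-equivalent (count 0..1) -> bin 1; 100 min at
        # 3000 cpm-equivalent (count 50) -> bin 5 (3000-3999)
        counts = np.zeros((300 * 60, 3), dtype=np.int64)
        counts[: 200 * 60] = 1  # 60 cpm
        counts[200 * 60 :] = 50  # 3000 cpm
        s = EpochSeries("kid", MONDAY, dt.time(8, 30), counts)
        day = summarize_day(s, None, DescriptorSpec.spectrum_uniaxial())
        assert day.bin_minutes["vertical"][0] == pytest.approx(200)
        assert day.bin_minutes["vertical"][4] == pytest.approx(100)
        assert day.wear_minutes == pytest.approx(300)

    def test_all_nonwear_day_is_empty(self):
        counts = np.zeros((3600, 3), dtype=np.int64)
        s = EpochSeries("kid", MONDAY, dt.time(9, 0), counts)
        mask = detect_nonwear(s)
        day = summarize_day(s, mask, DescriptorSpec.traditional())
        assert day.wear_minutes == 0
        assert day.bin_minutes["vertical"].sum() == 0

    def test_brute_force_oracle_and_closure(self, rng):
        """Per-epoch brute-force tally equals the vectorized summary exactly."""
        spec = DescriptorSpec.spectrum_triaxial()
        counts = rng.integers(0, 300, size=(3600, 3))
        counts[rng.random(3600) < 0.5] = 0
        s = EpochSeries("kid", MONDAY, dt.time(9, 0), counts)
        mask = detect_nonwear(s)
        day = summarize_day(s, mask, spec)
        for ax in AXES:
            col = AXES.index(ax)
            tally = np.zeros(17)
            for i in range(len(s)):
                if mask[i]:
                    b = classify_epoch(int(counts[i, col]), 1, spec, ax)
                    tally[b] += 1 / 60
            np.testing.assert_allclose(day.bin_minutes[ax], tally, atol=1e-9)
            assert day.bin_minutes[ax].sum() == pytest.approx(day.wear_minutes)


class TestAggregateChild:
    spec = DescriptorSpec.traditional()

    @staticmethod
    def _day(date, wear_min):
        n = int(wear_min * 60)
        s = EpochSeries("kid", date, dt.time(8, 30), np.full((n, 3), 1, dtype=np.int64))
        return summarize_day(s, None, DescriptorSpec.traditional())

    def test_three_valid_weekdays_valid(self):
        days = [self._day(MONDAY + dt.timedelta(d), 310) for d in range(3)]
        cs = aggregate_child(days, self.spec)
        assert cs.valid and cs.n_valid_days == 3
        assert cs.wear_minutes == pytest.approx(310)
        assert cs.values["sed"] == pytest.approx(310)

    def test_weekend_days_never_count(self):
        days = [self._day(MONDAY + dt.timedelta(d), 310) for d in (0, 1, 5, 6)]
        cs = aggregate_child(days, self.spec)
        assert not cs.valid and cs.values is None

    def test_short_wear_days_invalid(self):
        days = [self._day(MONDAY + dt.timedelta(d), 295) for d in range(4)]
        assert not aggregate_child(days, self.spec).valid

    def test_mixed_children_rejected(self):
        d1 = self._day(MONDAY, 310)
        d2 = self._day(MONDAY, 310)
        d2.child_id = "other"
        with pytest.raises(ValueError):
            aggregate_child([d1, d2], self.spec)


class TestEpochIO:
    def test_csv_roundtrip(self, tmp_path):
        series = generate_epochs(EpochSimConfig(), n_children=2, n_days=1, seed=3)
        path = tmp_path / "epochs.csv"
        epochs_to_csv(series, path)
        back = read_epoch_csv(path)
        assert len(back) == len(series)
        for a, b in zip(series, sorted(back, key=lambda s: s.child_id)):
            np.testing.assert_array_equal(a.counts, b.counts)
            assert a.start == b.start and a.date == b.date
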