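"""Pulse detection, event classification, censoring/exclusion, CAB and DAO."""

import numpy as np
import pandas as pd
import pytest

from finpam.calibrated_audio import AudioSegment
from finpam.call_analysis import (
    CountInterval,
    DetectorConfig,
    EventRidge,
    broadband_level,
    cab,
    classify_event,
    count_interval,
    daily_occurrence,
    detect_pulses,
    noise_gate_from_levels,
)
from finpam.synthetic_data import (
    CHORUS_TEMPLATE,
    FIN20_TEMPLATE,
    ZCALL_TEMPLATE,
    synthesize_pulse,
)

FS = 500.0
FLOOR_DB = 75.0


def noise(rng, duration_s, floor_db=FLOOR_DB):
    sigma = np.sqrt(10.0 ** (floor_db / 10.0) * FS / 2.0)
    return rng.normal(0.0, sigma, int(duration_s * FS))


def add_calls(x, times, template, snr_db):
    for t0 in times:
        y = synthesize_pulse(template, FS, snr_db=snr_db, noise_floor_db=FLOOR_DB)
        j = int(t0 * FS)
        x[j:j + len(y)] += y[:len(x) - j]
    return x


def segment(x, start="2013-05-12 06:00:00"):
    return AudioSegment(pd.Timestamp(start), FS, x)


class TestDetection:
    def test_eight_pulses_all_found(self, rng):
        truth = np.arange(8) * 7.0 + 2.0
        x = add_calls(noise(rng, 60.0), truth, FIN20_TEMPLATE, 20.0)
        fin = [e for e in detect_pulses(x, FS) if e.call_class == "fin20"]
        assert len(fin) == 8
        for t0 in truth:
            assert any(abs(e.time - t0) <= 0.25 for e in fin)

    def test_silence_and_noise_yield_no_detections(self, rng):
        assert detect_pulses(np.zeros(int(30 * FS)), FS) == []
        fa = sum(1 for s in range(20)
                 for e in detect_pulses(noise(np.random.default_rng(700 + s), 30.0), FS)
                 if e.call_class == "fin20")
        assert fa == 0

    def test_zcall_never_counted_as_pulse(self, rng):
        x = add_calls(noise(rng, 40.0), [5.0, 20.0], ZCALL_TEMPLATE, 18.0)
        events = detect_pulses(x, FS)
        assert all(e.call_class != "fin20" for e in events)

    def test_recall_degrades_monotonically_with_snr(self):
        recalls = []
        for snr in (15.0, 10.0, 5.0):
            hits = total = 0
            for s in range(8):
                rng = np.random.default_rng(40 + s)
                truth = np.arange(6) * 8.0 + 3.0
                x = add_calls(noise(rng, 55.0), truth, FIN20_TEMPLATE, snr)
                fin = [e.time for e in detect_pulses(x, FS)
                       if e.call_class == "fin20"]
                hits += sum(any(abs(f - t) <= 0.5 for f in fin) for t in truth)
                total += len(truth)
            recalls.append(hits / total)
        assert recalls[0] >= recalls[1] >= recalls[2]

    def test_segment_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_pulses(np.zeros(100), FS)


class TestClassifyRidge:
    def test_downsweep_ridge_is_fin20(self):
        t = np.arange(-0.2, 1.3, 0.064)
        f = np.clip(28.0 - 13.0 * t, 15.0, 28.0)
        lv = np.where((t >= 0) & (t <= 1.0), 20.0, 0.0)
        assert classify_event(EventRidge(t, f, lv)) == "fin20"

    def test_tonal_then_step_is_zcall(self):
        t = np.arange(-2.5, 1.3, 0.064)
        f = np.where(t < 0.1, 27.0, 19.0)
        lv = np.where((t > -2.0) & (t < 1.0), 18.0, 0.0)
        assert classify_event(EventRidge(t, f, lv)) == "zcall"

    def test_two_minute_band_is_chorus(self, rng):
        t = np.arange(0.0, 120.0, 0.064)
        f = rng.uniform(15, 30, t.size)
        lv = np.full(t.size, 6.0)
        assert classify_event(EventRidge(t, f, lv)) == "chorus"

    def test_flat_weak_ridge_is_other(self, rng):
        t = np.arange(-0.2, 1.3, 0.064)
        f = np.full(t.size, 22.0)
        lv = np.full(t.size, 6.0)
        assert classify_event(EventRidge(t, f, lv)) == "other"


class TestCountingAndCab:
    def test_censoring_above_limit(self, rng):
        truth = np.arange(8) * 7.0 + 2.0
        x = add_calls(noise(rng, 60.0), truth, FIN20_TEMPLATE, 15.0)
        iv = count_interval(segment(x), censor_limit=5)
        assert iv.censored and not iv.excluded
        assert iv.n_calls == 5  # reported as the '>limit' lower bound

    def test_noise_gate_excludes_loud_file(self, rng):
        x = noise(rng, 30.0, floor_db=95.0)
        level = broadband_level(x, FS)
        iv = count_interval(segment(x), noise_gate_db=level - 5.0)
        assert iv.excluded and np.isnan(iv.n_calls)

    def test_count_matches_detections(self, rng):
        truth = [3.0, 12.0, 21.0]
        x = add_calls(noise(rng, 30.0), truth, FIN20_TEMPLATE, 18.0)
        iv = count_interval(segment(x))
        assert iv.n_calls == 3 and not iv.censored and not iv.excluded

    def test_gate_is_95th_percentile_by_default(self):
        levels = np.arange(100.0)
        assert noise_gate_from_levels(levels) == pytest.approx(
            np.percentile(levels, 95))

    @staticmethod
    def _interval(n, minutes=10.0, censored=False, excluded=False):
        return CountInterval("f", pd.Timestamp("2013-05-12"), minutes * 60.0,
                             np.nan if excluded else float(n),
                             censored=censored, excluded=excluded)

    def test_cab_reproduces_258_per_hour(self):
        # 4301 calls over 100 ten-minute files = 1000 counted minutes
        intervals = [self._interval(43) for _ in range(99)] + [self._interval(44)]
        assert sum(iv.n_calls for iv in intervals) == 4301
        assert round(cab(intervals)) == 258

    def test_cab_simple_cases(self):
        assert cab([self._interval(0)]) == 0.0
        assert cab([self._interval(10)]) == pytest.approx(60.0)

    def test_cab_skips_censored_and_excluded(self):
        ivs = [self._interval(10), self._interval(100, censored=True),
               self._interval(0, excluded=True)]
        assert cab(ivs) == pytest.approx(60.0)

    def test_cab_invariant_to_ordering(self):
        ivs = [self._interval(n) for n in (5, 1, 9, 4)]
        assert cab(ivs) == cab(list(reversed(ivs)))

    def test_cab_requires_usable_intervals(self):
        with pytest.raises(ValueError):
            cab([self._interval(100, censored=True)])


class TestDailyOccurrence:
    def test_early_exit_after_first_pulse(self, rng):
        loads = []

        def loader(i, x):
            def _load():
                loads.append(i)
                return segment(x, pd.Timestamp("2013-05-12") + pd.Timedelta(hours=i))
            return _load

        files = []
        for i in range(5):
            x = noise(np.random.default_rng(i), 30.0)
            if i == 2:
                x = add_calls(x, [10.0], FIN20_TEMPLATE, 18.0)
            files.append(loader(i, x))
        occ = daily_occurrence(files)
        assert occ.present
        assert loads == [0, 1, 2]  # files 4+ never read
        assert occ.first_detection_time.floor("min") == pd.Timestamp(
            "2013-05-12 02:00")

    def test_chorus_only_day_is_absent(self, rng):
        x = noise(rng, 150.0)
        x += np.pad(synthesize_pulse(CHORUS_TEMPLATE, FS, snr_db=12.0,
                                     noise_floor_db=FLOOR_DB, rng=rng),
                    (int(10 * FS), int(20 * FS)))
        occ = daily_occurrence([segment(x)])
        assert not occ.present and occ.first_detection_time is None

    def test_noise_only_day_is_absent(self, rng):
        occ = daily_occurrence([segment(noise(rng, 30.0))])
        assert not occ.present
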