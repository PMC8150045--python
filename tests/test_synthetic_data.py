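"""Generator contracts: pulse morphology, schedules, ground truth,
determinism, ADCP cadence and ice fields."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import hilbert

from finpam.calibrated_audio import read_wav
from finpam.spectral_analysis import PsdConfig, welch_psd
from finpam.synthetic_data import (
    CHORUS_TEMPLATE,
    FIN20_TEMPLATE,
    FIN_HF_TEMPLATE,
    ZCALL_TEMPLATE,
    CallTemplate,
    RecordingSynthesizer,
    ScenarioConfig,
    SeasonalProfile,
    synthesize_adcp,
    synthesize_ice_field,
    synthesize_pulse,
    synthesize_recording_set,
)


def instantaneous_frequency(y: np.ndarray, fs: float) -> np.ndarray:
    phase = np.unwrap(np.angle(hilbert(y)))
    return np.gradient(phase) * fs / (2 * np.pi)


class TestPulseSynthesis:
    def test_fin20_sweep_endpoints_within_half_hz(self):
        fs = 32768.0
        y = synthesize_pulse(FIN20_TEMPLATE, fs)
        assert len(y) == 32768
        t = np.arange(len(y)) / fs
        f_inst = instantaneous_frequency(y, fs)
        # fit the linear sweep on the untapered core, extrapolate to the ends
        core = (t > 0.15) & (t < 0.85)
        b, a = np.polyfit(t[core], f_inst[core], 1)
        assert a == pytest.approx(28.0, abs=0.5)
        assert a + b * 1.0 == pytest.approx(15.0, abs=0.5)

    def test_pure_signal_energy_concentrated_in_sweep_band(self):
        fs = 512.0
        y = synthesize_pulse(FIN20_TEMPLATE, fs, snr_db=0.0, noise_floor_db=0.0)
        rec = welch_psd(np.tile(y, 4), PsdConfig(nfft=256, sample_rate=fs))
        df = rec.frequencies[1] - rec.frequencies[0]
        total = np.sum(rec.density_linear) * df
        sel = (rec.frequencies >= 15) & (rec.frequencies <= 30)
        in_band = np.sum(rec.density_linear[sel]) * df
        assert in_band / total > 0.9

    def test_hf_component_peaks_at_86_hz_with_1hz_bins(self):
        fs = 500.0
        y = synthesize_pulse(FIN_HF_TEMPLATE, fs)
        rec = welch_psd(np.tile(y, 2), PsdConfig(nfft=500, sample_rate=fs))
        assert rec.frequencies[np.argmax(rec.density_db)] == pytest.approx(86.0)

    def test_sub_nyquist_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="[Nn]yquist"):
            synthesize_pulse(FIN20_TEMPLATE, 50.0)

    def test_zcall_is_bitonal(self):
        fs = 500.0
        y = synthesize_pulse(ZCALL_TEMPLATE, fs)
        f_inst = instantaneous_frequency(y, fs)
        n = len(y)
        head = f_inst[int(0.1 * n):int(0.5 * n)]
        tail = f_inst[int(0.8 * n):int(0.95 * n)]
        assert np.median(head) == pytest.approx(27.0, abs=0.5)
        assert np.median(tail) == pytest.approx(19.0, abs=0.5)

    def test_template_invariants_enforced(self):
        with pytest.raises(ValueError):
            CallTemplate("fin20", 15.0, 28.0, 1.0)  # upsweep
        with pytest.raises(ValueError):
            CallTemplate("fin_hf", 70.0, 70.0, 1.0)  # centre outside 84-90
        with pytest.raises(ValueError):
            CallTemplate("fin20", 28.0, 15.0, -1.0)

    def test_chorus_band_limited(self, rng):
        fs = 500.0
        y = synthesize_pulse(CHORUS_TEMPLATE, fs, rng=rng)
        rec = welch_psd(y, PsdConfig(nfft=500, sample_rate=fs))
        inside = (rec.frequencies >= 16) & (rec.frequencies <= 29)
        outside = (rec.frequencies >= 40) & (rec.frequencies <= 100)
        assert rec.density_linear[inside].mean() > 1e4 * rec.density_linear[outside].mean()


class TestRecordingSet:
    def test_aural_day_has_24_files(self):
        cfg = ScenarioConfig.aural_like("2013-01-16", "2013-01-17", rng_seed=0)
        synth = RecordingSynthesizer(cfg, SeasonalProfile())
        assert len(synth) == 24

    def test_sonovault_day_has_144_files(self):
        cfg = ScenarioConfig.sonovault_like("2013-01-16", "2013-01-17", rng_seed=0)
        synth = RecordingSynthesizer(cfg, SeasonalProfile())
        assert len(synth) == 144

    def test_silent_profile_gives_empty_ground_truth(self):
        cfg = ScenarioConfig.scaled_year("2013-05-01", "2013-05-03", rng_seed=0,
                                         zcall_rate_per_10min=0.0)
        synth = RecordingSynthesizer(cfg, SeasonalProfile.silent())
        assert synth.ground_truth().empty

    def test_ground_truth_events_lie_inside_files(self):
        cfg = ScenarioConfig.scaled_year("2013-05-01", "2013-05-04", rng_seed=3,
                                         zcall_rate_per_10min=1.0)
        synth = RecordingSynthesizer(cfg, SeasonalProfile())
        truth = synth.ground_truth()
        assert not truth.empty
        n = int(cfg.file_duration_s * cfg.sample_rate)
        assert (truth["sample_index"] >= 0).all()
        assert (truth["sample_index"] < n).all()
        assert truth["recorded"].all()

    def test_poisson_call_counts_match_profile_mean(self):
        # flat profile, >=1000 one-minute intervals: empirical mean within 3 SE
        rate_10min = 5.0
        profile = SeasonalProfile(1, 180, 366, rate_10min, rate_10min, 0.0)
        cfg = ScenarioConfig(recorder="flat", sample_rate=512.0,
                             file_duration_s=60.0, duty=(1.0, 1.0),
                             start="2013-05-01", end="2013-05-01 20:00",
                             rng_seed=11, zcall_rate_per_10min=0.0)
        synth = RecordingSynthesizer(cfg, profile)
        n_files = len(synth)
        assert n_files == 1200
        truth = synth.ground_truth()
        counts = truth[truth["kind"] == "fin20"].groupby("file_index").size()
        mean = counts.reindex(range(n_files), fill_value=0).mean()
        expected = rate_10min / 10.0
        se = np.sqrt(expected / n_files)
        assert abs(mean - expected) < 3 * se

    def test_wav_output_byte_identical_across_runs(self, tmp_path):
        cfg = ScenarioConfig.scaled_year("2013-05-01", "2013-05-02", rng_seed=7,
                                         files_per_day=2, file_duration_s=10.0,
                                         zcall_rate_per_10min=1.0)
        profile = SeasonalProfile()
        m1, log1 = synthesize_recording_set(cfg, profile, tmp_path / "a")
        m2, log2 = synthesize_recording_set(cfg, profile, tmp_path / "b")
        assert list(m1["path"]) == list(m2["path"])
        for name in m1["path"]:
            b1 = (tmp_path / "a" / name).read_bytes()
            b2 = (tmp_path / "b" / name).read_bytes()
            assert b1 == b2
        pd.testing.assert_frame_equal(log1, log2)

    def test_wav_files_decode_to_rendered_counts(self, tmp_path):
        cfg = ScenarioConfig.scaled_year("2013-05-01", "2013-05-02", rng_seed=5,
                                         files_per_day=2, file_duration_s=10.0)
        synth = RecordingSynthesizer(cfg, SeasonalProfile())
        manifest = synth.write(tmp_path)
        rate, counts = read_wav(tmp_path / manifest["path"].iloc[0])
        assert rate == cfg.sample_rate
        np.testing.assert_array_equal(counts, synth.render_counts(0))

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig.aural_like("2013-01-17", "2013-01-16")


class TestSeasonalProfile:
    def test_background_outside_season(self):
        prof = SeasonalProfile()
        assert prof.rate_per_10min(30) == prof.background_rate_per_10min
        assert prof.rate_per_10min(300) == prof.background_rate_per_10min

    def test_maximum_at_peak_day(self):
        prof = SeasonalProfile()
        days = np.arange(1, 366)
        rates = [prof.rate_per_10min(float(d)) for d in days]
        assert days[int(np.argmax(rates))] == prof.peak_doy
        assert max(rates) == pytest.approx(prof.peak_rate_per_10min)

    def test_day_at_rate_fraction_inverts_profile(self):
        prof = SeasonalProfile()
        d = prof.day_at_rate_fraction(0.1, "rising")
        assert prof.rate_per_10min(d) == pytest.approx(
            0.1 * prof.peak_rate_per_10min, rel=1e-6)


class TestAdcp:
    def test_cadence_gives_32_ensembles_in_5_days(self):
        ens = synthesize_adcp(5, 100.0, seed=0)
        assert len(ens) == 32
        dt = ens[1].timestamp - ens[0].timestamp
        assert dt == pd.Timedelta(minutes=225)  # 3 h 45 min

    def test_counts_within_agc_scale(self):
        for e in synthesize_adcp(3, 80.0, seed=1):
            assert e.counts.min() >= 0 and e.counts.max() <= 255

    def test_zero_amplitude_layer_is_static(self):
        from finpam.environment import migration_amplitude, mvbs_series
        mig = migration_amplitude(mvbs_series(synthesize_adcp(10, 0.0, seed=2)))
        assert abs(mig.amplitude_m) <= 16.0  # within one bin

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            synthesize_adcp(2, -5.0)


class TestIceField:
    def test_zero_winter_peak_gives_all_zero_field(self):
        ice = synthesize_ice_field(days=10, winter_peak_fraction=0.0, seed=0)
        assert float(ice["concentration"].max()) == 0.0

    def test_values_bounded_and_winter_peaked(self):
        ice = synthesize_ice_field(days=365, winter_peak_fraction=1.0, seed=4)
        conc = ice["concentration"].values
        assert conc.min() >= 0.0 and conc.max() <= 100.0
        daily = conc.mean(axis=(1, 2))
        peak_day = ice["time"].values[int(np.argmax(daily))]
        assert pd.Timestamp(peak_day).month in (8, 9)  # austral winter

    def test_seeded_field_bit_identical(self):
        a = synthesize_ice_field(days=20, seed=9)
        b = synthesize_ice_field(days=20, seed=9)
        np.testing.assert_array_equal(a["concentration"].values,
                                      b["concentration"].values)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            synthesize_ice_field(days=5, winter_peak_fraction=1.5)
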