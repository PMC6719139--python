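import numpy as np
import pytest

from vcgbeat.errors import ParameterError
from vcgbeat.preprocess import UniformSignal, highpass_brickwall
from vcgbeat.synthetic import (GroundTruth, SimConfig, generate_beat_times,
                               read_ground_truth, synthesize_recording,
                               write_ground_truth)


class TestGenerateBeatTimes:
    def test_metronomic_beats(self):
        cfg = SimConfig(duration=10.0, mean_hr=60.0, hrv_sd=0.0, resp_mod=0.0)
        gt = generate_beat_times(cfg)
        np.testing.assert_allclose(gt.r_times, np.arange(10.0), atol=1e-12)
        np.testing.assert_allclose(gt.ao_times - gt.r_times, cfg.pep_delay)

    def test_recovery_profile_limits(self):
        cfg = SimConfig(duration=400.0, hr_trend=(140.0, 70.0, 60.0),
                        hrv_sd=0.0, resp_mod=0.0)
        gt = generate_beat_times(cfg)
        assert gt.rr_s[0] == pytest.approx(60.0 / 140.0, rel=0.02)
        assert gt.rr_s[-1] == pytest.approx(60.0 / 70.0, rel=0.02)

    def test_hrv_moment_recovery(self):
        cfg = SimConfig(duration=500.0, mean_hr=60.0, hrv_sd=0.05,
                        resp_mod=0.0, seed=3)
        gt = generate_beat_times(cfg)
        assert gt.rr_s.size >= 450
        cv = np.std(gt.rr_s) / np.mean(gt.rr_s)
        assert cv == pytest.approx(0.05, abs=0.007)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            generate_beat_times(SimConfig(mean_hr=-5.0))
        with pytest.raises(ParameterError):
            generate_beat_times(SimConfig(hrv_sd=-0.1))


class TestSynthesizeRecording:
    def test_seed_reproducibility(self):
        a, _ = synthesize_recording(SimConfig(duration=12.0, seed=9))
        b, _ = synthesize_recording(SimConfig(duration=12.0, seed=9))
        np.testing.assert_array_equal(a.timestamps, b.timestamps)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])

    def test_single_beat_morphology(self):
        cfg = SimConfig(duration=3.0, mean_hr=15.0, hrv_sd=0.0, resp_mod=0.0,
                        noise_snr_db=200.0, wander_frac=0.0, jitter_sd=0.0)
        rec, gt = synthesize_recording(cfg)
        assert gt.ao_times.size == 1
        az = rec.channels["aZ"]
        peak_t = rec.timestamps[np.argmax(np.abs(az))]
        assert abs(peak_t - gt.ao_times[0]) < 0.020
        # S2 packet present at the configured offset with relative amplitude
        s2_region = (rec.timestamps > gt.ao_times[0] + 0.25) & \
                    (rec.timestamps < gt.ao_times[0] + 0.35)
        assert np.max(np.abs(az[s2_region])) == pytest.approx(
            cfg.s2_rel_scg * np.max(np.abs(az)), rel=0.1)

    def test_gcg_s2_smaller_than_scg_s2(self, default_sim):
        cfg, _, _ = default_sim
        assert cfg.s2_rel_gcg < cfg.s2_rel_scg

    def test_timestamps_strictly_increasing(self, default_sim):
        _, rec, _ = default_sim
        assert np.all(np.diff(rec.timestamps) > 0)

    def test_wander_energy_removed_by_highpass(self):
        cfg = SimConfig(duration=30.0, seed=4)
        rec, _ = synthesize_recording(cfg)
        # evaluate on a uniform render of aZ
        n = int(30 * 200)
        t = np.arange(n) / 200.0
        x = np.interp(t, rec.timestamps, rec.channels["aZ"])
        sig = UniformSignal(x, 200.0, 0.0)
        filtered = highpass_brickwall(sig, 0.4)
        freqs = np.fft.rfftfreq(n, 1 / 200.0)
        low = freqs < 0.4
        before = np.sum(np.abs(np.fft.rfft(x))[low] ** 2)
        after = np.sum(np.abs(np.fft.rfft(filtered.values))[low] ** 2)
        assert after < 0.01 * before

    def test_ecg_recoverable_by_pan_tompkins(self):
        from vcgbeat.evaluation import match_beats
        from vcgbeat.pipeline import reference_rpeaks

        cfg = SimConfig(duration=30.0, mean_hr=72.0, noise_snr_db=200.0,
                        wander_frac=0.0, seed=6)
        rec, gt = synthesize_recording(cfg)
        peaks = reference_rpeaks(rec)
        c = match_beats(peaks.timestamps, gt.r_times[gt.r_times > 0.5], 0.020)
        assert c.fn == 0


def test_ground_truth_round_trip(tmp_path, default_sim):
    _, _, gt = default_sim
    path = tmp_path / "gt.csv"
    write_ground_truth(gt, path)
    back = read_ground_truth(path)
    np.testing.assert_allclose(back.r_times, gt.r_times, atol=1e-9)
    np.testing.assert_allclose(back.ao_times, gt.ao_times, atol=1e-9)
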