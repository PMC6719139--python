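import numpy as np
import pytest

from vcgbeat.errors import ParameterError
from vcgbeat.hr_autocorr import (WindowEstimate, consolidate_axes, fuse_windows,
                                 hr_from_window, run_hr_pipeline)
from vcgbeat.signal_io import stream_buffers
from vcgbeat.varwin import EnhancedSignal

FS = 200.0


def _enh(x):
    return EnhancedSignal(np.asarray(x, dtype=float), FS, 0.0, "hr", 250.0)


def _train(rate_hz, seconds=10.0):
    n = int(seconds * FS)
    x = np.zeros(n)
    idx = np.round(np.arange(0, seconds, 1.0 / rate_hz) * FS).astype(int)
    x[idx[idx < n]] = 1.0
    return x


class TestHrFromWindow:
    def test_one_hz_impulse_train(self):
        est = hr_from_window(_enh(_train(1.0)))
        assert est.hr_bpm == pytest.approx(60.0, abs=1.0)
        assert est.hr_bpm == pytest.approx(60.0 / est.btb_s, abs=1e-9)

    def test_high_rate_impulse_train(self):
        est = hr_from_window(_enh(_train(2.2)))
        assert est.hr_bpm == pytest.approx(132.0, abs=2.0)

    def test_white_noise_is_mostly_absent(self):
        absent = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            est = hr_from_window(_enh(np.abs(rng.normal(0, 1, 2000))))
            absent += est.hr_bpm is None
        assert absent >= 95

    def test_all_zero_input_is_absent(self):
        est = hr_from_window(_enh(np.zeros(2000)))
        assert est.hr_bpm is None

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ParameterError):
            hr_from_window(_enh(_train(1.0)), bounds=(200.0, 30.0))

    def test_subharmonic_resisted(self):
        """A 2 s-period candidate must lose to the true 1 s beat lag."""
        est = hr_from_window(_enh(_train(1.0)), bounds=(25.0, 200.0))
        assert est.hr_bpm == pytest.approx(60.0, abs=1.5)


class TestFuseWindows:
    def test_equal_estimates(self):
        ests = [WindowEstimate(float(n), "aZ", 60.0, 1.0) for n in range(2, 11)]
        assert fuse_windows(ests) == pytest.approx(60.0)

    def test_inverse_size_weighting(self):
        ests = [WindowEstimate(2.0, "aZ", 60.0, 1.0),
                WindowEstimate(10.0, "aZ", 70.0, 60.0 / 70.0)]
        assert fuse_windows(ests) == pytest.approx(61.6667, abs=1e-3)

    def test_single_present_estimate(self):
        ests = [WindowEstimate(2.0, "aZ", None, None),
                WindowEstimate(5.0, "aZ", 85.0, 60.0 / 85.0),
                WindowEstimate(10.0, "aZ", None, None)]
        assert fuse_windows(ests) == pytest.approx(85.0)

    def test_all_absent_gives_none(self):
        assert fuse_windows([WindowEstimate(2.0, "aZ", None, None)]) is None

    def test_mixed_axes_rejected(self):
        with pytest.raises(ParameterError):
            fuse_windows([WindowEstimate(2.0, "aZ", 60.0, 1.0),
                          WindowEstimate(2.0, "gX", 60.0, 1.0)])


class TestConsolidateAxes:
    def test_agreement_averages(self):
        m = consolidate_axes(70.0, 72.0, None, 10.0)
        assert (m.hr_bpm, m.source) == (71.0, "both-agree")

    def test_disagreement_prefers_closer_to_previous(self):
        m = consolidate_axes(70.0, 90.0, 68.0, 10.0)
        assert (m.hr_bpm, m.source) == (70.0, "scg-selected")
        m = consolidate_axes(70.0, 90.0, 88.0, 10.0)
        assert (m.hr_bpm, m.source) == (90.0, "gcg-selected")

    def test_exact_agreement_identity(self):
        for prev in (None, 10.0, 300.0):
            assert consolidate_axes(66.0, 66.0, prev, 10.0).hr_bpm == 66.0

    def test_equidistant_tie_resolves_to_scg(self):
        m = consolidate_axes(60.0, 80.0, 70.0, 10.0 - 1e-9)
        assert m.source == "scg-selected"

    def test_single_axis_and_carry_forward(self):
        assert consolidate_axes(75.0, None, None, 10.0).source == "scg-selected"
        assert consolidate_axes(None, 75.0, None, 10.0).source == "gcg-selected"
        m = consolidate_axes(None, None, 64.0, 10.0)
        assert (m.hr_bpm, m.source) == (64.0, "carry-forward")
        assert consolidate_axes(None, None, None, 10.0).hr_bpm is None


def test_run_hr_pipeline_on_clean_recording(default_sim):
    _, rec, gt = default_sim
    seg = next(stream_buffers(rec, 10.0, 1.0))
    m = run_hr_pipeline(seg, None)
    true_hr = np.mean(60.0 / np.diff(gt.r_times[gt.r_times <= 10.0]))
    assert m.present
    assert m.hr_bpm == pytest.approx(true_hr, abs=2.0)
    assert m.source == "both-agree"


def test_run_hr_pipeline_without_gyro(default_sim):
    _, rec, _ = default_sim
    stripped = type(rec)(timestamps=rec.timestamps,
                         channels={"aZ": rec.channels["aZ"]}, meta=dict(rec.meta))
    seg = next(stream_buffers(stripped, 10.0, 1.0))
    m = run_hr_pipeline(seg, None)
    assert m.present
    assert m.source == "scg-selected"
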