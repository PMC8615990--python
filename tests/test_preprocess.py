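import numpy as np
import pandas as pd
import pytest
from scipy import signal

import erpdecode as ed
from erpdecode.preprocess import RawRecording

from conftest import make_epochs


def _raw(data, sfreq=250.0):
    data = np.atleast_2d(data)
    return RawRecording(data, sfreq, [f"E{i+1}" for i in range(len(data))])


class TestBandpass:
    def test_dc_is_rejected(self):
        raw = _raw(np.full((2, 2000), 7.5))
        out = ed.bandpass(raw)
        assert np.abs(out.data).max() < 1e-6 * 7.5

    def test_passband_sinusoid_amplitude_and_zero_lag(self):
        sfreq, f0 = 250.0, 10.0
        t = np.arange(5000) / sfreq
        x = np.sin(2 * np.pi * f0 * t)
        out = ed.bandpass(_raw(x)).data[0]
        interior = slice(500, -500)
        # analytic magnitude of the forward-backward cascaded filter
        sos = signal.butter(2, [1, 40], btype="bandpass", fs=sfreq,
                            output="sos")
        _, h = signal.sosfreqz(sos, worN=[f0], fs=sfreq)
        expected = np.abs(h[0]) ** 2  # applied twice
        amp = np.abs(out[interior]).max()
        assert 0.9 <= amp <= 1.0
        assert abs(amp - expected) < 0.02
        # zero phase: cross-correlation peaks at lag 0
        xc = np.correlate(out[interior], x[interior], mode="full")
        assert np.argmax(xc) == len(out[interior]) - 1

    def test_stopband_sinusoid_attenuated(self):
        sfreq = 250.0
        t = np.arange(5000) / sfreq
        x = np.sin(2 * np.pi * 60.0 * t)
        out = ed.bandpass(_raw(x)).data[0]
        assert np.abs(out[500:-500]).max() < 0.1

    def test_invalid_band_raises(self):
        raw = _raw(np.zeros((1, 500)))
        for low, high in [(0, 40), (40, 1), (1, 200)]:
            with pytest.raises(ValueError):
                ed.bandpass(raw, low, high)


class TestCommonAverage:
    def test_identical_channels_become_zero(self):
        raw = _raw(np.tile(np.random.default_rng(0).standard_normal(100),
                           (4, 1)))
        assert np.allclose(ed.common_average(raw).data, 0.0)

    def test_column_means_vanish(self):
        rng = np.random.default_rng(1)
        raw = _raw(rng.standard_normal((5, 200)))
        out = ed.common_average(raw)
        assert np.abs(out.data.mean(axis=0)).max() <= 1e-10
        ep = make_epochs(rng.standard_normal((6, 4, 50)))
        out_ep = ed.common_average(ep)
        assert np.abs(out_ep.data.mean(axis=1)).max() <= 1e-10

    def test_two_channel_hand_computation(self):
        a, b = np.arange(10.0), np.linspace(3, -4, 10)
        out = ed.common_average(_raw(np.stack([a, b])))
        assert np.allclose(out.data[0], (a - b) / 2)
        assert np.allclose(out.data[1], (b - a) / 2)

    def test_single_channel_raises(self):
        with pytest.raises(ValueError):
            ed.common_average(_raw(np.zeros((1, 100))))


class TestEpoch:
    def _events(self, onsets, conds=None, types=None):
        n = len(onsets)
        return pd.DataFrame({
            "onset_sample": onsets,
            "condition": conds or ["near"] * n,
            "trial_type": types or ["go"] * n,
            "rt_ms": [900.0] * n,
        })

    def test_sample_count(self):
        raw = _raw(np.zeros((2, 2000)))
        ep = ed.epoch(raw, self._events([1000]))
        assert ep.data.shape == (1, 2, 750)
        assert ep.times_ms[0] == -1500.0
        assert ep.times_ms[-1] == 1496.0

    def test_edge_event_dropped_with_warning(self):
        raw = _raw(np.zeros((2, 2000)))
        with pytest.warns(UserWarning, match="dropped 1 event"):
            ep = ed.epoch(raw, self._events([10, 1000]))
        assert ep.n_trials == 1

    def test_nogo_events_excluded_and_counts_match(self, null_study):
        raw = RawRecording(null_study.recordings[0], null_study.sfreq_hz,
                           null_study.ch_names, "S00")
        ev = null_study.events[0]
        ep = ed.epoch(raw, ev)
        n_go = int((ev["trial_type"] == "go").sum())
        assert ep.n_trials == n_go
        assert (ep.labels == 1).sum() == int(
            ((ev.trial_type == "go") & (ev.condition == "near")).sum())

    def test_label_encoding(self):
        raw = _raw(np.zeros((2, 3000)))
        ep = ed.epoch(raw, self._events([600, 1800], conds=["near", "far"]))
        assert list(ep.labels) == [1, -1]


class TestBaseline:
    def test_constant_becomes_zero_and_idempotent(self):
        ep = make_epochs(np.full((3, 2, 750), 5.0))
        out = ed.baseline_correct(ep)
        assert np.allclose(out.data, 0.0)
        again = ed.baseline_correct(out)
        assert np.allclose(again.data, out.data)

    def test_window_means_vanish(self):
        rng = np.random.default_rng(2)
        ep = make_epochs(rng.standard_normal((4, 3, 750)))
        out = ed.baseline_correct(ep, (-1500, -1200))
        m = out.time_mask((-1500, -1200))
        assert np.abs(out.data[:, :, m].mean(axis=2)).max() <= 1e-10

    def test_empty_window_raises(self):
        ep = make_epochs(np.zeros((2, 2, 750)))
        with pytest.raises(ValueError):
            ed.baseline_correct(ep, (-3000, -2900))


class TestRejectArtifacts:
    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng.standard_normal((8, 2, 100)),
                         labels=[1, -1] * 4)
        out = ed.reject_artifacts(ep, peak_to_peak_uv=np.inf, min_epochs=1)
        assert out.n_trials == 8

    def test_spiked_epoch_removed_exactly(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((10, 3, 100))
        data[4, 1, 50] += 100.0  # 10x the background amplitude
        ep = make_epochs(data, labels=[1, -1] * 5)
        out = ed.reject_artifacts(ep, peak_to_peak_uv=20.0, min_epochs=1)
        assert out.n_trials == 9
        assert np.array_equal(out.data, np.delete(data, 4, axis=0))
        assert out.n_rejected["n_rejected"] == 1

    def test_min_epochs_boundary(self):
        data = np.zeros((79, 2, 50))  # 40 near / 39 far, all clean
        ep = make_epochs(data, labels=[1] * 40 + [-1] * 39)
        with pytest.raises(ValueError, match="far"):
            ed.reject_artifacts(ep, peak_to_peak_uv=150.0, min_epochs=40)
        ed.reject_artifacts(ep, peak_to_peak_uv=150.0, min_epochs=39)

    def test_nonpositive_threshold_raises(self):
        ep = make_epochs(np.zeros((2, 2, 50)))
        with pytest.raises(ValueError):
            ed.reject_artifacts(ep, peak_to_peak_uv=0.0)


class TestPipelineInvariants:
    def test_baseline_and_car_commute(self):
        rng = np.random.default_rng(5)
        ep = make_epochs(rng.standard_normal((5, 4, 750)))
        a = ed.common_average(ed.baseline_correct(ep))
        b = ed.baseline_correct(ed.common_average(ep))
        assert np.abs(a.data - b.data).max() <= 1e-10

    def test_filter_then_epoch_equals_epoch_padded_then_trim(self):
        """Filtering continuous data then cutting equals filtering a padded
        segment then trimming, on interior samples."""
        rng = np.random.default_rng(6)
        raw = _raw(rng.standard_normal((2, 6000)))
        ev = pd.DataFrame({"onset_sample": [3000], "condition": ["near"],
                           "trial_type": ["go"], "rt_ms": [900.0]})
        a = ed.epoch(ed.bandpass(raw), ev).data[0]
        pad = 1500  # 6 s context on each side
        seg = raw.data[:, 3000 - 375 - pad:3000 + 375 + pad]
        b = ed.bandpass(_raw(seg)).data[:, pad:-pad]
        interior = slice(50, -50)
        assert np.abs(a[:, interior] - b[:, interior]).max() < 1e-6

    def test_preprocess_study_shapes(self, null_epochs, null_study):
        cfg = null_study.config
        n_go = 2 * cfg.n_trials_per_condition * cfg.n_subjects
        assert null_epochs.n_trials == n_go  # no artifacts at default threshold
        assert null_epochs.data.shape[1:] == (cfg.n_channels, 750)
        assert set(null_epochs.subject_ids) == set(null_study.subject_ids())
        m = null_epochs.time_mask((-1500, -1200))
        assert np.abs(null_epochs.data[:, :, m].mean(axis=2)).max() <= 1e-9
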