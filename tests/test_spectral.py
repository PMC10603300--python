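"""Filtering, epoching, Morlet maps, ERD and feature vectors vs oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sg

from coupledraw import spectral
from coupledraw.core import BAND_PRESETS, MOTOR_CHANNELS, EEGSession

BANDS = BAND_PRESETS["default"]
FS = 256.0


def _session(data, events=None):
    chans = [f"ch{i}" for i in range(data.shape[0])]
    return EEGSession(data=data, channels=chans, sfreq=FS,
                      events=events if events is not None else pd.DataFrame())


class TestBandpass:
    def test_stopband_and_passband(self):
        t = np.arange(int(20 * FS)) / FS
        sess = _session(np.vstack([np.sin(2 * np.pi * 50 * t),
                                   np.sin(2 * np.pi * 10 * t)]))
        out = spectral.bandpass_filter(sess)
        mid = slice(int(2 * FS), int(18 * FS))  # avoid filter edges
        # 50 Hz sits half an octave above the 35 Hz corner: the 4th-order
        # zero-phase Butterworth attenuates it to below 10 % amplitude
        assert np.abs(out.data[0, mid]).max() < 0.1
        assert np.abs(out.data[1, mid]).max() > 0.95      # 10 Hz preserved

    def test_white_noise_spectrum_shaped(self, rng):
        sess = _session(rng.standard_normal((1, int(60 * FS))))
        out = spectral.bandpass_filter(sess)
        f, p = sg.periodogram(out.data[0], fs=FS)  # periodogram oracle
        p45 = p[(f > 43) & (f < 47)].mean()
        p10 = p[(f > 8) & (f < 12)].mean()
        assert p45 / p10 < 0.05

    def test_invalid_corners_rejected(self, rng):
        sess = _session(rng.standard_normal((1, 1000)))
        with pytest.raises(ValueError):
            spectral.bandpass_filter(sess, 35.0, 0.5)
        with pytest.raises(ValueError):
            spectral.bandpass_filter(sess, 1.0, 200.0)


class TestRereference:
    def test_reference_channel_becomes_zero(self, rng):
        data = rng.standard_normal((3, 1000))
        sess = EEGSession(data=data, channels=["a", "b", "c"], sfreq=FS)
        out = spectral.rereference(sess, ["c"])
        assert np.allclose(out.data[2], 0.0)

    def test_matches_direct_arithmetic(self, rng):
        data = rng.standard_normal((4, 500))
        sess = EEGSession(data=data, channels=["a", "b", "m1", "m2"], sfreq=FS)
        out = spectral.rereference(sess, ["m1", "m2"])
        expected = data - (data[2] + data[3]) / 2  # direct oracle
        assert np.allclose(out.data, expected)
        # two equal references are the same as subtracting one of them
        sess2 = EEGSession(data=np.vstack([data[0], data[2], data[2]]),
                           channels=["a", "m1", "m1b"], sfreq=FS)
        out2 = spectral.rereference(sess2, ["m1", "m1b"])
        assert np.allclose(out2.data[0], data[0] - data[2])

    def test_empty_reference_is_passthrough(self, rng):
        data = rng.standard_normal((2, 100))
        sess = EEGSession(data=data, channels=["a", "b"], sfreq=FS)
        assert np.array_equal(spectral.rereference(sess, []).data, data)

    def test_missing_reference_reported(self, rng):
        sess = EEGSession(data=rng.standard_normal((2, 100)),
                          channels=["a", "b"], sfreq=FS)
        with pytest.raises(ValueError, match="M9"):
            spectral.rereference(sess, ["M9"])


class TestEpoching:
    def _events(self, rows):
        return pd.DataFrame(rows, columns=["trial_id", "onset_s", "offset_s", "condition"])

    def test_epoch_length_is_pre_plus_trial(self, rng):
        ev = self._events([(0, 5.0, 12.0, "line-line")])
        sess = _session(rng.standard_normal((2, int(20 * FS))), ev)
        (ep,) = spectral.epoch_trials(sess)
        assert ep.data.shape[1] == int(9 * FS) == 2304

    def test_insufficient_preonset_excluded(self, rng, caplog):
        ev = self._events([(0, 1.0, 6.0, "line-line"), (1, 12.0, 18.0, "circle-circle")])
        sess = _session(rng.standard_normal((1, int(25 * FS))), ev)
        eps = spectral.epoch_trials(sess)
        assert [e.trial_id for e in eps] == [1]

    def test_boundaries_match_event_table(self, rng):
        onsets = [5.0, 17.3, 31.9]
        durs = [6.0, 7.5, 4.25]
        ev = self._events([(i, o, o + d, "line-line")
                           for i, (o, d) in enumerate(zip(onsets, durs))])
        data = rng.standard_normal((1, int(45 * FS)))
        sess = _session(data, ev)
        for ep, o, d in zip(spectral.epoch_trials(sess), onsets, durs):
            i0 = int(round((o - 2.0) * FS))   # index arithmetic oracle
            i1 = int(round((o + d) * FS))
            assert np.array_equal(ep.data[0], data[0, i0:i1])


class TestMorlet:
    def test_peak_at_stimulus_frequency(self):
        t = np.arange(int(8 * FS)) / FS
        power = spectral.morlet_tf(np.sin(2 * np.pi * 10 * t)[None, :], FS)
        avg = power[0].mean(axis=0)
        peak = spectral.FREQ_GRID[np.argmax(avg)]
        nearest = spectral.FREQ_GRID[np.argmin(np.abs(spectral.FREQ_GRID - 10))]
        assert peak == nearest

    def test_zero_signal_zero_power_and_quadratic_scaling(self, rng):
        x = rng.standard_normal(int(8 * FS))
        assert np.allclose(spectral.morlet_tf(np.zeros((1, int(8 * FS))), FS), 0.0)
        p1 = spectral.morlet_tf(x[None, :], FS)
        p2 = spectral.morlet_tf(2 * x[None, :], FS)
        assert np.allclose(p2, 4 * p1, rtol=1e-10)

    def test_short_epoch_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter than"):
            spectral.morlet_tf(rng.standard_normal((1, int(2 * FS))), FS)


class TestBaselineLogratio:
    def test_reference_levels(self, rng):
        base = rng.random(50) + 0.5
        power = np.tile(base, (30, 1))
        assert np.allclose(spectral.baseline_logratio(power, base), 0.0)
        assert np.allclose(spectral.baseline_logratio(10 * power, base), 1.0)
        assert np.allclose(spectral.baseline_logratio(power / 10, base), -1.0)

    def test_zero_baseline_reported(self):
        base = np.ones(50)
        base[3] = 0.0
        with pytest.raises(ValueError, match="baseline"):
            spectral.baseline_logratio(np.ones((10, 50)), base)


class TestResample:
    def test_constant_and_ramp_preserved(self):
        const = np.full((37, 5), 3.3)
        assert np.allclose(spectral.resample_time(const), 3.3)
        ramp = np.linspace(0, 1, 64)[:, None] * np.ones((1, 5))
        out = spectral.resample_time(ramp)
        assert np.allclose(out[:, 0], np.linspace(0, 1, 200), atol=1e-12)

    def test_matches_interp_oracle(self, rng):
        m = rng.standard_normal((33, 7))
        out = spectral.resample_time(m)
        for j in range(7):  # independent per-row interpolation oracle
            expected = np.interp(np.linspace(0, 1, 200), np.linspace(0, 1, 33), m[:, j])
            assert np.allclose(out[:, j], expected)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spectral.resample_time(np.ones((1, 5)))


class TestFeatures:
    def _map(self, values):
        return spectral.TimeFrequencyMap(trial_id=0, channel="C3", values=values)

    def test_erd_of_constant_maps(self):
        assert spectral.compute_erd(self._map(np.full((200, 50), -0.5)), BANDS[0]) == -0.5
        assert spectral.compute_erd(self._map(np.zeros((200, 50))), BANDS[1]) == 0.0

    def test_erd_matches_two_loop_oracle(self, rng):
        vals = rng.standard_normal((200, 50))
        tf = self._map(vals)
        for band in BANDS:
            total, count = 0.0, 0
            for ti in range(200):            # explicit two-loop summation
                for fi in range(50):
                    f = spectral.FREQ_GRID[fi]
                    inband = (band.lo <= f <= band.hi) if band.closed_right \
                        else (band.lo <= f < band.hi)
                    if inband:
                        total += vals[ti, fi]
                        count += 1
            assert spectral.compute_erd(tf, band) == pytest.approx(total / count)

    def test_band_outside_grid_reported(self):
        from coupledraw.core import BandSpec
        narrow = BandSpec("narrow", 20.0, 20.1)
        with pytest.raises(ValueError, match="no grid"):
            spectral.compute_erd(self._map(np.zeros((200, 50))), narrow)

    def test_feature_vector_shape_order_and_oracle(self, rng):
        tfs = {ch: spectral.TimeFrequencyMap(0, ch, rng.standard_normal((200, 50)))
               for ch in MOTOR_CHANNELS}
        vec = spectral.build_feature_vector(tfs, BANDS)
        assert vec.shape == (3600,)
        # per-time-point band-mean oracle, channel-major then band order
        k = 0
        for ch in MOTOR_CHANNELS:
            for band in BANDS:
                mask = band.mask(spectral.FREQ_GRID)
                expected = tfs[ch].values[:, mask].mean(axis=1)
                assert np.allclose(vec[k * 200:(k + 1) * 200], expected)
                k += 1

    def test_constant_maps_give_constant_vector(self):
        tfs = {ch: spectral.TimeFrequencyMap(0, ch, np.full((200, 50), 0.25))
               for ch in MOTOR_CHANNELS}
        assert np.allclose(spectral.build_feature_vector(tfs, BANDS), 0.25)

    def test_missing_channel_reported_by_name(self):
        tfs = {ch: spectral.TimeFrequencyMap(0, ch, np.zeros((200, 50)))
               for ch in MOTOR_CHANNELS if ch != "CPz"}
        with pytest.raises(ValueError, match="CPz"):
            spectral.build_feature_vector(tfs, BANDS)

    def test_erd_equals_time_mean_of_feature_block(self, nonlinear_chain):
        """Univariate and multivariate features agree: each ERD value is the
        time-mean of the matching 200-point band time-course."""
        erd = nonlinear_chain["erd"].set_index("trial_id")
        feats = nonlinear_chain["features"]
        k = 0
        for ch in MOTOR_CHANNELS:
            for band in BANDS:
                block_mean = feats.iloc[:, k * 200:(k + 1) * 200].mean(axis=1)
                assert np.allclose(block_mean, erd[f"{ch}_{band.name}"], atol=1e-12)
                k += 1

    def test_map_shapes(self, nonlinear_chain):
        maps = nonlinear_chain["maps"]
        some = next(iter(maps.values()))
        for tf in some.values():
            assert tf.values.shape == (200, 50)
        assert nonlinear_chain["features"].shape == (240, 3600)


class TestBaselineSelfConsistency:
    def test_stationary_signal_gives_zero_mean_erd(self, rng):
        """When the trial window is statistically identical to baseline the
        ERD distribution is centred on zero."""
        n_trials = 12
        dur, rest = 6.0, 5.0
        total = rest + n_trials * (dur + rest)
        data = rng.standard_normal((1, int(total * FS)))
        rows, t0 = [], rest
        for i in range(n_trials):
            rows.append((i, t0, t0 + dur, "line-line"))
            t0 += dur + rest
        ev = pd.DataFrame(rows, columns=["trial_id", "onset_s", "offset_s", "condition"])
        sess = EEGSession(data=data, channels=["C3"], sfreq=FS, events=ev)
        epochs = spectral.epoch_trials(sess)
        erds = []
        for ep in epochs:
            (tf,) = spectral.epoch_tf_maps(ep, channels=["C3"])
            erds.append(spectral.compute_erd(tf, BANDS[0]))
        # Monte-Carlo-style bound: mean of n_trials ERDs, each with sd well
        # below 0.2 log10 units for stationary noise
        assert abs(np.mean(erds)) < 3 * 0.2 / np.sqrt(n_trials)
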