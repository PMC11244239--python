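import numpy as np
import pytest
from scipy import signal as sig

from strokeeg.data import EegRecording
from strokeeg.errors import EmptyResultWarning, ParameterError, UnrecoverableDataError
from strokeeg.montage import CHANNELS, POSITIONS
from strokeeg.preprocess import (
    bandpass_filter,
    interpolate_bad_channels,
    reject_artifact_epochs,
    segment,
)


def _sine_recording(freq: float, duration: float = 60.0, fs: float = 256.0,
                    n_channels: int = 19) -> EegRecording:
    t = np.arange(int(fs * duration)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return EegRecording(data=data, fs=fs)


class TestBandpassFilter:
    def test_mains_interference_suppressed(self):
        """50 Hz input must be attenuated at least 40 dB (steady state)."""
        rec = _sine_recording(50.0)
        out = bandpass_filter(rec).data[0]
        fs = 256
        interior = slice(2 * fs, -2 * fs)  # skip high-pass edge transients
        rms_in = np.sqrt(np.mean(rec.data[0][interior] ** 2))
        rms_out = np.sqrt(np.mean(out[interior] ** 2))
        assert rms_out <= 0.01 * rms_in
        # the designed response itself (two-pass magnitude) is below -40 dB
        sos = sig.butter(8, [1, 35], btype="band", fs=256, output="sos")
        _, h = sig.sosfreqz(sos, worN=[50.0], fs=256)
        assert 20 * np.log10(np.abs(h[0]) ** 2) < -40

    def test_passband_preserved(self):
        rec = _sine_recording(10.0)
        out = bandpass_filter(rec).data[0]
        rms_ratio = np.sqrt(np.mean(out ** 2)) / np.sqrt(np.mean(rec.data[0] ** 2))
        assert abs(rms_ratio - 1.0) < 0.12
        # passband ripple < 1 dB at 10 Hz from the transfer function
        sos = sig.butter(8, [1, 35], btype="band", fs=256, output="sos")
        _, h = sig.sosfreqz(sos, worN=[10.0], fs=256)
        assert abs(20 * np.log10(np.abs(h[0]) ** 2)) < 1.0

    def test_zero_signal_maps_to_zero(self):
        rec = EegRecording(data=np.zeros((19, 1024)))
        assert np.allclose(bandpass_filter(rec).data, 0.0)

    def test_idempotent_up_to_ripple(self, realistic_recording):
        once = bandpass_filter(realistic_recording)
        twice = bandpass_filter(once)
        rms1 = np.sqrt(np.mean(once.data ** 2))
        rms2 = np.sqrt(np.mean(twice.data ** 2))
        assert abs(rms2 - rms1) / rms1 < 0.02

    def test_cutoff_beyond_nyquist_rejected(self, realistic_recording):
        with pytest.raises(ParameterError):
            bandpass_filter(realistic_recording, 1.0, 130.0)
        with pytest.raises(ParameterError):
            bandpass_filter(realistic_recording, 40.0, 35.0)


class TestInterpolateBadChannels:
    def test_empty_bad_list_is_identity(self, realistic_recording):
        out = interpolate_bad_channels(realistic_recording, [])
        assert np.array_equal(out.data, realistic_recording.data)

    def test_interpolated_channel_tracks_neighbor(self, rng):
        """Corrupt a channel with a copy of its nearest neighbor, mark it
        bad: the repair should correlate strongly with that neighbor.

        Interpolation presumes spatial smoothness (volume-conducted EEG
        is strongly correlated between nearby electrodes), so the fixture
        is a shared source plus small independent per-channel noise.
        """
        t = np.arange(256 * 8) / 256.0
        source = 20 * np.sin(2 * np.pi * 10 * t) + 10 * np.sin(2 * np.pi * 4 * t)
        data = source + rng.normal(0, 2.0, size=(19, t.size))
        rec = EegRecording(data=data)
        names = list(rec.channel_names)
        target = "Cz"
        dists = {n: np.linalg.norm(POSITIONS[n] - POSITIONS[target])
                 for n in names if n != target}
        neighbor = min(dists, key=dists.get)
        data = rec.data.copy()
        data[names.index(target)] = data[names.index(neighbor)]
        out = interpolate_bad_channels(rec.copy_with(data=data), [target])
        interp = out.data[names.index(target)]
        nb = out.data[names.index(neighbor)]
        corr = np.corrcoef(interp, nb)[0, 1]
        assert corr > 0.9
        # good channels untouched
        good_idx = [i for i, n in enumerate(names) if n != target]
        assert np.array_equal(out.data[good_idx], data[good_idx])

    def test_constant_cohort_reproduces_common_value(self):
        data = np.full((19, 512), 3.25)
        rec = EegRecording(data=data)
        out = interpolate_bad_channels(rec, ["F3", "O2"])
        assert np.allclose(out.data, 3.25)

    def test_unknown_channel_rejected(self, realistic_recording):
        with pytest.raises(ParameterError):
            interpolate_bad_channels(realistic_recording, ["Xx9"])

    def test_nearly_all_bad_rejected(self, realistic_recording):
        with pytest.raises(UnrecoverableDataError):
            interpolate_bad_channels(realistic_recording, list(CHANNELS)[:-2])


class TestSegment:
    def test_five_minutes_gives_300_epochs(self):
        rec = EegRecording(data=np.zeros((19, 300 * 256)))
        ep = segment(rec, 1.0)
        assert ep.n_epochs == 300
        assert ep.samples_per_epoch == 256

    def test_trailing_remainder_dropped(self):
        rec = EegRecording(data=np.zeros((19, int(256.5 * 256))))
        assert segment(rec, 1.0).n_epochs == 256

    def test_partition_property(self, realistic_recording):
        rec = realistic_recording
        ep = segment(rec, 1.0)
        n_kept = ep.n_epochs * ep.samples_per_epoch
        recon = ep.epochs.transpose(1, 0, 2).reshape(rec.n_channels, n_kept)
        assert np.array_equal(recon, rec.data[:, :n_kept])

    def test_too_short_warns_empty(self):
        rec = EegRecording(data=np.zeros((19, 100)))
        with pytest.warns(EmptyResultWarning):
            ep = segment(rec, 1.0)
        assert ep.n_epochs == 0


class TestRejectArtifactEpochs:
    @pytest.fixture
    def epochs(self, realistic_recording):
        return segment(realistic_recording, 1.0)

    def test_infinite_threshold_is_identity(self, epochs):
        out = reject_artifact_epochs(epochs, np.inf)
        assert np.array_equal(out.epochs, epochs.epochs)

    def test_spiked_epoch_removed(self, epochs):
        data = epochs.epochs.copy()
        thr = float(np.abs(data).max()) * 1.5
        data[4, 0, 10] = 10 * thr
        spiked = reject_artifact_epochs(
            type(epochs)(epochs=data, fs=epochs.fs,
                         epoch_length_s=epochs.epoch_length_s,
                         channel_names=epochs.channel_names), thr)
        assert spiked.n_epochs == epochs.n_epochs - 1
        assert np.array_equal(spiked.epochs, np.delete(data, 4, axis=0))

    def test_count_matches_bruteforce(self, epochs, rng):
        data = epochs.epochs + rng.normal(0, 30, size=epochs.epochs.shape)
        ep = type(epochs)(epochs=data, fs=epochs.fs,
                          epoch_length_s=epochs.epoch_length_s,
                          channel_names=epochs.channel_names)
        thr = 80.0
        out = reject_artifact_epochs(ep, thr)
        expected = sum(1 for e in range(data.shape[0])
                       if np.abs(data[e]).max() <= thr)
        assert out.n_epochs == expected

    def test_all_rejected_warns(self, epochs):
        with pytest.warns(EmptyResultWarning):
            out = reject_artifact_epochs(epochs, 1e-9)
        assert out.n_epochs == 0
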