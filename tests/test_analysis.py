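"""Spectral analysis pipeline: preprocessing, epoching, PSD, band power,
cluster permutation test."""

import numpy as np
import pytest
from scipy import signal

from dreamstream import analysis
from dreamstream.analysis import (AnalysisError, EpochSet, band_power,
                                  cluster_permutation_test, epoch, preprocess,
                                  psd, reject_bad_epochs)
from dreamstream.montage import CHANNEL_LABELS, default_montage
from dreamstream.recording import EYES_CLOSED, EYES_OPEN, Recording


def make_recording(data, fs=250.0, events=None):
    labels = CHANNEL_LABELS[: data.shape[0]]
    return Recording(fs, labels, data, events or [(0, EYES_CLOSED)])


class TestPreprocess:
    def test_dc_offset_channel_flattened(self):
        data = np.zeros((24, 2500))
        data[0] = 37.0
        # give the others some signal so channel 0 is not "flat"
        rng = np.random.default_rng(0)
        data[1:] += rng.normal(0, 5, (23, 2500))
        data[0] += rng.normal(0, 5, 2500)
        out = preprocess(make_recording(data))
        assert np.max(np.abs(out.data[0])) < 5 * 5.0
        assert abs(out.data[0].mean()) < 1e-9

    def test_50hz_tone_attenuated_40db(self):
        fs = 250.0
        t = np.arange(5000) / fs
        rng = np.random.default_rng(1)
        data = rng.normal(0, 5, (24, 5000))
        data[0] += 100 * np.sin(2 * np.pi * 50 * t)
        sos = signal.butter(4, [1, 30], btype="bandpass", fs=fs, output="sos")
        out = preprocess(make_recording(data, fs))
        f, p_after = signal.periodogram(out.data[0], fs=fs)
        band = (f > 48) & (f < 52)
        p_in = 100**2 / 2
        p_out = np.trapezoid(p_after[band], f[band])
        assert 10 * np.log10(p_in / p_out) >= 40.0

    def test_noisy_channel_flagged_bad(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 5, (24, 2500))
        data[3] = rng.normal(0, 500, 2500)  # 100x the variance
        out = preprocess(make_recording(data))
        assert CHANNEL_LABELS[3] not in out.labels
        assert out.n_channels == 23

    def test_all_channels_rejected_aborts(self):
        data = np.zeros((24, 2500))  # every channel flat
        with pytest.raises(AnalysisError):
            preprocess(make_recording(data))


class TestEpoching:
    def _session(self, fs=250.0, block_s=120.0, n_blocks=2):
        n = int(fs * block_s) * n_blocks
        events = [(int(k * fs * block_s),
                   EYES_CLOSED if k % 2 == 0 else EYES_OPEN)
                  for k in range(n_blocks)]
        return make_recording(np.zeros((24, n)), fs, events)

    def test_120s_block_gives_8_epochs(self):
        eo, ec = epoch(self._session())
        assert ec.n_epochs == 8 and eo.n_epochs == 8
        assert ec.data.shape[-1] == 3750

    def test_default_session_gives_40_epochs_per_condition(self):
        eo, ec = epoch(self._session(n_blocks=10))
        assert eo.n_epochs == 40 and ec.n_epochs == 40

    def test_short_block_contributes_nothing_with_warning(self):
        fs = 250.0
        rec = make_recording(np.zeros((24, int(fs * 14))), fs,
                             [(0, EYES_OPEN)])
        with pytest.warns(UserWarning, match="shorter"):
            eo, ec = epoch(rec)
        assert eo.n_epochs == 0 and ec.n_epochs == 0

    def test_epochs_do_not_span_condition_boundaries(self):
        # 100 s blocks: 6 epochs of 15 s per block, 10 s remainder dropped
        eo, ec = epoch(self._session(block_s=100.0, n_blocks=4))
        assert eo.n_epochs == 12 and ec.n_epochs == 12


class TestEpochRejection:
    def _epochs(self, n=6, amp=50.0):
        rng = np.random.default_rng(0)
        data = rng.normal(0, amp / 10, (n, 24, 750))
        return EpochSet(EYES_OPEN, data, 250.0, CHANNEL_LABELS, 3.0)

    def test_infinite_threshold_is_identity(self):
        eps = self._epochs()
        kept = reject_bad_epochs(eps, np.inf)
        assert np.array_equal(kept.data, eps.data)

    def test_large_blink_epoch_removed(self):
        eps = self._epochs()
        eps.data[2, 0, 100] += 300.0
        kept = reject_bad_epochs(eps, 150.0)
        assert kept.n_epochs == eps.n_epochs - 1

    def test_all_removed_aborts(self):
        eps = self._epochs()
        eps.data += 1000.0 * np.sin(np.arange(750) / 10)
        with pytest.raises(AnalysisError):
            reject_bad_epochs(eps, 150.0)


class TestPSD:
    def test_pure_tone_peak_bin(self):
        fs, dur = 250.0, 15.0
        t = np.arange(int(fs * dur)) / fs
        data = np.tile(np.sin(2 * np.pi * 10 * t), (24, 1))[None]
        res = psd(EpochSet(EYES_CLOSED, data, fs, CHANNEL_LABELS, dur))
        assert res.freqs[np.argmax(res.power[0, 0])] == pytest.approx(10.0)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 3, (20, 1, 3750))
        res = psd(EpochSet(EYES_CLOSED, data, 250.0, CHANNEL_LABELS[:1], 15.0))
        total = np.trapezoid(res.power, res.freqs, axis=-1).mean()
        var = data.var()
        assert total == pytest.approx(var, rel=0.05)

    def test_zero_signal_zero_power(self):
        data = np.zeros((2, 24, 3750))
        res = psd(EpochSet(EYES_CLOSED, data, 250.0, CHANNEL_LABELS, 15.0))
        assert np.all(res.power == 0)

    def test_matches_independent_multitaper_oracle(self):
        # cross-check the Hanning periodogram against mne's implementation
        mne = pytest.importorskip("mne")
        from mne.time_frequency import psd_array_welch

        rng = np.random.default_rng(8)
        data = rng.normal(0, 2, (3, 4, 1000))
        data -= data.mean(axis=-1, keepdims=True)  # oracle detrends segments
        res = psd(EpochSet(EYES_CLOSED, data, 250.0, CHANNEL_LABELS[:4], 4.0))
        ref, freqs = psd_array_welch(data, 250.0, fmin=0, fmax=125.0,
                                     n_fft=1000, n_per_seg=1000,
                                     window="hann", verbose=False)
        sel = np.isin(res.freqs, freqs)
        assert np.allclose(res.power[..., sel], ref, rtol=1e-6, atol=1e-12)

    def test_dpss_mode_runs_and_smooths(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, (1, 2, 1000))
        eps = EpochSet(EYES_CLOSED, data, 250.0, CHANNEL_LABELS[:2], 4.0)
        hann = psd(eps, taper="hann")
        multi = psd(eps, taper="dpss")
        assert multi.power.shape == hann.power.shape
        assert multi.power.std() < hann.power.std()


class TestBandPower:
    def test_band_sums_bounded_by_total(self):
        rng = np.random.default_rng(6)
        data = rng.normal(0, 2, (4, 3, 3750))
        res = psd(EpochSet(EYES_CLOSED, data, 250.0, CHANNEL_LABELS[:3], 15.0))
        parts = sum(band_power(res, b) for b in analysis.BANDS)
        total = band_power(res, (1.0, 30.0))
        assert np.all(parts <= total + 1e-12)

    def test_zero_psd_zero_power(self):
        res = psd(EpochSet(EYES_CLOSED, np.zeros((1, 2, 3750)), 250.0,
                           CHANNEL_LABELS[:2], 15.0))
        assert np.all(band_power(res, "alpha") == 0)

    def test_empty_band_rejected(self):
        res = psd(EpochSet(EYES_CLOSED, np.zeros((1, 2, 3750)), 250.0,
                           CHANNEL_LABELS[:2], 15.0))
        with pytest.raises(ValueError):
            band_power(res, (10.0, 10.01))


class TestClusterPermutation:
    def _null_data(self, rng, n=20):
        return 10 ** rng.normal(0, 1, (n, 24))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        a, b = self._null_data(rng), self._null_data(rng)
        r1 = cluster_permutation_test(a, b, n_perm=200, seed=42)
        r2 = cluster_permutation_test(a, b, n_perm=200, seed=42)
        assert [(c.channels, c.p_value) for c in r1.clusters] == \
               [(c.channels, c.p_value) for c in r2.clusters]

    def test_detects_injected_occipital_effect(self):
        rng = np.random.default_rng(11)
        a, b = self._null_data(rng, 30), self._null_data(rng, 30)
        montage = default_montage()
        for lab in ("O1", "O2", "OZ", "POZ"):
            a[:, montage.index(lab)] *= 10 ** 1.5
        res = cluster_permutation_test(a, b, n_perm=500, seed=1)
        sig = res.significant(0.01)
        assert sig
        assert set(("O1", "O2", "OZ", "POZ")) <= set(sig[0].channels)
        assert sig[0].sign == 1

    def test_clusters_respect_adjacency(self):
        rng = np.random.default_rng(12)
        a, b = self._null_data(rng, 30), self._null_data(rng, 30)
        montage = default_montage()
        # boost two disconnected sites: they must not share a cluster
        for lab in ("FP1", "O2"):
            a[:, montage.index(lab)] *= 10**2
        res = cluster_permutation_test(a, b, n_perm=200, seed=2)
        for c in res.clusters:
            assert not {"FP1", "O2"} <= set(c.channels)
            idx = [montage.index(l) for l in c.channels]
            if len(idx) > 1:  # connectivity: each member touches the cluster
                sub = montage.adjacency[np.ix_(idx, idx)]
                assert np.all(sub.sum(axis=1) >= 1)

    def test_degenerate_variance_guard(self):
        a = np.full((5, 24), 2.0)
        b = np.full((6, 24), 2.0)
        res = cluster_permutation_test(a, b, n_perm=100, seed=0,
                                       log_transform=False)
        assert np.all(np.isfinite(res.t_values))
        assert res.clusters == []

    def test_requires_two_epochs_per_condition(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(np.ones((1, 24)), np.ones((5, 24)),
                                     n_perm=10, seed=0)
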