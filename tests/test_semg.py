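"""sEMG preprocessing, ECG template subtraction, normalization, bursts."""

import numpy as np
import pytest

from spinecpg import ParameterError, semg, synthetic as syn
from spinecpg._util import rms
from spinecpg.semg import SemgRecording

FS = 2000.0


def tone(freq, duration=5.0, fs=FS):
    t = np.arange(0.0, duration, 1.0 / fs)
    return np.sin(2 * np.pi * freq * t)


class TestPreprocess:
    def test_channel_means_are_zero(self):
        rec = semg.preprocess(syn.simulate_semg(seed=2))
        for x in rec.channels.values():
            assert abs(x.mean()) < 1e-9

    def test_subband_tone_attenuated(self):
        rec = SemgRecording({"left_rec": tone(5.0)}, fs=FS)
        out = semg.preprocess(rec)
        db = 20 * np.log10(rms(out.channels["left_rec"]) / rms(rec.channels["left_rec"]))
        assert db <= -20.0

    def test_passband_tone_preserved(self):
        rec = SemgRecording({"left_rec": tone(50.0)}, fs=FS)
        out = semg.preprocess(rec)
        db = 20 * np.log10(rms(out.channels["left_rec"]) / rms(rec.channels["left_rec"]))
        assert abs(db) <= 1.0

    def test_idempotent_up_to_edge_effects(self):
        # in-band content only: the ECG's low-frequency mass sits in the
        # filter's transition band and is legitimately attenuated twice
        once = semg.preprocess(syn.simulate_semg(seed=5, ecg_amplitude=0.0))
        twice = semg.preprocess(once)
        for name in once.channels:
            r1, r2 = rms(once.channels[name]), rms(twice.channels[name])
            assert abs(r2 - r1) / r1 < 0.01

    def test_inverted_band_rejected(self):
        rec = SemgRecording({"left_rec": tone(50.0)}, fs=FS)
        with pytest.raises(ParameterError):
            semg.preprocess(rec, band=(500.0, 100.0))


class TestRemoveEcg:
    def test_zero_reference_returns_input(self):
        x = np.sin(np.linspace(0, 40, 4000))
        res = semg.remove_ecg(x, np.zeros_like(x), FS)
        assert not res.applied
        np.testing.assert_array_equal(res.signal, x)

    def test_injected_template_energy_removed(self, semg_injection):
        pp, inj, fs = semg_injection
        for side in ("left", "right"):
            contaminated = pp.channels[f"{side}_rec"]
            injected = inj.channels[f"{side}_rec"]
            res = semg.remove_ecg(contaminated, pp.channels[f"{side}_ref"], fs)
            assert res.applied
            residual = res.signal - (contaminated - injected)
            assert np.sum(residual**2) < 0.10 * np.sum(injected**2)

    def test_template_free_signal_not_inflated(self):
        clean = semg.preprocess(syn.simulate_semg(seed=8, ecg_amplitude=0.0))
        ref = semg.preprocess(syn.simulate_semg(seed=9)).channels["left_ref"]
        x = clean.channels["left_rec"]
        res = semg.remove_ecg(x, ref, FS)
        assert res.applied
        assert np.sum(res.signal**2) <= np.sum(x**2) * (1 + 1e-12)

    def test_aperiodic_reference_flagged_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10_000)
        ref = rng.normal(0, 1, 10_000)
        res = semg.remove_ecg(x, ref, FS)
        if not res.applied:
            np.testing.assert_array_equal(res.signal, x)


class TestBendingNormalize:
    def _recording(self, scale_left=1.0, scale_right=1.0, posture="standing", seed=3):
        rec = semg.preprocess(syn.simulate_semg(seed=seed, ecg_amplitude=0.0,
                                                posture=posture))
        chans = {k: v * (scale_left if k.startswith("left") else scale_right)
                 for k, v in rec.channels.items()}
        return SemgRecording(chans, fs=FS, posture=posture)

    def test_self_normalization_gives_unit_rms(self):
        standing = self._recording()
        bl = self._recording(posture="bend_left")
        br = self._recording(posture="bend_right")
        bl.channels = dict(standing.channels)
        br.channels = dict(standing.channels)
        out = semg.bending_normalize(standing, bl, br)
        for x in out.values():
            assert rms(x) == pytest.approx(1.0)

    def test_half_amplitude_standing_gives_half_rms(self):
        standing = self._recording()
        bl = self._recording(posture="bend_left")
        br = self._recording(posture="bend_right")
        halved = SemgRecording({k: 0.5 * v for k, v in standing.channels.items()},
                               fs=FS)
        bl.channels = dict(standing.channels)
        br.channels = dict(standing.channels)
        out = semg.bending_normalize(halved, bl, br)
        for x in out.values():
            assert rms(x) == pytest.approx(0.5)

    def test_common_gain_invariance(self):
        standing = self._recording(seed=4)
        bl = self._recording(posture="bend_left", seed=5)
        br = self._recording(posture="bend_right", seed=6)
        base = semg.bending_normalize(standing, bl, br)
        g = 37.5
        scaled = semg.bending_normalize(
            SemgRecording({k: g * v for k, v in standing.channels.items()}, fs=FS),
            SemgRecording({k: g * v for k, v in bl.channels.items()}, fs=FS,
                          posture="bend_left"),
            SemgRecording({k: g * v for k, v in br.channels.items()}, fs=FS,
                          posture="bend_right"))
        for k in base:
            np.testing.assert_allclose(scaled[k], base[k], rtol=1e-9)

    def test_zero_bending_rms_rejected(self):
        standing = self._recording()
        silent = SemgRecording({k: np.zeros_like(v)
                                for k, v in standing.channels.items()},
                               fs=FS, posture="bend_left")
        with pytest.raises(ParameterError):
            semg.bending_normalize(standing, silent, self._recording(posture="bend_right"))


class TestBurstMetrics:
    def test_stationary_noise_rarely_bursts(self):
        rec = semg.preprocess(syn.simulate_semg(seed=11, ecg_amplitude=0.0,
                                                duration_s=20.0))
        bm = semg.burst_metrics(rec.channels["left_rec"], FS)
        assert bm.burst_fraction < 0.01

    def test_injected_bursts_detected_at_expected_fraction(self):
        bursts = [syn.BurstSpec("left", s, 0.25, gain=5.0)
                  for s in np.arange(0.25, 20.0, 2.5)]
        rec = semg.preprocess(syn.simulate_semg(seed=12, ecg_amplitude=0.0,
                                                duration_s=20.0, burst_spec=bursts))
        bm = semg.burst_metrics(rec.channels["left_rec"], FS)
        assert bm.burst_fraction == pytest.approx(0.10, abs=0.03)

    def test_silent_signal_has_zero_bursts(self):
        bm = semg.burst_metrics(np.zeros(10_000), FS)
        assert bm.burst_count == 0

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ParameterError):
            semg.burst_metrics(np.zeros(100), FS, window_s=1.0)

    def test_recording_level_metrics(self):
        bursts = [syn.BurstSpec("left", 1.0, 0.5, gain=6.0)]
        rec = semg.preprocess(syn.simulate_semg(seed=13, ecg_amplitude=0.0,
                                                burst_spec=bursts))
        m = semg.semg_metrics(rec)
        assert m.lr_rms_ratio > 1.0
        assert m.bursts_left.burst_count >= m.bursts_right.burst_count
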