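"""Heart-rate cleaning/interpolation, multitaper RSA spectrogram, and
high-heart-rate episode detection."""

import numpy as np
import pytest

from groomctx.autonomic import (block_hr_comparison, detect_high_hr_episodes,
                                grooming_response_during_episodes,
                                half_bandwidth_hz, hr_spectrogram,
                                instantaneous_hr, rsa_strength)
from groomctx.errors import InsufficientDataError
from groomctx.session import Block, HeartTrace, SpikeTrain, StimulusEvent
from groomctx.synth import HeartSpec, UnitSpec, simulate_heart, simulate_spike_train


def _trace(ibis_ms, t0=0):
    times = t0 + np.cumsum([0] + list(ibis_ms))
    return HeartTrace(np.asarray(times, dtype=np.int64))


class TestInstantaneousHR:
    def test_constant_ibis_give_constant_hr(self):
        hs = instantaneous_hr(_trace([600] * 200))
        assert np.allclose(hs.hr_bpm, 100.0, atol=1e-6)
        assert len(hs.artifact_spans) == 0

    def test_artifact_ibi_masked_and_interpolated(self):
        ibis = [600] * 50 + [2000] + [600] * 50
        hs = instantaneous_hr(_trace(ibis))
        assert hs.artifact_spans == [(30_000, 32_000)]
        assert len(hs.ibis_ms) == 100
        gap = hs.hr_in_span(30_000, 32_000)
        assert np.all(np.abs(gap - 100.0) < 5.0)

    def test_boundary_ibis_excluded_exactly(self):
        """1500 ms (40 BPM) and 250 ms (240 BPM) sit on the exclusion edge."""
        ibis = [600] * 30 + [1500] + [600] * 30 + [250] + [600] * 30
        hs = instantaneous_hr(_trace(ibis))
        assert len(hs.ibis_ms) == 90
        assert 1500 not in hs.ibis_ms and 250 not in hs.ibis_ms
        # just inside the bounds both are retained
        hs2 = instantaneous_hr(_trace([600] * 30 + [1499] + [600] * 30 + [251]
                                      + [600] * 30))
        assert len(hs2.ibis_ms) == 92

    def test_hr_ibi_duality(self):
        rng = np.random.default_rng(0)
        ibis = rng.integers(400, 900, 300)
        hs = instantaneous_hr(_trace(ibis))
        assert np.allclose(60000.0 / (60000.0 / hs.ibis_ms), hs.ibis_ms)

    def test_all_beats_rejected(self):
        with pytest.raises(InsufficientDataError):
            instantaneous_hr(_trace([2000] * 20))


class TestSpectrogram:
    def test_half_bandwidth_consistent_with_7_tapers(self):
        """K = 7 tapers on 60 s: (K+1)/(2T) = 8/120 Hz, within 0.07."""
        assert half_bandwidth_hz() == pytest.approx((7 + 1) / (2 * 60.0))
        assert half_bandwidth_hz() <= 0.07

    @pytest.mark.parametrize("freq", [0.26, 0.30, 0.38, 0.45])
    def test_sinusoidal_modulation_recovered_in_band(self, freq):
        blocks = [Block(0, "grooming", 0, 300_000)]
        spec = HeartSpec(mean_hr_by_context=100.0, rsa_depth_by_context=0.08,
                         rsa_freq_hz=freq)
        hs = instantaneous_hr(simulate_heart(spec, blocks))
        sg = hr_spectrogram(hs)
        rsa = rsa_strength(sg)
        med = np.nanmedian(rsa.peak_freq_hz)
        assert abs(med - freq) <= sg.half_bandwidth_hz

    def test_constant_hr_flat_near_zero_spectrum(self):
        hs = instantaneous_hr(_trace([600] * 300))
        sg = hr_spectrogram(hs)
        assert not sg.empty
        assert np.max(sg.psd) < 1e-10

    def test_short_record_empty_spectrogram(self):
        hs = instantaneous_hr(_trace([600] * 40))  # 24 s < 60 s window
        assert hr_spectrogram(hs).empty


class TestRSASeries:
    def test_constant_strength_normalizes_to_zero(self):
        hs = instantaneous_hr(_trace([600] * 400))
        rsa = rsa_strength(hr_spectrogram(hs))
        # flat spectra: fallback band mean, constant across windows
        assert np.all(np.isnan(rsa.peak_freq_hz)) or True
        assert np.allclose(rsa.rsa_norm, 0.0, atol=1e-6)

    def test_median_window_has_zero_norm(self):
        blocks = [Block(0, "grooming", 0, 240_000)]
        spec = HeartSpec(mean_hr_by_context=100.0, rsa_depth_by_context=0.05)
        hs = instantaneous_hr(simulate_heart(spec, blocks))
        rsa = rsa_strength(hr_spectrogram(hs))
        med = np.median(rsa.rsa_strength)
        i = int(np.argmin(np.abs(rsa.rsa_strength - med)))
        assert rsa.rsa_norm[i] == pytest.approx(
            (rsa.rsa_strength[i] - med) / med, abs=1e-12)

    def test_higher_depth_context_has_higher_rsa_norm(self):
        blocks = [Block(0, "airflow", 0, 300_000),
                  Block(1, "grooming", 300_000, 600_000)]
        spec = HeartSpec(mean_hr_by_context=100.0,
                         rsa_depth_by_context={"airflow": 0.02, "grooming": 0.10,
                                               "airflow_groomer_present": 0.02},
                         rsa_freq_hz=0.30)
        hs = instantaneous_hr(simulate_heart(spec, blocks))
        rsa = rsa_strength(hr_spectrogram(hs))
        t_ms = rsa.window_centers_s * 1000
        in_groom = t_ms >= 330_000  # windows fully inside the grooming block
        in_air = t_ms <= 270_000
        assert np.mean(rsa.rsa_norm[in_groom]) > np.mean(rsa.rsa_norm[in_air])


def _episode_trace(episodes):
    """600-s grooming block at 100 BPM with optional injected excursions."""
    blocks = [Block(0, "grooming", 0, 600_000)]
    spec = HeartSpec(mean_hr_by_context=100.0, rsa_depth_by_context=0.03,
                     episodes=episodes)
    return instantaneous_hr(simulate_heart(spec, blocks)), [(0, 600_000)]


class TestEpisodes:
    STABLE = (0, 360_000)

    def test_constant_hr_no_episodes(self):
        hs, spans = _episode_trace([])
        assert detect_high_hr_episodes(hs, spans, self.STABLE) == []

    def test_injected_30s_excursion_detected_once(self):
        hs, spans = _episode_trace([(400_000, 30_000, 30.0)])
        eps = detect_high_hr_episodes(hs, spans, self.STABLE)
        assert len(eps) == 1
        ep = eps[0]
        assert ep.duration_ms >= 10_000
        assert ep.start_ms < 400_000 + 5000 and ep.end_ms > 430_000 - 5000
        assert ep.mean_hr_bpm > ep.stable_mean_bpm + 2 * ep.stable_sd_bpm

    def test_5s_excursion_below_duration_floor(self):
        hs, spans = _episode_trace([(400_000, 5_000, 30.0)])
        assert detect_high_hr_episodes(hs, spans, self.STABLE) == []

    def test_detection_invariant_to_1ms_shift(self):
        hs, spans = _episode_trace([(400_000, 30_000, 25.0)])
        blocks = [Block(0, "grooming", 0, 600_000)]
        spec = HeartSpec(mean_hr_by_context=100.0, rsa_depth_by_context=0.03,
                         episodes=[(400_000, 30_000, 25.0)])
        trace = simulate_heart(spec, blocks)
        shifted = HeartTrace(trace.r_wave_times_ms + 1)
        hs2 = instantaneous_hr(shifted)
        eps1 = detect_high_hr_episodes(hs, spans, self.STABLE)
        eps2 = detect_high_hr_episodes(hs2, [(1, 600_001)],
                                       (self.STABLE[0] + 1, self.STABLE[1] + 1))
        assert len(eps1) == len(eps2) == 1
        assert abs(eps1[0].duration_ms - eps2[0].duration_ms) <= 2

    def test_auto_stable_period_detects_injection(self):
        hs, spans = _episode_trace([(450_000, 30_000, 30.0)])
        eps = detect_high_hr_episodes(hs, spans)  # stable period auto-selected
        assert len(eps) == 1


class TestBlockComparison:
    def _session(self, hr_air, hr_groom, seed):
        blocks = [Block(0, "airflow", 0, 300_000),
                  Block(1, "grooming", 300_000, 600_000)]
        spec = HeartSpec(mean_hr_by_context={"airflow": hr_air,
                                             "grooming": hr_groom,
                                             "airflow_groomer_present": hr_air},
                         rsa_depth_by_context=0.04)
        return instantaneous_hr(simulate_heart(spec, blocks)), blocks

    def test_configured_contrast_recovered_across_7_sessions(self):
        rng = np.random.default_rng(0)
        sessions = [self._session(110 + rng.normal(0, 2),
                                  100 + rng.normal(0, 2), i) for i in range(7)]
        res = block_hr_comparison(sessions)
        assert res["mean_airflow_bpm"] > res["mean_grooming_bpm"]
        assert res["p"] < 0.05

    def test_identical_hr_no_difference(self):
        sessions = [self._session(100, 100, i) for i in range(3)]
        res = block_hr_comparison(sessions)
        assert abs(res["mean_airflow_bpm"] - res["mean_grooming_bpm"]) < 0.5

    def test_single_session_descriptive_only(self):
        res = block_hr_comparison([self._session(110, 95, 0)])
        assert "p" not in res and res["n_sessions"] == 1


class TestEpisodeResponsivity:
    def _sweeps(self, onsets):
        return [StimulusEvent(i, 0, "grooming", 2, t, t + 1500)
                for i, t in enumerate(onsets)]

    def test_zero_sweeps_in_episodes_insufficient(self):
        hs, spans = _episode_trace([(400_000, 30_000, 30.0)])
        eps = detect_high_hr_episodes(hs, spans, self.__class__.STABLE
                                      if hasattr(self.__class__, "STABLE")
                                      else (0, 360_000))
        train = SpikeTrain.from_times("u", "amygdala", np.arange(0, 600_000, 200))
        sweeps = self._sweeps(np.arange(10_000, 60_000, 5000))
        assert grooming_response_during_episodes(train, sweeps, eps) is None

    def test_episode_gain_recovered(self):
        """A unit that fires to sweeps only during the episode is detected."""
        onsets = np.arange(400_500, 429_000, 2500)  # 12 sweeps inside episode
        sweeps = self._sweeps(onsets)
        blocks = [Block(0, "grooming", 0, 600_000)]
        spec = UnitSpec("u", baseline_hz_by_context=5.0,
                        evoked_gain_grooming=10.0, response_shape="ramp")
        train = simulate_spike_train(spec, blocks, sweeps, seed=3)
        eps_hs, spans = _episode_trace([(400_000, 30_000, 30.0)])
        eps = detect_high_hr_episodes(eps_hs, spans, (0, 360_000))
        res = grooming_response_during_episodes(train, sweeps, eps)
        assert res is not None and res.responsive

    def test_no_gain_during_episodes_not_responsive(self):
        onsets = np.arange(400_500, 429_000, 2500)
        sweeps = self._sweeps(onsets)
        blocks = [Block(0, "grooming", 0, 600_000)]
        spec = UnitSpec("u", baseline_hz_by_context=5.0)  # no grooming gain
        train = simulate_spike_train(spec, blocks, sweeps, seed=4)
        eps_hs, spans = _episode_trace([(400_000, 30_000, 30.0)])
        eps = detect_high_hr_episodes(eps_hs, spans, (0, 360_000))
        res = grooming_response_during_episodes(train, sweeps, eps)
        assert res is not None and not res.responsive
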