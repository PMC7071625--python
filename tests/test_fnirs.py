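"""Hemodynamics: HRF shape, Beer-Lambert conversion, filtering, ICA
denoising and the 96-feature extraction."""

import numpy as np
import pandas as pd
import pytest

from affectfuse.config import ConfigurationError, HRFParams, MBLLParams, StudyConfig
from affectfuse.fnirs import (
    FNIRS_FEATURE_NAMES,
    baseline_adjust,
    expected_response,
    extract_fnirs_features,
    hrf,
    ica_select_hemodynamic,
    lowpass_fnirs,
    mbll_convert,
)
from affectfuse.signals import DataError, HemodynamicSignals, RawFNIRSRecord
from affectfuse.synthetic import build_protocol, plant_fnirs_response, planted_concentrations


def _record_from_conc(hbo, hbr, params=None, rate=4.0):
    """Forward-map concentration series through the MBLL so mbll_convert
    should invert it exactly (reference window = first 30 s, all-zero)."""
    params = params or MBLLParams()
    n = hbo.shape[0]
    conc = np.stack([hbo, hbr], axis=-1)
    dod = np.einsum("wc,noc->now", params.matrix(), conc)
    intensity = 1000.0 * 10.0 ** (-dod)
    return RawFNIRSRecord(
        time=np.arange(n) / rate,
        intensity=intensity + 50.0,
        ambient=np.full((n, 4), 50.0),
        rate=rate,
    )


class TestHRF:
    def test_zero_at_origin(self):
        assert hrf(np.array([0.0]))[0] == 0.0

    def test_peak_near_five_seconds(self):
        # numeric maximization oracle on a 0.01 s grid
        t = np.arange(0.0, 32.0, 0.01)
        h = hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.02)

    def test_pure_response_is_nonnegative_without_undershoot(self):
        t = np.linspace(0, 40, 2000)
        h = hrf(t, HRFParams(undershoot_ratio=0.0))
        assert np.all(h >= 0)

    def test_single_undershoot_sign_change_after_peak(self):
        t = np.arange(0.0, 40.0, 0.01)
        h = hrf(t)
        after_peak = h[np.argmax(h):]
        changes = np.sum(np.diff(np.sign(after_peak[after_peak != 0])) != 0)
        assert changes == 1

    def test_invalid_shape_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            HRFParams(alpha1=0.5)
        with pytest.raises(ConfigurationError):
            HRFParams(beta2=0.0)


class TestExpectedResponse:
    def test_empty_protocol_gives_zero_regressor(self):
        empty = pd.DataFrame(columns=["trial_id", "onset_s", "duration_s"])
        assert np.all(expected_response(empty, 100) == 0)

    def test_impulse_reproduces_sampled_hrf(self):
        proto = pd.DataFrame(
            [{"trial_id": 1, "onset_s": 0.0, "duration_s": 0.25}])
        reg = expected_response(proto, 128, rate=4.0)
        kernel = hrf(np.arange(0, 32, 0.25))
        np.testing.assert_allclose(reg, kernel[:128], atol=1e-12)

    def test_boxcar_matches_double_loop_oracle(self):
        rate, n = 4.0, 200
        proto = pd.DataFrame(
            [{"trial_id": 1, "onset_s": 10.0, "duration_s": 5.0}])
        reg = expected_response(proto, n, rate=rate)
        box = np.zeros(n)
        box[int(10 * rate):int(15 * rate)] = 1.0
        kernel = hrf(np.arange(0, 32, 1 / rate))
        oracle = np.zeros(n)
        for i in range(n):                      # brute-force convolution
            for j, kv in enumerate(kernel):
                if 0 <= i - j < n:
                    oracle[i] += box[i - j] * kv
        np.testing.assert_allclose(reg, oracle, atol=1e-9)

    def test_trial_past_recording_end_rejected(self):
        proto = pd.DataFrame(
            [{"trial_id": 1, "onset_s": 90.0, "duration_s": 20.0}])
        with pytest.raises(Exception, match="recording"):
            expected_response(proto, 100, rate=4.0)


class TestMBLL:
    def test_constant_intensity_gives_zero_concentration(self):
        n = 200
        rec = RawFNIRSRecord(
            time=np.arange(n) / 4.0,
            intensity=np.full((n, 4, 2), 900.0),
            ambient=np.zeros((n, 4)),
        )
        sig = mbll_convert(rec)
        assert np.allclose(sig.hbo, 0) and np.allclose(sig.hbr, 0)

    def test_planted_concentrations_recovered_exactly(self):
        # algebraic round trip: (dHbO, dHbR) = (1.0, -0.25) uM plateau
        n = 400
        hbo = np.zeros((n, 4))
        hbr = np.zeros((n, 4))
        hbo[150:, :] = 1.0
        hbr[150:, :] = -0.25
        sig = mbll_convert(_record_from_conc(hbo, hbr))
        np.testing.assert_allclose(sig.hbo, hbo, atol=1e-9)
        np.testing.assert_allclose(sig.hbr, hbr, atol=1e-9)

    def test_identities_hold_exactly(self):
        n = 300
        hbo = np.random.default_rng(0).normal(size=(n, 4)) * 0.5
        hbr = np.random.default_rng(1).normal(size=(n, 4)) * 0.2
        hbo[:120] = 0  # keep the 30-s reference window clean
        hbr[:120] = 0
        sig = mbll_convert(_record_from_conc(hbo, hbr))
        np.testing.assert_array_equal(sig.hbt, sig.hbo + sig.hbr)
        np.testing.assert_array_equal(sig.oxy, sig.hbo - sig.hbr)

    def test_nonpositive_intensity_names_sample(self):
        n = 130
        rec = RawFNIRSRecord(
            time=np.arange(n) / 4.0,
            intensity=np.full((n, 4, 2), 900.0),
            ambient=np.zeros((n, 4)),
        )
        rec.intensity[57, 2, 1] = -1.0
        with pytest.raises(DataError, match="57"):
            mbll_convert(rec)

    def test_singular_extinction_matrix_rejected(self):
        params = MBLLParams(extinction={730: (1.0, 1.0), 850: (2.0, 2.0)})
        with pytest.raises(ConfigurationError, match="singular"):
            params.matrix()


class TestLowpass:
    def test_constant_signal_unchanged(self):
        n = 400
        sig = HemodynamicSignals(
            time=np.arange(n) / 4.0,
            hbo=np.full((n, 4), 3.7), hbr=np.full((n, 4), -1.2))
        out = lowpass_fnirs(sig)
        np.testing.assert_allclose(out.hbo, 3.7, atol=1e-9)
        np.testing.assert_allclose(out.hbr, -1.2, atol=1e-9)

    def test_one_hz_attenuated_20db(self):
        n = 4000
        t = np.arange(n) / 4.0
        wave = np.sin(2 * np.pi * 1.0 * t)
        sig = HemodynamicSignals(
            time=t, hbo=np.tile(wave[:, None], (1, 4)), hbr=np.zeros((n, 4)))
        out = lowpass_fnirs(sig, cutoff=0.1)
        # >= 20 dB attenuation = amplitude ratio <= 0.1
        assert np.abs(out.hbo[500:-500]).max() <= 0.1

    def test_cutoff_at_nyquist_rejected(self):
        sig = HemodynamicSignals(
            time=np.arange(100) / 4.0, hbo=np.zeros((100, 4)), hbr=np.zeros((100, 4)))
        with pytest.raises(ConfigurationError):
            lowpass_fnirs(sig, cutoff=2.0)


class TestICASelect:
    def _signals(self, data, rate=4.0):
        n = data.shape[0]
        return HemodynamicSignals(
            time=np.arange(n) / rate, hbo=data, hbr=np.zeros_like(data))

    def test_planted_component_recovered(self, rng):
        n = 1200
        reg = expected_response(
            pd.DataFrame([{"trial_id": i, "onset_s": 40 * i + 20.0, "duration_s": 10.0}
                          for i in range(1, 7)]), n, rate=4.0)
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            data = r.normal(size=(n, 4))
            data[:, 2] += 3.0 * reg
            out = ica_select_hemodynamic(self._signals(data), reg, seed=seed)
            if np.corrcoef(out.hbo[:, 2], reg)[0, 1] > 0.95:
                hits += 1
        assert hits >= 4

    def test_null_regressor_rarely_significant(self):
        # With 4 white-noise components and the max-|t| selection rule the
        # chance that some component clears p<0.05 is ~1-(0.95)^4 = 0.185;
        # 20 seeds give P(X > 8 | p=0.185) < 0.01.
        from affectfuse.fnirs import _regression_tstat
        from sklearn.decomposition import FastICA
        n = 800
        sig_count = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            data = r.normal(size=(n, 4))
            reg = r.normal(size=n)
            ica = FastICA(n_components=4, random_state=seed, whiten="unit-variance")
            sources = ica.fit_transform(data)
            stats_ = [_regression_tstat(sources[:, k], reg) for k in range(4)]
            best = max(stats_, key=lambda tp: abs(tp[0]))
            if best[1] < 0.05:
                sig_count += 1
        assert sig_count <= 8

    def test_single_channel_passes_through(self, caplog):
        n = 200
        data = np.random.default_rng(0).normal(size=(n, 1))
        sig = self._signals(data)
        with caplog.at_level("WARNING"):
            out = ica_select_hemodynamic(sig, np.zeros(n))
        np.testing.assert_array_equal(out.hbo, data)
        assert "ICA skipped" in caplog.text


class TestBaselineAdjust:
    def _proto(self, onset, dur=5.0):
        return pd.DataFrame([{
            "trial_id": 1, "participant_id": 1, "kind": "image",
            "onset_s": onset, "duration_s": dur, "valence": "positive",
            "likert": 9}])

    def test_constant_signal_gives_zero_trial(self):
        n = 200
        sig = HemodynamicSignals(
            time=np.arange(n) / 4.0,
            hbo=np.full((n, 4), 2.0), hbr=np.full((n, 4), 1.0))
        trials = baseline_adjust(sig, self._proto(onset=20.0))
        assert np.allclose(trials[1].hbo, 0) and np.allclose(trials[1].hbr, 0)

    def test_subtracts_exact_baseline_mean(self):
        n = 200
        hbo = np.arange(n, dtype=float)[:, None] * np.ones((1, 4))
        sig = HemodynamicSignals(time=np.arange(n) / 4.0, hbo=hbo, hbr=-hbo)
        trials = baseline_adjust(sig, self._proto(onset=20.0), baseline=5.0)
        # 4 Hz x 5 s = 20 samples before onset index 80: mean of 60..79 = 69.5
        np.testing.assert_allclose(trials[1].hbo[0], 80.0 - 69.5)

    def test_missing_baseline_excludes_trial(self, caplog):
        n = 100
        sig = HemodynamicSignals(
            time=np.arange(n) / 4.0, hbo=np.zeros((n, 4)), hbr=np.zeros((n, 4)))
        with caplog.at_level("WARNING"):
            trials = baseline_adjust(sig, self._proto(onset=2.0))
        assert trials == {}
        assert "excluded" in caplog.text


class TestFeatures:
    def test_exactly_96_named_features(self):
        n = 40
        trial = HemodynamicSignals(
            time=np.arange(n) / 4.0,
            hbo=np.random.default_rng(0).normal(size=(n, 4)),
            hbr=np.random.default_rng(1).normal(size=(n, 4)))
        feats = extract_fnirs_features(trial)
        assert len(feats) == 96
        assert list(feats.index) == list(FNIRS_FEATURE_NAMES)

    def test_constant_trial_statistics(self):
        n = 20
        trial = HemodynamicSignals(
            time=np.arange(n) / 4.0,
            hbo=np.full((n, 4), 3.0), hbr=np.full((n, 4), 1.0))
        feats = extract_fnirs_features(trial)
        assert feats["o1_hbo_mean"] == 3.0
        assert feats["o1_hbo_std"] == 0.0
        assert feats["o1_hbo_range"] == 0.0
        # identities: hbt = 4, oxy = 2 everywhere
        assert feats["o3_hbt_median"] == 4.0
        assert feats["o3_oxy_max"] == 2.0

    def test_hand_computed_example(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        trial = HemodynamicSignals(
            time=np.arange(4) / 4.0,
            hbo=np.tile(vals[:, None], (1, 4)), hbr=np.zeros((4, 4)))
        feats = extract_fnirs_features(trial)
        assert feats["o2_hbo_mean"] == pytest.approx(2.5)
        assert feats["o2_hbo_median"] == pytest.approx(2.5)
        assert feats["o2_hbo_max"] == 4.0
        assert feats["o2_hbo_min"] == 1.0
        assert feats["o2_hbo_range"] == 3.0
        assert feats["o2_hbo_std"] == pytest.approx(np.std(vals, ddof=1))

    def test_ordering_invariants(self):
        n = 30
        trial = HemodynamicSignals(
            time=np.arange(n) / 4.0,
            hbo=np.random.default_rng(5).normal(size=(n, 4)),
            hbr=np.random.default_rng(6).normal(size=(n, 4)))
        feats = extract_fnirs_features(trial)
        for opt in range(1, 5):
            for sig in ("hbo", "hbr", "hbt", "oxy"):
                assert feats[f"o{opt}_{sig}_min"] <= feats[f"o{opt}_{sig}_median"] \
                    <= feats[f"o{opt}_{sig}_max"]
                assert feats[f"o{opt}_{sig}_range"] >= 0


class TestGeneratorRoundTrip:
    def test_zero_effect_zero_noise_gives_zero_concentrations(self):
        cfg = StudyConfig(n_participants=1, n_image_trials=4, n_video_trials=4,
                          effect_fnirs=0.0, noise_fnirs=0.0, drift_fnirs=0.0,
                          seed=7)
        proto = build_protocol(cfg, 1)
        sig = mbll_convert(plant_fnirs_response(proto, cfg))
        np.testing.assert_allclose(sig.hbo, 0.0, atol=1e-9)
        np.testing.assert_allclose(sig.hbr, 0.0, atol=1e-9)

    def test_noise_free_round_trip_within_1e9(self):
        cfg = StudyConfig(n_participants=1, n_image_trials=4, n_video_trials=4,
                          effect_fnirs=1.0, noise_fnirs=0.0, drift_fnirs=0.0,
                          seed=7)
        proto = build_protocol(cfg, 1)
        sig = mbll_convert(plant_fnirs_response(proto, cfg))
        hbo, hbr = planted_concentrations(proto, cfg)
        np.testing.assert_allclose(sig.hbo, hbo, atol=1e-9)
        np.testing.assert_allclose(sig.hbr, hbr, atol=1e-9)

    def test_both_wavelengths_emitted(self, small_study):
        rec = small_study.participants[0].fnirs
        assert rec.wavelengths == (730, 850)
        assert rec.intensity.shape[1:] == (4, 2)
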