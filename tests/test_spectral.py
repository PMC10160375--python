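"""Spectral estimation: DFT against a direct-sum oracle, the periodogram
normalization, band powers, ratio metrics, notch filtering, artifact
flagging and sliding-window feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegsa import spectral, synth
from eegsa.recording import RawRecording
from eegsa.spectral import (
    DEFAULT_BANDS,
    METRICS,
    SpectralEstimate,
    band_powers,
    dft,
    extract_features,
    feature_name,
    flag_artifacts,
    parse_feature_name,
    psd,
    ratio_metrics,
    remove_line_noise,
)


def dft_direct(x):
    """O(N²) direct evaluation of the DFT sum (independent oracle)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    w = np.arange(n)
    return np.array([np.sum(x * np.exp(-2j * np.pi * wi * np.arange(n) / n)) for wi in w])


class TestDFT:
    def test_constant_series_concentrates_at_dc(self):
        X = dft(np.full(8, 3.0))
        assert X[0] == pytest.approx(24.0)
        assert np.allclose(X[1:], 0.0, atol=1e-12)

    def test_single_cycle_cosine(self):
        t = np.arange(8)
        X = dft(np.cos(2 * np.pi * t / 8))
        assert X[1] == pytest.approx(4.0, abs=1e-12)
        assert X[7] == pytest.approx(4.0, abs=1e-12)
        others = np.delete(X, [1, 7])
        assert np.allclose(others, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 16, 100, 1024])
    def test_matches_direct_sum_oracle(self, n, rng):
        x = rng.normal(size=n)
        X = dft(x)
        Xo = dft_direct(x)
        assert np.max(np.abs(X - Xo)) / np.max(np.abs(Xo)) < 1e-9

    def test_linearity(self, rng):
        a, b = rng.normal(size=32), rng.normal(size=32)
        assert np.allclose(dft(a + b), dft(a) + dft(b))

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            dft(np.array([1.0]))


class TestPSD:
    def test_cosine_bin_value(self):
        # cos(2πt/8), N=8, fs=256: |X(1)|² = 16, S(1) = 16 / (8·256)
        t = np.arange(8)
        est = psd(np.cos(2 * np.pi * t / 8), fs=256.0)
        assert est.psd[1] == pytest.approx(0.0078125)

    def test_zero_signal(self):
        est = psd(np.zeros(16), fs=256.0)
        assert np.all(est.psd == 0.0)

    def test_quadratic_scaling(self, rng):
        x = rng.normal(size=64)
        assert np.allclose(psd(2 * x, 256.0).psd, 4 * psd(x, 256.0).psd)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=2, max_value=200), st.integers(0, 2**31 - 1))
    def test_parseval_identity(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        est = psd(x, fs=128.0)
        dt = 1 / 128.0
        assert np.sum(est.psd) == pytest.approx(dt * np.sum(x**2), rel=1e-9)


class TestBandPowers:
    def _tone_est(self, f, fs=256.0, dur=5.0):
        t = np.arange(int(fs * dur)) / fs
        return psd(np.sin(2 * np.pi * f * t), fs)

    def test_pure_alpha_tone_lands_in_alpha(self):
        bp = band_powers(self._tone_est(10.0))
        total = sum(bp.values())
        assert bp["alpha"] / total >= 0.99

    @pytest.mark.parametrize("freq,band", [(6.0, "theta"), (3.0, "delta")])
    def test_band_edges_route_tones(self, freq, band):
        bp = band_powers(self._tone_est(freq))
        assert bp[band] == max(bp.values())

    def test_zero_signal_zero_powers(self):
        est = psd(np.zeros(256), fs=256.0)
        assert all(v == 0.0 for v in band_powers(est).values())

    def test_band_above_nyquist_rejected(self):
        est = psd(np.zeros(256), fs=64.0)
        with pytest.raises(ValueError):
            band_powers(est, (spectral.BandDefinition("hf", 40.0, 50.0),))

    def test_bands_contiguous(self):
        for a, b in zip(DEFAULT_BANDS, DEFAULT_BANDS[1:]):
            assert a.hi == b.lo


class TestRatioMetrics:
    def test_symmetric_powers(self):
        r = ratio_metrics({"theta": 2.0, "alpha": 2.0, "beta": 2.0})
        assert r["theta/beta"] == 1.0
        assert r["alpha/beta"] == 1.0
        assert r["theta/(alpha+theta)"] == 0.5
        assert r["(alpha+theta)/beta"] == 2.0
        assert r["(alpha+theta)/(alpha+beta)"] == 1.0

    def test_hand_arithmetic(self):
        r = ratio_metrics({"theta": 0.2, "alpha": 0.4, "beta": 0.5})
        expected = (0.4, 0.8, 1 / 3, 1.2, 2 / 3)
        assert tuple(r[m] for m in METRICS) == pytest.approx(expected)

    def test_zero_beta_is_an_error(self):
        with pytest.raises(ValueError, match="beta"):
            ratio_metrics({"theta": 1.0, "alpha": 1.0, "beta": 0.0})

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(1e-6, 1e6), st.floats(1e-6, 1e6), st.floats(1e-6, 1e6)
    )
    def test_theta_fraction_bounded(self, th, al, be):
        r = ratio_metrics({"theta": th, "alpha": al, "beta": be})
        assert 0.0 <= r["theta/(alpha+theta)"] <= 1.0
        assert all(v >= 0 for v in r.values())


class TestLineNoiseRemoval:
    def _rec(self, sig, fs=256.0):
        return RawRecording("s", [("F1", "F")], fs, sig[None, :])

    def test_mains_tone_suppressed(self):
        # 30 s so the filter's edge transient is negligible next to the tone
        t = np.arange(256 * 30) / 256.0
        rec = self._rec(10.0 * np.sin(2 * np.pi * 50.0 * t))
        out = remove_line_noise(rec)
        before = psd(rec.data[0], 256.0)
        after = psd(out.data[0], 256.0)
        i50 = int(round(50.0 * len(t) / 256.0))
        assert after.psd[i50] <= 1e-4 * before.psd[i50]  # amplitude <= 1%

    def test_passband_untouched(self):
        t = np.arange(256 * 4) / 256.0
        rec = self._rec(np.sin(2 * np.pi * 10.0 * t))
        out = remove_line_noise(rec)
        b_in = band_powers(psd(rec.data[0], 256.0))["alpha"]
        b_out = band_powers(psd(out.data[0], 256.0))["alpha"]
        assert abs(10 * np.log10(b_out / b_in)) < 1.0  # < 1 dB

    def test_zero_in_zero_out(self):
        out = remove_line_noise(self._rec(np.zeros(1024)))
        assert np.allclose(out.data, 0.0)

    def test_notch_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            remove_line_noise(self._rec(np.zeros(1024), fs=100.0), f0=50.0)


class TestArtifactFlagging:
    def test_single_spike_flags_its_epoch(self):
        data = np.zeros((1, 256 * 15))
        data[0, 256 * 7] = 250.0  # inside epoch [5 s, 10 s)
        rec = RawRecording("s", [("F1", "F")], 256.0, data)
        mask = flag_artifacts(rec)
        assert mask[256 * 5 : 256 * 10].all()
        assert not mask[: 256 * 5].any() and not mask[256 * 10 :].any()

    def test_subthreshold_signal_unflagged(self):
        rec = RawRecording("s", [("F1", "F")], 256.0, np.full((1, 2560), 199.0))
        assert not flag_artifacts(rec).any()

    def test_every_injected_artifact_epoch_flagged(self):
        spec = synth.default_spec(duration=120.0, artifact_rate=3.0, seed=5)
        rec = synth.generate_recording(spec, "low", "s", 5)
        mask = flag_artifacts(rec)
        block = int(5 * rec.sampling_rate)
        for ev in rec.artifacts:
            # the pulse peaks at its center; that sample's epoch must flag
            i = int(round((ev.start_s + ev.duration_s / 2) * rec.sampling_rate))
            i = min(i, rec.n_samples - 1)
            peak_region = mask[(i // block) * block : (i // block + 1) * block]
            assert peak_region.all()


class TestFeatureNames:
    def test_roundtrip(self):
        for m in METRICS:
            for r in ("F", "C"):
                for stat in ("mean", "median"):
                    assert parse_feature_name(feature_name(r, stat, m)) == (r, stat, m)


class TestExtractFeatures:
    def test_trio_over_two_regions_gives_twelve_columns(self, small_cohort):
        df = extract_features(small_cohort[0])
        feats = spectral.feature_columns(df)
        assert len(feats) == 12
        assert feats == [
            "FM1", "FP1", "CM1", "CP1",
            "FM2", "FP2", "CM2", "CP2",
            "FM3", "FP3", "CM3", "CP3",
        ]

    def test_row_count_without_overlap(self):
        spec = synth.default_spec(duration=60.0, artifact_rate=0.0, seed=2)
        rec = synth.generate_recording(spec, "high", "s", 2)
        df = extract_features(rec, overlap=0.0)
        assert len(df) == 12  # floor(60/5)

    def test_half_overlap_doubles_rows_minus_one(self):
        spec = synth.default_spec(duration=60.0, artifact_rate=0.0, seed=2)
        rec = synth.generate_recording(spec, "high", "s", 2)
        assert len(extract_features(rec, overlap=0.5)) == 23

    def test_channel_order_invariance(self, small_cohort):
        rec = small_cohort[0]
        perm = list(range(rec.n_channels))[::-1]
        swapped = RawRecording(
            rec.subject_id,
            [rec.channels[i] for i in perm],
            rec.sampling_rate,
            rec.data[perm],
            group=rec.group,
        )
        a = extract_features(rec)
        b = extract_features(swapped)
        assert np.allclose(
            a[spectral.feature_columns(a)].to_numpy(),
            b[spectral.feature_columns(b)].to_numpy(),
        )

    def test_constant_metric_signal_mean_equals_median(self, clean_tone_spec):
        # pure stationary tones: every sub-epoch yields identical ratios
        spec = synth.default_spec(
            duration=20.0, pink_noise_sd=0.0, line_noise_amp=0.0,
            artifact_rate=0.0, seed=3,
        )
        spec.alpha_ratio_sd = {g: {r: 0.0 for r in "FCPO"} for g in ("high", "low")}
        rec = synth.generate_recording(spec, "high", "s", 3)
        df = extract_features(rec)
        for m in spectral.CORRELATED_METRICS:
            for r in ("F", "C"):
                assert np.allclose(
                    df[feature_name(r, "mean", m)],
                    df[feature_name(r, "median", m)],
                    rtol=1e-8,
                )

    def test_all_flagged_is_an_error(self):
        data = np.full((1, 256 * 10), 300.0)
        rec = RawRecording("s", [("F1", "F")], 256.0, data)
        with pytest.raises(ValueError, match="flagged"):
            extract_features(rec, regions=("F",))

    def test_too_short_recording_rejected(self):
        rec = RawRecording("s", [("F1", "F")], 256.0, np.zeros((1, 100)))
        with pytest.raises(ValueError, match="shorter"):
            extract_features(rec, regions=("F",))
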