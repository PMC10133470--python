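"""Feature extraction: band filtering, DE/PSD, asymmetry, montages."""

import math

import numpy as np
import pytest

from oracles import fft_bandpass
from stgate.errors import ConfigurationError, DataError
from stgate.features import (
    BandSpec,
    ElectrodeMontage,
    FeatureConfig,
    RawRecording,
    asymmetry_features,
    bandpass_decompose,
    default_bands,
    differential_entropy,
    extract_features,
    mirror_pairs,
    power_spectral_density,
    seed62_montage,
    segment_windows,
)

RATE = 200.0
GAUSS_DE = 0.5 * math.log(2 * math.pi * math.e)  # ~1.4189


def make_rec(data, rate=RATE, label=0):
    data = np.atleast_2d(data)
    return RawRecording(
        data=data, rate=rate,
        channel_labels=[f"E{i+1}" for i in range(data.shape[0])],
        subject_id="S00", trial_id="T0", label=label,
    )


class TestBandpass:
    def test_alpha_sinusoid_lands_in_alpha_band(self):
        t = np.arange(int(10 * RATE)) / RATE
        sig = np.sin(2 * np.pi * 10.0 * t)
        rec = make_rec(sig)
        stacks = bandpass_decompose(rec)
        names = [b.name for b in default_bands()]
        alpha = stacks[names.index("alpha")][0]
        delta = stacks[names.index("delta")][0]
        in_var = sig.var()
        assert alpha.var() > 0.90 * in_var
        assert delta.var() < 0.05 * in_var
        # agree with an ideal FFT-mask filter on band energy
        oracle = fft_bandpass(sig, RATE, 8.0, 13.0)
        assert abs(alpha.var() - oracle.var()) < 0.05 * in_var

    def test_zero_signal_gives_zero_outputs(self):
        rec = make_rec(np.zeros((2, 400)))
        stacks = bandpass_decompose(rec)
        assert np.allclose(stacks, 0.0)

    def test_band_above_nyquist_is_configuration_error(self):
        rec = make_rec(np.random.default_rng(0).standard_normal(400))
        with pytest.raises(ConfigurationError):
            bandpass_decompose(rec, [BandSpec("bad", 100.0, 200.0)])


class TestWindows:
    @pytest.mark.parametrize(
        "n_samples,window,stride,expected",
        [(400, 1.0, 1.0, 2), (399, 1.0, 1.0, 1), (600, 1.0, 0.5, 5)],
    )
    def test_window_counts(self, n_samples, window, stride, expected):
        sig = np.zeros((3, n_samples))
        wins = segment_windows(sig, RATE, window, stride)
        assert len(wins) == expected
        # independently enumerate valid start indices
        w, s = int(window * RATE), int(stride * RATE)
        starts = [i for i in range(0, n_samples, s) if i + w <= n_samples]
        assert len(starts) == expected

    def test_window_longer_than_signal_returns_empty(self):
        assert segment_windows(np.zeros((1, 50)), RATE, 1.0, 1.0) == []


class TestDifferentialEntropy:
    def test_gaussian_closed_form(self):
        x = np.random.default_rng(7).standard_normal(10_000)
        assert abs(differential_entropy(x) - GAUSS_DE) < 0.05

    def test_scale_rule_adds_log_a(self):
        x = np.random.default_rng(8).standard_normal(500)
        for a in (2.0, 0.5, 10.0):
            assert differential_entropy(a * x) == pytest.approx(
                differential_entropy(x) + math.log(a), abs=1e-9
            )

    def test_constant_window_hits_variance_floor(self):
        expected = 0.5 * math.log(2 * math.pi * math.e * 1e-12)
        assert differential_entropy(np.full(100, 3.3)) == pytest.approx(expected)


class TestPSD:
    def test_sinusoid_alpha_dominates_beta(self):
        t = np.arange(int(5 * RATE)) / RATE
        win = np.sin(2 * np.pi * 10.0 * t)
        alpha = power_spectral_density(win, RATE, BandSpec("alpha", 8, 13), log=False)
        beta = power_spectral_density(win, RATE, BandSpec("beta", 14, 30), log=False)
        assert alpha > 10 * beta
        # direct FFT oracle on the same window
        spec = np.abs(np.fft.rfft(win)) ** 2
        freqs = np.fft.rfftfreq(win.size, 1 / RATE)
        assert spec[(freqs >= 8) & (freqs < 13)].sum() > 10 * spec[
            (freqs >= 14) & (freqs < 30)
        ].sum()

    def test_white_noise_roughly_flat(self):
        win = np.random.default_rng(3).standard_normal(10_000)
        vals = [
            power_spectral_density(win, RATE, b, log=False)
            for b in default_bands()
        ]
        assert max(vals) < 2 * min(vals)

    def test_zero_signal_returns_log_epsilon(self):
        out = power_spectral_density(np.zeros(256), RATE, BandSpec("alpha", 8, 13))
        assert out == pytest.approx(math.log(1e-12))

    def test_empty_band_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="narrow"):
            power_spectral_density(
                np.zeros(16), RATE, BandSpec("narrow", 10.0, 10.5)
            )


class TestAsymmetry:
    montage = ElectrodeMontage(
        labels=["L1", "R1", "L2", "R2"],
        coords2d=np.array([[-1, 0], [1, 0], [-0.5, 0.5], [0.5, 0.5]]),
        symmetric_pairs=[(0, 1), (2, 3)],
    )

    def test_symmetric_input_gives_zero_dasm_unit_rasm(self):
        de = np.ones((3, 4, 5))
        assert np.allclose(asymmetry_features(de, self.montage, "DASM"), 0.0)
        assert np.allclose(asymmetry_features(de, self.montage, "RASM"), 1.0)

    def test_swapping_hemispheres_negates_and_reciprocates(self):
        rng = np.random.default_rng(5)
        de = np.abs(rng.standard_normal((2, 4, 3))) + 0.5
        swapped = de[:, [1, 0, 3, 2], :]
        assert np.allclose(
            asymmetry_features(swapped, self.montage, "DASM"),
            -asymmetry_features(de, self.montage, "DASM"),
        )
        assert np.allclose(
            asymmetry_features(swapped, self.montage, "RASM"),
            1.0 / asymmetry_features(de, self.montage, "RASM"),
        )

    def test_direct_substitution(self):
        de = np.zeros((1, 4, 1))
        de[0, 0, 0], de[0, 1, 0] = 2.0, 0.5  # pair (L1, R1)
        de[0, 2, 0], de[0, 3, 0] = 1.0, 1.0
        dasm = asymmetry_features(de, self.montage, "DASM")
        rasm = asymmetry_features(de, self.montage, "RASM")
        assert dasm[0, 0, 0] == pytest.approx(1.5)
        assert rasm[0, 0, 0] == pytest.approx(4.0)
        asm = asymmetry_features(de, self.montage, "ASM")
        assert asm.shape == (1, 4, 1)  # [DASM || RASM] along the pair axis

    def test_empty_pair_list_is_configuration_error(self):
        empty = ElectrodeMontage(["A", "B"], np.zeros((2, 2)), [])
        with pytest.raises(ConfigurationError):
            asymmetry_features(np.ones((1, 2, 1)), empty, "DASM")


class TestExtractFeatures:
    def test_shapes_for_de_and_dasm_on_62_channels(self):
        rng = np.random.default_rng(11)
        montage = seed62_montage()
        rec = RawRecording(
            data=rng.standard_normal((62, int(60 * RATE))),
            rate=RATE, channel_labels=montage.labels,
            subject_id="S01", trial_id="T1", label=1,
        )
        de = extract_features(rec, FeatureConfig(feature_kind="DE"), montage)
        assert de.values.shape == (60, 62, 5)
        dasm = extract_features(rec, FeatureConfig(feature_kind="DASM"), montage)
        assert dasm.values.shape == (60, 27, 5)

    def test_extraction_is_deterministic(self):
        rng = np.random.default_rng(12)
        rec = make_rec(rng.standard_normal((4, 2000)))
        cfg = FeatureConfig()
        a = extract_features(rec, cfg).values
        b = extract_features(rec, cfg).values
        assert np.array_equal(a, b)

    def test_errors_carry_subject_and_trial_context(self):
        rec = make_rec(np.random.default_rng(1).standard_normal((2, 1000)), rate=50.0)
        with pytest.raises(ConfigurationError, match="S00/T0"):
            extract_features(rec, FeatureConfig())  # beta/gamma above Nyquist at 50 Hz


class TestMontage:
    def test_seed62_montage_has_27_mirror_pairs(self):
        m = seed62_montage()
        assert m.n_channels == 62
        assert len(m.symmetric_pairs) == 27
        used = [i for pair in m.symmetric_pairs for i in pair]
        assert len(used) == len(set(used))  # disjoint pairs
        # left/right really are mirrored across the midline
        for left, right in m.symmetric_pairs:
            assert m.coords2d[left, 0] < 0 < m.coords2d[right, 0]

    def test_mirror_pairs_skips_midline(self):
        pairs = mirror_pairs(["F3", "FZ", "F4", "CZ"])
        assert pairs == [(0, 2)]

    def test_recording_validation(self):
        with pytest.raises(DataError):
            make_rec(np.array([[np.nan, 1.0]]))
        with pytest.raises(DataError):
            RawRecording(np.zeros((2, 10)), RATE, ["A", "A"], "s", "t", 0)
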