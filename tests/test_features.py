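"""Window features against brute-force oracles and closed-form cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ehgselect.features import (
    AMPLITUDE_BANDS,
    FEATURE_NAMES,
    FeatureTable,
    N_EHG_FEATURES,
    OBSTETRIC_NAMES,
    app,
    bubble_entropy,
    dispersion_entropy,
    extract_record,
    fuzzy_entropy,
    impute_obstetrics,
    katz_fd,
    lempel_ziv,
    poincare,
    quantize,
    sample_entropy,
    spectral_entropy,
    spectral_features,
    time_reversibility,
)
from ehgselect.features import _lz76_phrases
from ehgselect.synthetic import generate_record

FS = 20.0


def _sine(freq, n=2400, fs=FS, phase=0.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def lz76_oracle(symbols):
    """Exhaustive-production parsing by substring search (independent of
    the pointer-based parser in the package)."""
    s = "".join(map(str, symbols))
    n, i, c = len(s), 0, 0
    while i < n:
        k = 1
        while i + k <= n and s[i:i + k] in s[:i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def sampen_oracle(x, m=2, r=None):
    """O(n^2) template-counting sample entropy."""
    x = np.asarray(x, float)
    if r is None:
        r = 0.15 * x.std()
    N = len(x)

    def count(mm):
        templates = [x[i:i + mm] for i in range(N - m)]
        c = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if np.max(np.abs(templates[i] - templates[j])) <= r:
                    c += 1
        return c

    B, A = count(m), count(m + 1)
    return -np.log(A / B)


def kfd_oracle(x):
    x = np.asarray(x, float)
    L = sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))
    a = L / (len(x) - 1)
    d = max(abs(x[i] - x[0]) for i in range(len(x)))
    return np.log10(L / a) / np.log10(d / a)


# ---------------------------------------------------------------------------
# temporal
# ---------------------------------------------------------------------------

class TestApp:
    def test_unit_sine(self):
        assert app(_sine(0.5)) == pytest.approx(2.0, abs=1e-6)

    def test_constant(self):
        assert app(np.full(100, 3.7)) == 0.0

    def test_matches_direct_scan(self, rng):
        w = rng.standard_normal(500)
        assert app(w) == max(w) - min(w)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            app(np.array([]))


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------

class TestSpectralFeatures:
    def test_pure_half_hz(self):
        out = spectral_features(_sine(0.5), FS)
        assert out["DF1"] == pytest.approx(0.5, abs=0.034)
        assert out["DF2"] == pytest.approx(0.5, abs=0.034)
        assert out["HLRatio"] > 10
        assert out["NormEn_0.34-0.6"] > 0.9

    def test_pure_quarter_hz(self):
        out = spectral_features(_sine(0.25), FS)
        assert out["DF1"] == pytest.approx(0.25, abs=0.034)
        assert out["NormEn_0.2-0.34"] > 0.9
        assert out["HLRatio"] < 0.1

    def test_flat_spectrum_deciles(self):
        """Ideally band-limited white noise: cumulative energy is linear in
        frequency, so D_k ~= 0.2 + 0.08 k."""
        rng = np.random.default_rng(8)
        n = 24000
        spec = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n, 1 / FS)
        spec[(f < 0.2) | (f > 1.0)] = 0.0
        x = np.fft.irfft(spec, n=n)
        deciles = np.zeros((10, 9))
        for w in range(10):
            out = spectral_features(x[w * 2400:(w + 1) * 2400], FS)
            deciles[w] = [out[f"D{k}"] for k in range(1, 10)]
        mean_d = deciles.mean(axis=0)
        for k in range(1, 10):
            assert mean_d[k - 1] == pytest.approx(0.2 + 0.08 * k, abs=0.034)

    def test_deciles_monotone_and_in_band(self, rng):
        out = spectral_features(rng.standard_normal(2400), FS)
        d = [out[f"D{k}"] for k in range(1, 10)]
        assert all(a <= b for a, b in zip(d, d[1:]))
        assert 0.2 <= d[0] and d[-1] <= 1.0

    def test_normen_partitions_band_energy(self, rng):
        out = spectral_features(rng.standard_normal(2400), FS)
        total = (out["NormEn_0.2-0.34"] + out["NormEn_0.34-0.6"]
                 + out["NormEn_0.6-1"])
        assert 0.9 < total <= 1.0 + 1e-9

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError):
            spectral_features(np.zeros(2400), FS)


# ---------------------------------------------------------------------------
# Lempel-Ziv
# ---------------------------------------------------------------------------

class TestLempelZiv:
    def test_constant_is_two_phrase_minimum(self):
        n = 500
        value = lempel_ziv(np.zeros(n), 2)
        assert value == pytest.approx(2 * np.log(n) / (n * np.log(2)))

    def test_alternating_matches_oracle(self):
        seq = np.tile([0, 1], 500)
        c = lz76_oracle(seq)
        assert _lz76_phrases(np.array(seq)) == c

    def test_parser_equals_oracle_on_random_sequences(self, rng):
        for n_states in (2, 6):
            for n in (5, 17, 64, 200):
                for _ in range(10):
                    seq = rng.integers(0, n_states, size=n)
                    assert _lz76_phrases(seq) == lz76_oracle(seq), seq

    def test_random_binary_near_unity(self, rng):
        x = rng.standard_normal(1000)
        assert 0.85 <= lempel_ziv(x, 2) <= 1.15

    def test_multistate_quantizer_equiprobable(self, rng):
        symbols = quantize(rng.standard_normal(6000), 6)
        counts = np.bincount(symbols, minlength=6)
        assert counts.min() > 800  # ~1000 each

    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            lempel_ziv(np.zeros(10), 3)


# ---------------------------------------------------------------------------
# time reversibility, KFD, Poincare
# ---------------------------------------------------------------------------

class TestTimeRev:
    def test_time_symmetric_cosine(self):
        x = np.cos(2 * np.pi * np.arange(2000) / 100)  # integer periods
        assert time_reversibility(x) == pytest.approx(0.0, abs=1e-9)

    def test_sawtooth_sign_matches_direct_formula(self):
        x = np.tile(np.linspace(0, 1, 50), 20)  # slow rise, instant fall
        d = np.diff(x)
        assert time_reversibility(x) == pytest.approx(np.mean(d**3))
        assert time_reversibility(x) < 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_odd_under_reversal(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        assert time_reversibility(x[::-1]) == pytest.approx(
            -time_reversibility(x), rel=1e-9, abs=1e-12)


class TestKatzFD:
    def test_straight_line(self):
        assert katz_fd(np.linspace(0, 5, 100)) == pytest.approx(1.0)

    def test_matches_oracle(self, rng):
        x = rng.standard_normal(500)
        assert katz_fd(x) == pytest.approx(kfd_oracle(x), abs=1e-10)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(300)
        assert katz_fd(10 * x) == pytest.approx(katz_fd(x), rel=1e-12)

    def test_at_least_one(self, rng):
        for _ in range(10):
            assert katz_fd(rng.standard_normal(200)) >= 1.0


class TestPoincare:
    def test_constant(self):
        out = poincare(np.full(100, 2.0))
        assert out["SD1"] == out["SD2"] == out["SDRR"] == 0.0
        assert np.isnan(out["SD1SD2"])

    def test_white_noise(self):
        x = np.random.default_rng(4).normal(0, 2.0, size=200_000)
        out = poincare(x)
        assert out["SD1"] == pytest.approx(2.0, rel=0.02)
        assert out["SD2"] == pytest.approx(2.0, rel=0.02)
        assert out["SD1SD2"] == pytest.approx(1.0, abs=0.05)

    def test_slow_ramp_dominated_by_sd2(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 1000) + 0.001 * rng.standard_normal(1000)
        out = poincare(x)
        assert out["SD1"] < 0.1 * out["SD2"]

    def test_matches_direct_formula(self, rng):
        x = rng.standard_normal(400)
        out = poincare(x)
        sd1 = np.sqrt(np.var(np.diff(x)) / 2)
        sd2 = np.sqrt(2 * np.var(x) - np.var(np.diff(x)) / 2)
        assert out["SD1"] == pytest.approx(sd1, abs=1e-12)
        assert out["SD2"] == pytest.approx(sd2, abs=1e-12)
        assert out["SDRR"] == pytest.approx(np.sqrt((sd1**2 + sd2**2) / 2), abs=1e-12)


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

class TestEntropies:
    def test_constant_signal(self):
        x = np.full(300, 1.5)
        assert sample_entropy(x) == 0.0
        assert dispersion_entropy(x) == 0.0
        assert fuzzy_entropy(x) == 0.0

    def test_pure_sinusoid_low_spectral_entropy(self):
        # Welch/Hann leakage spreads the line over ~3 bins, so the floor
        # is small but not exactly zero
        assert spectral_entropy(_sine(0.5), FS) < 0.35
        noise = np.random.default_rng(6).standard_normal(2400)
        assert spectral_entropy(noise, FS, band=(0.2, 1.0)) > \
            spectral_entropy(_sine(0.5), FS)

    def test_sampen_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal(300)
        assert sample_entropy(x) == pytest.approx(sampen_oracle(x), abs=1e-10)

    def test_sampen_regular_vs_random(self, rng):
        regular = _sine(0.5, n=500)
        noise = rng.standard_normal(500)
        assert sample_entropy(regular) < sample_entropy(noise)

    def test_dispersion_entropy_uniformity(self, rng):
        """Random data uses many dispersion patterns, periodic data few."""
        assert dispersion_entropy(rng.standard_normal(2000)) > \
            dispersion_entropy(_sine(0.5, n=2000))

    def test_bubble_entropy_finite_on_noise(self, rng):
        v = bubble_entropy(rng.standard_normal(500))
        assert np.isfinite(v) and v > 0


# ---------------------------------------------------------------------------
# record-level extraction
# ---------------------------------------------------------------------------

class TestExtractRecord:
    def test_feature_accounting(self, short_record_features):
        vals = short_record_features
        assert len(vals) == 227
        assert list(vals) == FEATURE_NAMES
        ehg = [n for n in vals if n not in OBSTETRIC_NAMES]
        assert len(ehg) == 222
        for ch in ("S1", "S2", "S3"):
            per_channel = [n for n in ehg if n.startswith(ch)]
            assert len(per_channel) == 74
            assert sum("App" in n for n in per_channel) == 4
            nl = [n for n in per_channel if any(
                n.startswith(f"{ch}_{m}_") for m in
                ("LZBin", "LZMulti", "TimeRev", "KFD", "SD1", "SD2", "SDRR",
                 "SD1SD2", "SampEn", "FuzEn", "SpEn", "DispEn", "BubbEn"))]
            assert len(nl) == 52

    def test_value_sanity(self, short_record_features):
        vals = short_record_features
        for band in AMPLITUDE_BANDS:
            assert vals[f"S1_App_{band[0]:g}-{band[1]:g}Hz"] >= 0
        assert vals["S1_KFD_0.1-4Hz"] >= 1.0
        d = [vals[f"S2_D{k}"] for k in range(1, 10)]
        assert all(a <= b for a, b in zip(d, d[1:]))
        assert 22 <= vals["weeks_of_gestation"] <= 37

    def test_channel_permutation(self, short_spec, short_record,
                                 short_record_features):
        swapped = type(short_record)(
            record_id="T001s",
            signals=short_record.signals[[1, 0, 2]],
            fs=short_record.fs,
            artifact_intervals=short_record.artifact_intervals,
            obstetrics=short_record.obstetrics,
            label=short_record.label)
        vals2 = extract_record(swapped)
        for name, v in short_record_features.items():
            if name.startswith("S1"):
                other = "S2" + name[2:]
            elif name.startswith("S2"):
                other = "S1" + name[2:]
            else:
                other = name
            assert vals2[other] == pytest.approx(v, rel=1e-9, abs=1e-12), name

    def test_offset_invariance(self, short_record, short_record_features):
        """A constant offset is rejected by the 0.1 Hz high-pass edge, so
        every signal feature is offset-invariant."""
        shifted = type(short_record)(
            record_id="T001o",
            signals=short_record.signals + 100.0,
            fs=short_record.fs,
            artifact_intervals=short_record.artifact_intervals,
            obstetrics=short_record.obstetrics,
            label=short_record.label)
        vals2 = extract_record(shifted)
        for name, v in short_record_features.items():
            assert vals2[name] == pytest.approx(v, rel=1e-4, abs=1e-6), name


class TestImputation:
    def test_median_from_training_rows_only(self):
        X = np.array([[0.0, 25.0], [1.0, 30.0], [2.0, 40.0], [3.0, np.nan]])
        table = FeatureTable(X, ["S1_App_0.1-4Hz", "maternal_age"],
                             np.array([0, 0, 1, 1]))
        out = impute_obstetrics(table, train_idx=np.array([0, 1]))
        assert out.X[3, 1] == 27.5  # median of rows 0-1, not of all rows
        # signal features are never touched
        assert np.array_equal(out.X[:, 0], X[:, 0])
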