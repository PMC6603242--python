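"""Equalizer chain: excitation, NLMS identification, minimum phase,
band-limited inversion, latency measurement."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from startlekit import equalizer as eq
from startlekit.simulate import simulate_lems
from startlekit.stimulus import Waveform

RATE = 48000.0


def _convolve_through(system, x):
    import warnings

    from startlekit.stimulus import ClippingWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClippingWarning)
        return Waveform(fftconvolve(x.samples, system)[: len(x)], RATE)


@pytest.fixture(scope="module")
def colored_chain():
    lems = simulate_lems(RATE, n_taps=256, coloration_db=6.0, seed=2)
    x = eq.generate_excitation("white", RATE, duration_s=2.0, seed=0)
    y = _convolve_through(lems.coefficients, x)
    return lems, x, y


class TestExcitation:
    def test_mls_order4_length_15(self):
        w = eq.generate_excitation("mls", RATE, mls_order=4)
        assert len(w) == 15
        assert set(np.unique(w.samples)) == {-1.0, 1.0}

    @pytest.mark.parametrize("order", [3, 4, 6, 8])
    def test_mls_periodic_autocorrelation(self, order):
        # brute-force circular autocorrelation: peak N, off-peak -1
        x = eq.generate_excitation("mls", RATE, mls_order=order).samples
        n = len(x)
        acf = np.array([np.dot(x, np.roll(x, k)) for k in range(n)])
        assert acf[0] == pytest.approx(n)
        np.testing.assert_allclose(acf[1:], -1.0, atol=1e-9)

    def test_white_determinism_and_rms(self):
        a = eq.generate_excitation("white", RATE, duration_s=0.1, seed=4)
        b = eq.generate_excitation("white", RATE, duration_s=0.1, seed=4)
        assert np.array_equal(a.samples, b.samples)
        assert a.rms() == pytest.approx(0.5, rel=1e-9)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            eq.generate_excitation("chirp", RATE, duration_s=0.1)

    def test_mls_order_out_of_range(self):
        with pytest.raises(ValueError):
            eq.generate_excitation("mls", RATE, mls_order=25)


class TestNLMS:
    def test_one_tap_noiseless_convergence(self):
        x = eq.generate_excitation("white", RATE, duration_s=0.05, seed=0)
        y = Waveform(0.5 * x.samples, RATE)
        h, _ = eq.nlms_identify(x, y, eq.NLMSConfig(filter_length=1, step_size=1.0))
        assert h.coefficients[0] == pytest.approx(0.5, abs=1e-6)

    def test_random_fir_misalignment_below_1e3(self):
        rng = np.random.default_rng(1)
        true = rng.standard_normal(64) * np.exp(-np.arange(64) / 16)
        x = eq.generate_excitation("white", RATE, duration_s=2.0, seed=2)
        y = _convolve_through(true, x)
        cfg = eq.NLMSConfig(filter_length=64, step_size=1.0,
                            regularization=1e-8, passes=2)
        h, _ = eq.nlms_identify(x, y, cfg)
        mis = np.linalg.norm(h.coefficients - true) / np.linalg.norm(true)
        assert mis < 1e-3

    def test_zero_step_size_leaves_zeros(self):
        x = eq.generate_excitation("white", RATE, duration_s=0.02, seed=0)
        h, _ = eq.nlms_identify(x, x, eq.NLMSConfig(filter_length=8, step_size=0.0))
        assert not np.any(h.coefficients)

    def test_silent_excitation_rejected(self):
        silent = Waveform(np.zeros(1000), RATE)
        with pytest.raises(ValueError, match="silent"):
            eq.nlms_identify(silent, silent, eq.NLMSConfig(filter_length=8))

    def test_error_power_decreasing_trend(self):
        # on stationary white excitation the smoothed e^2 trace must fall
        true = np.array([1.0, -0.4, 0.2, 0.1])
        x = eq.generate_excitation("white", RATE, duration_s=0.5, seed=5)
        y = _convolve_through(true, x)
        _, e2 = eq.nlms_identify(
            x, y, eq.NLMSConfig(filter_length=4, step_size=0.5, passes=1))
        k = len(e2) // 4
        first, last = np.mean(e2[:k]), np.mean(e2[-k:])
        assert last < first * 0.1


class TestMinimumPhase:
    def test_already_minimum_phase_recovered(self):
        h = eq.FIRSystem([1.0, 0.5], RATE)
        out = eq.minimum_phase(h)
        np.testing.assert_allclose(out.coefficients, [1.0, 0.5], atol=1e-6)

    def test_maximum_phase_magnitude_preserved(self):
        h = eq.FIRSystem([0.5, 1.0], RATE)
        out = eq.minimum_phase(h)
        _, H = h.freq_response(1024)
        _, M = out.freq_response(1024)
        dev_db = 20 * np.log10(np.abs(M) / np.abs(H))
        assert np.max(np.abs(dev_db)) < 0.01

    def test_impulse_identity(self):
        out = eq.minimum_phase(eq.FIRSystem([1.0], RATE))
        np.testing.assert_allclose(out.coefficients, [1.0], atol=1e-12)

    def test_output_zeros_inside_unit_circle(self):
        lems = simulate_lems(RATE, n_taps=64, coloration_db=6.0, seed=3)
        roots = np.roots(lems.coefficients)
        assert np.max(np.abs(roots)) <= 1.0 + 1e-6

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            eq.minimum_phase(eq.FIRSystem([0.0, 0.0], RATE))


class TestInvertTransfer:
    def test_pure_gain_delay_inverts_flat(self):
        h = np.zeros(32)
        h[4] = 2.0  # gain 2, delay 4 samples
        eqf = eq.invert_transfer(eq.FIRSystem(h, RATE), (2000, 20000), n_taps=2048)
        rep = eq.cascade_flatness(eq.FIRSystem(h, RATE), eqf)
        assert rep.max_deviation_db < 0.1
        # in-band cascade magnitude is 1 (0 dB), not just flat
        casc = fftconvolve(h, eqf.coefficients)
        f = np.fft.rfftfreq(1 << 15, 1 / RATE)
        C = np.abs(np.fft.rfft(casc, n=1 << 15))
        sel = (f >= 2000) & (f <= 20000)
        np.testing.assert_allclose(C[sel], 0.5 * 2.0, rtol=0.01)

    def test_large_regularization_kills_gain(self):
        h = eq.FIRSystem([1.0], RATE)
        eqf = eq.invert_transfer(h, (2000, 20000), n_taps=512, regularization=1e6)
        f, G = np.fft.rfftfreq(8192, 1 / RATE), np.fft.rfft(eqf.coefficients, n=8192)
        sel = (f >= 4000) & (f <= 16000)
        assert np.max(np.abs(G[sel])) < 1e-2

    def test_too_few_taps_rejected(self):
        with pytest.raises(ValueError):
            eq.invert_transfer(eq.FIRSystem([1.0], RATE), (2000, 20000), n_taps=4)


class TestDesignEqualizer:
    def test_identity_system_near_delta(self):
        x = eq.generate_excitation("white", RATE, duration_s=0.5, seed=0)
        cfg = eq.NLMSConfig(filter_length=32, step_size=1.0, regularization=1e-8)
        eqf, rep = eq.design_equalizer(x, x, cfg, n_taps=256)
        assert rep.max_deviation_db < 0.1

    def test_colored_lems_flattened_within_1db(self, colored_chain):
        lems, x, y = colored_chain
        cfg = eq.NLMSConfig(filter_length=512, step_size=1.0,
                            regularization=1e-8, passes=3)
        eqf, report = eq.design_equalizer(x, y, cfg, n_taps=1024)
        assert eqf.band_hz == (2000.0, 20000.0)
        assert report.unequalized_deviation_db > 3.0
        assert report.max_deviation_db < 1.0
        # flatness also holds against the true (not just identified) system
        assert eq.cascade_flatness(lems, eqf).max_deviation_db < 1.0


class TestApplyEqualizer:
    def test_unit_impulse_identity(self):
        w = Waveform(np.sin(np.arange(400) * 0.1) * 0.5, RATE)
        imp = np.zeros(16)
        imp[0] = 1.0
        eqf = eq.EqualizerFilter(imp, RATE, (2000, 20000), delay_samples=0)
        out = eq.apply_equalizer(w, eqf)
        np.testing.assert_allclose(out.samples, w.samples, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        w = Waveform(rng.standard_normal(300) * 0.1, RATE)
        eqf = eq.EqualizerFilter(rng.standard_normal(32) * 0.1, RATE, (2000, 20000))
        a = eq.apply_equalizer(Waveform(3.0 * w.samples, RATE), eqf)
        b = eq.apply_equalizer(w, eqf)
        np.testing.assert_allclose(a.samples, 3.0 * b.samples, atol=1e-12)

    def test_matches_direct_convolution(self):
        rng = np.random.default_rng(7)
        w = Waveform(rng.standard_normal(50) * 0.1, RATE)
        taps = rng.standard_normal(8) * 0.2
        eqf = eq.EqualizerFilter(taps, RATE, (2000, 20000))
        out = eq.apply_equalizer(w, eqf, full=True)
        # O(N*M) direct-sum oracle
        expected = np.zeros(50 + 8 - 1)
        for i, wi in enumerate(w.samples):
            for j, tj in enumerate(taps):
                expected[i + j] += wi * tj
        np.testing.assert_allclose(out.samples, expected, atol=1e-10)

    def test_rate_mismatch_rejected(self):
        w = Waveform(np.zeros(100) + 0.1, 44100.0)
        eqf = eq.EqualizerFilter(np.ones(16), RATE, (2000, 20000))
        with pytest.raises(ValueError, match="rate"):
            eq.apply_equalizer(w, eqf)


class TestMeasureLatency:
    def _pulse(self, delay, n=500):
        x = np.zeros(n)
        x[delay:delay + 50] = 1.0
        return Waveform(x, RATE, "trigger")

    def test_identical_pulses_zero_offsets(self):
        offs = eq.measure_latency([self._pulse(100)] * 3)
        assert np.array_equal(offs, [0, 0, 0])

    def test_delayed_channel(self):
        offs = eq.measure_latency([self._pulse(100), self._pulse(110)])
        assert list(offs) == [0, 10]

    def test_arbitrary_shifts_recovered(self):
        shifts = [40, 173, 7]
        offs = eq.measure_latency([self._pulse(s) for s in shifts])
        assert list(offs) == [0, 133, -33]

    def test_missing_pulse_rejected(self):
        with pytest.raises(ValueError, match="no pulse"):
            eq.measure_latency([self._pulse(100), Waveform(np.zeros(500), RATE, "trigger")])

    def test_equalizer_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        eqf = eq.EqualizerFilter(rng.standard_normal(64), RATE, (2000.0, 20000.0),
                                 delay_samples=16)
        eqf.save_csv(tmp_path / "eq.csv")
        back = eq.EqualizerFilter.load_csv(tmp_path / "eq.csv")
        np.testing.assert_array_equal(back.coefficients, eqf.coefficients)
        assert back.band_hz == eqf.band_hz and back.delay_samples == 16
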