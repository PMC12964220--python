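"""Smoothing, envelope, rate-trace, and ISI-QC primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import icloco as ic
from icloco.errors import DegenerateInputError

from conftest import make_signal


def brute_force_hanning(x: np.ndarray, n: int) -> np.ndarray:
    """Independent O(n*w) oracle: reflect-pad + direct convolution."""
    from scipy.signal.windows import hann

    if n % 2 == 0:
        n += 1
    k = hann(n, sym=True)
    k = k / k.sum()
    half = n // 2
    # symmetric reflection with edge repetition (d c b a | a b c d | d c b a)
    padded = np.concatenate([x[:half][::-1], x, x[-half:][::-1]])
    out = np.empty_like(x)
    for i in range(x.size):
        out[i] = np.dot(padded[i:i + n], k)
    return out


class TestSmoothHanning:
    def test_constant_preserved(self):
        sig = make_signal(np.full(500, 3.7))
        out = ic.smooth_hanning(sig, 0.05)
        assert np.allclose(out.samples, 3.7, atol=1e-12)

    def test_impulse_gives_unit_area_kernel(self):
        x = np.zeros(1001)
        x[500] = 1.0
        out = ic.smooth_hanning(make_signal(x), 0.1)
        assert out.samples.sum() == pytest.approx(1.0, abs=1e-12)
        assert out.samples[500] == out.samples.max()
        assert np.allclose(out.samples, out.samples[::-1], atol=1e-15)  # symmetric

    def test_linear_ramp_preserved_interior(self):
        ramp = np.linspace(0.0, 10.0, 2000)
        out = ic.smooth_hanning(make_signal(ramp), 0.1)
        assert np.allclose(out.samples[150:-150], ramp[150:-150], atol=1e-9)

    @pytest.mark.parametrize("win", [0.02, 0.05, 0.13])
    def test_matches_bruteforce_oracle(self, win):
        rng = np.random.default_rng(7)
        x = rng.normal(size=3000)
        out = ic.smooth_hanning(make_signal(x), win)
        oracle = brute_force_hanning(x, int(round(win * 1000)))
        assert np.allclose(out.samples, oracle, atol=1e-10)

    @given(st.floats(-5.0, 5.0))
    def test_linearity_in_amplitude(self, a):
        rng = np.random.default_rng(11)
        x = rng.normal(size=800)
        base = ic.smooth_hanning(make_signal(x), 0.05).samples
        scaled = ic.smooth_hanning(make_signal(a * x), 0.05).samples
        assert np.allclose(scaled, a * base, atol=1e-10)

    def test_window_longer_than_signal_errors(self):
        with pytest.raises(DegenerateInputError):
            ic.smooth_hanning(make_signal(np.zeros(50)), 0.2)

    def test_causal_variant_preserves_constants(self):
        sig = make_signal(np.full(400, -2.0))
        out = ic.smooth_hanning(sig, 0.05, causal=True)
        assert np.allclose(out.samples, -2.0, atol=1e-12)


class TestMovingAverageEnvelope:
    @pytest.mark.parametrize("c", [2.5, -2.5])
    def test_constant_rectified(self, c):
        sig = make_signal(np.full(4000, c))
        out = ic.moving_average_envelope(sig, 0.2, 100.0)
        assert out.rate == 100.0
        assert np.allclose(out.samples, abs(c), atol=1e-12)

    def test_fast_sine_envelope_is_two_over_pi(self):
        rate, amp, freq = 10000.0, 3.0, 500.0
        t = np.arange(int(rate * 2)) / rate
        x = amp * np.sin(2 * np.pi * freq * t)
        out = ic.moving_average_envelope(make_signal(x, rate), 0.2, 1000.0)
        expected = 2 * amp / np.pi  # mean of |sin|
        mid = out.samples[300:-300]
        assert np.allclose(mid, expected, rtol=0.02)
        # brute-force average over one window agrees
        brute = np.abs(x[10000 - 1000:10000 + 1000]).mean()
        assert brute == pytest.approx(expected, rel=0.02)

    def test_out_rate_above_input_errors(self):
        with pytest.raises(ValueError):
            ic.moving_average_envelope(make_signal(np.ones(100)), 0.01, 2000.0)

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        e1 = ic.moving_average_envelope(make_signal(x), 0.1, 500.0).samples
        e2 = ic.moving_average_envelope(make_signal(3.5 * x), 0.1, 500.0).samples
        assert np.allclose(e2, 3.5 * e1, atol=1e-12)

    def test_decimation_is_bin_mean(self):
        x = np.arange(40, dtype=float)
        out = ic.moving_average_envelope(make_signal(x, rate=40.0), 1 / 40.0, 10.0)
        # window of 1 sample -> pure bin-mean of |x|
        assert np.allclose(out.samples, x.reshape(-1, 4).mean(axis=1))


class TestFiringRateTrace:
    def test_empty_train_is_zero(self, cfg):
        st_ = ic.SpikeTrain(np.array([]), 10.0)
        out = ic.firing_rate_trace(st_, cfg)
        assert out.n == 10000
        assert np.all(out.samples == 0.0)

    def test_rate_conservation(self, cfg):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 30.0, 600))
        tr = ic.firing_rate_trace(ic.SpikeTrain(times, 30.0), cfg)
        assert tr.samples.mean() * 30.0 == pytest.approx(600, rel=1e-3)

    def test_homogeneous_poisson_mean(self, cfg):
        rng = np.random.default_rng(17)
        lam, dur = 20.0, 100.0
        times = np.sort(rng.uniform(0, dur, rng.poisson(lam * dur)))
        tr = ic.firing_rate_trace(ic.SpikeTrain(times, dur), cfg)
        se = np.sqrt(lam / dur)
        assert abs(tr.samples.mean() - lam) < 3 * se

    @given(seed=st.integers(0, 2**31 - 1))
    def test_count_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 400))
        dur = float(rng.uniform(2.0, 20.0))
        times = np.sort(rng.uniform(0, dur, n))
        tr = ic.firing_rate_trace(ic.SpikeTrain(times, dur))
        integral = tr.samples.sum() / tr.rate
        assert integral == pytest.approx(n, abs=max(1e-3 * max(n, 1), 1e-9))


class TestIsiViolations:
    def test_regular_train_has_none(self, cfg):
        st_ = ic.SpikeTrain(np.arange(0, 5, 0.01), 5.0)
        assert ic.isi_violation_rate(st_, cfg) == 0.0
        assert ic.passes_isi_qc(st_, cfg)

    def test_boundary_rate_fails_strictly(self, cfg):
        # 200 ISIs, exactly one of 0.5 ms -> rate 0.005, QC requires strictly below
        times = np.cumsum(np.r_[0.0, np.full(199, 0.01), 0.0005])
        st_ = ic.SpikeTrain(times, times[-1] + 0.01)
        assert ic.isi_violation_rate(st_, cfg) == pytest.approx(0.005)
        assert not ic.passes_isi_qc(st_, cfg)

    def test_three_in_thousand_passes(self, cfg):
        isis = np.full(1000, 0.01)
        isis[[10, 500, 900]] = 0.0005
        st_ = ic.SpikeTrain(np.cumsum(np.r_[0.0, isis]), 12.0)
        assert ic.isi_violation_rate(st_, cfg) == pytest.approx(0.003)
        assert ic.passes_isi_qc(st_, cfg)

    def test_undefined_below_two_spikes(self, cfg):
        with pytest.raises(DegenerateInputError):
            ic.isi_violation_rate(ic.SpikeTrain(np.array([1.0]), 5.0), cfg)


class TestContainers:
    def test_invalid_signal_rejected(self):
        with pytest.raises(ValueError):
            ic.ContinuousSignal(np.array([1.0, np.nan]), 100.0)
        with pytest.raises(ValueError):
            ic.ContinuousSignal(np.zeros(5), 0.0)

    def test_invalid_spiketrain_rejected(self):
        with pytest.raises(ValueError):
            ic.SpikeTrain(np.array([0.2, 0.1]), 1.0)
        with pytest.raises(ValueError):
            ic.SpikeTrain(np.array([0.5, 1.5]), 1.0)

    def test_duration_definition(self):
        sig = ic.ContinuousSignal(np.zeros(2500), 500.0)
        assert sig.duration == pytest.approx(5.0)
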