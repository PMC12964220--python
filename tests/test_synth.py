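"""Ground-truth generator: locomotion, spikes, EMG, vibration, audio, presets."""

import numpy as np
import pytest
from scipy import stats

import icloco as ic
from icloco.modulation import DECREASED, INCREASED, NS


class TestSimulateLocomotion:
    def test_no_bouts_means_zero_speed(self):
        rng = np.random.default_rng(0)
        _, speed, bouts = ic.simulate_locomotion(30.0, 0, rng, speed_noise_sd=0.0)
        assert bouts == []
        assert np.all(speed.samples == 0.0)

    def test_bouts_disjoint_with_rest_before_each(self):
        rng = np.random.default_rng(1)
        _, _, bouts = ic.simulate_locomotion(300.0, 5, rng)
        assert len(bouts) == 5
        prev_end = 0.0
        for onset, end in bouts:
            assert end > onset
            assert onset - prev_end >= 0.5  # at least the pre-onset stillness
            prev_end = end

    def test_same_seed_reproduces_traces(self):
        a = ic.simulate_locomotion(60.0, 4, np.random.default_rng(7))
        b = ic.simulate_locomotion(60.0, 4, np.random.default_rng(7))
        assert np.array_equal(a[0].samples, b[0].samples)
        assert np.array_equal(a[1].samples, b[1].samples)
        assert a[2] == b[2]

    def test_infeasible_packing_errors(self):
        with pytest.raises(ValueError):
            ic.simulate_locomotion(20.0, 10, np.random.default_rng(0))


class TestSimulateUnit:
    def test_unmodulated_rate_within_3se(self):
        rng = np.random.default_rng(2)
        lam, dur = 12.0, 200.0
        st = ic.simulate_unit([], NS, 1.0, 0.0, lam, dur, rng, refractory=0.0)
        se = np.sqrt(lam / dur)
        assert abs(st.mean_rate - lam) < 3 * se

    def test_zero_base_rate_is_empty(self):
        st = ic.simulate_unit([(1.0, 2.0)], INCREASED, 3.0, 0.0, 0.0, 10.0, np.random.default_rng(3))
        assert st.n_spikes == 0

    def test_mixture_mean_matches_oracle(self):
        """5 Hz base, gain 3, modulated half the time -> overall 10 Hz."""
        rng = np.random.default_rng(4)
        dur = 400.0
        bouts = [(float(k), float(k + 1)) for k in range(0, int(dur), 2)]
        st = ic.simulate_unit(bouts, INCREASED, 3.0, 0.0, 5.0, dur, rng, refractory=0.0)
        expected = 0.5 * 5.0 + 0.5 * 15.0
        se = np.sqrt(expected / dur)
        assert abs(st.mean_rate - expected) < 3 * se

    def test_lead_before_session_start_clips_with_warning(self):
        with pytest.warns(UserWarning):
            st = ic.simulate_unit(
                [(0.1, 2.0)], INCREASED, 3.0, -0.5, 10.0, 10.0, np.random.default_rng(5)
            )
        assert st.times.min() >= 0.0

    def test_refractory_enforced_by_default(self, cfg):
        st = ic.simulate_unit([], NS, 1.0, 0.0, 40.0, 100.0, np.random.default_rng(6))
        assert np.diff(st.times).min() >= 0.001
        assert ic.passes_isi_qc(st, cfg)

    def test_time_rescaling_gives_exponential_isis(self):
        """KS test of time-rescaled ISIs against Exp(1), 100 seeded runs."""
        bouts = [(10.0, 30.0)]
        dur, base, gain = 60.0, 10.0, 3.0
        passes = 0
        for seed in range(100):
            st = ic.simulate_unit(
                bouts, INCREASED, gain, 0.0, base, dur, np.random.default_rng(seed),
                refractory=0.0,
            )
            # rescale time by the cumulative intensity
            t = st.times
            inside = (t >= 10.0) & (t < 30.0)
            Lambda = base * t + base * (gain - 1) * np.clip(t - 10.0, 0.0, 20.0)
            isis = np.diff(Lambda)
            p = stats.kstest(isis, "expon").pvalue
            passes += p > 0.01
        assert passes >= 95


class TestSimulateEmgAndVibration:
    def test_zero_burst_amp_is_pure_noise(self):
        rng = np.random.default_rng(7)
        sig = ic.simulate_emg([(5.0, 8.0)], np.array([-0.1]), 20.0, rng,
                              noise_sd=0.1, burst_amp=0.0)
        assert np.std(sig.view(5.5, 7.5)) == pytest.approx(0.1, rel=0.1)

    def test_degenerate_delay_distribution(self):
        rng = np.random.default_rng(8)
        delays = np.full(3, -0.125)
        sig = ic.simulate_emg(
            [(5.0, 8.0), (15.0, 18.0), (25.0, 28.0)], delays, 35.0, rng
        )
        assert sig.duration == pytest.approx(35.0)

    def test_zero_noise_gives_perfect_correlation(self, cfg):
        rng = np.random.default_rng(9)
        _, speed_raw, _ = ic.simulate_locomotion(120.0, 8, rng)
        speed = ic.compute_speed(speed_raw, cfg)
        vib, used = ic.simulate_vibration(speed, 0.02, rng, noise_sd=0.0)
        assert used == 0.0
        r = ic.vibration_speed_correlation(vib, speed, cfg, is_envelope=True)
        assert r == pytest.approx(1.0)

    def test_zero_coupling_uncorrelated(self, cfg):
        rng = np.random.default_rng(10)
        _, speed_raw, _ = ic.simulate_locomotion(600.0, 40, rng)
        speed = ic.compute_speed(speed_raw, cfg)
        vib, _ = ic.simulate_vibration(speed, 0.0, rng, noise_sd=0.05)
        assert abs(ic.vibration_speed_correlation(vib, speed, cfg, is_envelope=True)) < 0.05

    @pytest.mark.parametrize("target", [0.2, 0.42, 0.8])
    def test_analytic_noise_calibration(self, cfg, target):
        rng = np.random.default_rng(11)
        _, speed_raw, _ = ic.simulate_locomotion(600.0, 40, rng)
        speed = ic.compute_speed(speed_raw, cfg)
        vib, _ = ic.simulate_vibration(speed, 0.02, rng, target_r=target)
        r = ic.vibration_speed_correlation(vib, speed, cfg, is_envelope=True)
        assert r == pytest.approx(target, abs=0.05)

    def test_invalid_target_r_errors(self, cfg):
        rng = np.random.default_rng(12)
        _, speed_raw, _ = ic.simulate_locomotion(60.0, 3, rng)
        speed = ic.compute_speed(speed_raw, cfg)
        for bad in (0.0, 1.2, -0.3):
            with pytest.raises(ValueError):
                ic.simulate_vibration(speed, 0.02, rng, target_r=bad)


class TestSimulateAudio:
    def test_rate_below_nyquist_of_tone_errors(self):
        with pytest.raises(ValueError):
            ic.simulate_audio(np.array([5.0]), 40.0, 60.0, np.random.default_rng(0), rate=6000.0)

    def test_tone_rms_realized(self):
        rng = np.random.default_rng(13)
        audio, truth = ic.simulate_audio(np.array([5.0, 5.5]), 40.0, 60.0, rng)
        tone = audio.view(*truth.tone_interval)
        # tone RMS dominates background by design
        assert np.sqrt(np.mean(tone**2)) == pytest.approx(0.05, rel=0.02)


class TestPresets:
    def test_largest_remainder_examples(self):
        assert ic.largest_remainder_counts(100, (0.44, 0.22, 0.34)).tolist() == [44, 22, 34]
        assert ic.largest_remainder_counts(3, (1.0, 0.0, 0.0)).tolist() == [3, 0, 0]
        assert ic.largest_remainder_counts(146, (0.44, 0.22, 0.34)).tolist() == [64, 32, 50]

    def test_unknown_preset_lists_available(self):
        with pytest.raises(ValueError, match="deaf_population"):
            ic.build_paper_matched_session("nope", 0)

    def test_composition_realized_in_truth(self):
        bundle = ic.build_paper_matched_session("demo", 5, n_units=100,
                                                fractions=(0.44, 0.22, 0.34))
        dirs = [u.direction for u in bundle.truth.units]
        assert dirs.count(INCREASED) == 44
        assert dirs.count(DECREASED) == 22
        assert dirs.count(NS) == 34
        # invariant: unmodulated units carry unit gain
        for u in bundle.truth.units:
            assert (u.direction == NS) == (u.gain == 1.0)

    def test_same_seed_serializes_byte_identical(self, tmp_path):
        for i, d in enumerate(("a", "b")):
            b = ic.build_paper_matched_session("demo", 99, n_units=4)
            ic.save_session(b, tmp_path / d)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a if f.is_file()] == [
            f.name for f in files_b if f.is_file()
        ]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_signals_share_duration(self):
        bundle = ic.build_paper_matched_session("demo", 2, n_units=2)
        durs = [s.duration for s in bundle.signals.values()]
        assert max(durs) - min(durs) <= 1.0 / 1000.0
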