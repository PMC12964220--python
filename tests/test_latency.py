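"""Onset-triggered averaging, latency estimation, bout-wise typing."""

import numpy as np
import pytest

import icloco as ic
from icloco.errors import EligibilityError
from icloco.latency import OnsetProfile
from icloco.modulation import DECREASED, INCREASED

from conftest import make_signal


def profile_from(t, rate_vals, unit_id="u0", n_onsets=20):
    return OnsetProfile(t=t, rate=np.asarray(rate_vals, float), n_onsets=n_onsets, unit_id=unit_id)


def window_times(hz=1000.0, half=2.0):
    w = int(half * hz)
    return (np.arange(2 * w) - w + 0.5) / hz


class TestOnsetTriggeredAverage:
    def test_homogeneous_poisson_is_flat(self, cfg):
        rng = np.random.default_rng(3)
        lam, dur = 20.0, 300.0
        st = ic.SpikeTrain(np.sort(rng.uniform(0, dur, rng.poisson(lam * dur))), dur)
        onsets = list(np.arange(10.0, 290.0, 9.0))
        prof = ic.onset_triggered_average(st, onsets, cfg)
        se = np.sqrt(lam / (len(onsets) * 0.1))  # per-sample SE at the smoothing scale
        assert abs(prof.rate.mean() - lam) < 3 * np.sqrt(lam / (len(onsets) * 4.0))
        assert prof.rate.std() < 3 * se

    def test_shift_equivariance(self, cfg):
        rng = np.random.default_rng(5)
        st = ic.SpikeTrain(np.sort(rng.uniform(0, 200, 3000)), 200.0)
        trace = ic.firing_rate_trace(st, cfg)
        base = ic.onset_triggered_average(st, list(np.arange(10.0, 180.0, 10.0)), cfg, trace=trace)
        shifted = ic.onset_triggered_average(
            st, list(np.arange(10.1, 180.1, 10.0)), cfg, trace=trace
        )
        assert np.allclose(shifted.rate[:-100], base.rate[100:], atol=1e-9)

    def test_deterministic_step_profile(self, cfg):
        """With a known rate trace, the average is the trace slice itself."""
        hz = 1000.0
        x = np.zeros(int(60 * hz))
        for onset in (10.0, 25.0, 40.0):
            x[int((onset - 0.2) * hz):int((onset + 3.0) * hz)] = 8.0
        trace = make_signal(x, rate=hz, units="Hz")
        dummy = ic.SpikeTrain(np.array([0.5]), 60.0)
        prof = ic.onset_triggered_average(
            dummy, [10.0, 25.0, 40.0], cfg.with_overrides(min_onsets=3), trace=trace
        )
        t = prof.t
        assert np.allclose(prof.rate[t < -0.21], 0.0)
        assert np.allclose(prof.rate[(t > -0.19) & (t < 1.9)], 8.0)

    def test_too_few_onsets_is_ineligible(self, cfg):
        st = ic.SpikeTrain(np.array([1.0, 2.0]), 30.0)
        with pytest.raises(EligibilityError):
            ic.onset_triggered_average(st, [5.0, 10.0], cfg)


class TestEstimateLatency:
    def test_step_recovered_within_tolerance(self, cfg):
        """+5 SD step at -150 ms recovered within the half-kernel tolerance."""
        rng = np.random.default_rng(11)
        t = window_times()
        base, sd = 10.0, 0.8
        rate = base + rng.normal(0, sd, t.size)
        # smooth like the pipeline does, then superpose the smoothed step
        rate = ic.smooth_hanning(make_signal(rate), cfg.rate_smooth_win).samples
        step = np.where(t >= -0.150, 5 * sd * 5, 0.0)
        rate = rate + ic.smooth_hanning(make_signal(step), cfg.rate_smooth_win).samples
        lat = ic.estimate_latency(profile_from(t, rate), INCREASED, cfg)
        assert lat.status == "ok"
        assert abs(lat.latency_ms - (-150.0)) <= 60.0

    def test_flat_profile_has_no_crossing(self, cfg):
        t = window_times()
        lat = ic.estimate_latency(profile_from(t, np.full(t.size, 4.0)), INCREASED, cfg)
        assert lat.status == "no_crossing" and lat.latency_ms is None

    def test_zero_baseline_uses_rate_floor(self, cfg):
        """Silent baseline: the 0.5 Hz floor replaces the 0 Hz mean."""
        t = window_times()
        rate = np.where(t >= 0.05, 3.0, 0.0)
        lat = ic.estimate_latency(profile_from(t, rate), INCREASED, cfg)
        assert lat.baseline_mean == 0.0
        assert lat.latency_ms == pytest.approx(50.0, abs=2.0)
        # a 0.4 Hz step would stay below the floor: no crossing
        lat2 = ic.estimate_latency(
            profile_from(t, np.where(t >= 0.05, 0.4, 0.0)), INCREASED, cfg
        )
        assert lat2.status == "no_crossing"

    def test_decrease_crossing(self, cfg):
        rng = np.random.default_rng(13)
        t = window_times()
        rate = 30.0 + rng.normal(0, 1.0, t.size)
        rate = ic.smooth_hanning(make_signal(rate), cfg.rate_smooth_win).samples
        drop = np.where(t >= -0.09, -28.0, 0.0)
        rate = rate + ic.smooth_hanning(make_signal(drop), cfg.rate_smooth_win).samples
        lat = ic.estimate_latency(profile_from(t, rate), DECREASED, cfg)
        assert abs(lat.latency_ms - (-90.0)) <= 60.0

    def test_pre_onset_noise_blip_ignored(self, cfg):
        """A transient baseline excursion that dies before onset is skipped."""
        t = window_times()
        rate = np.full(t.size, 10.0)
        rate[(t >= -0.8) & (t < -0.65)] = 20.0      # isolated pre-onset blip
        rate[t >= -0.1] = 20.0                       # the real sustained departure
        noise = 0.5 * np.sin(np.arange(t.size))      # gives a nonzero baseline SD
        prof = profile_from(t, rate + noise)
        lat = ic.estimate_latency(prof, INCREASED, cfg)
        assert lat.latency_ms == pytest.approx(-100.0, abs=15.0)

    def test_estimator_spread_shrinks_with_onsets(self, cfg):
        """More onsets -> tighter latency estimates (consistency).

        Robust spread (IQR) is compared: the 1-SD threshold scales with
        the baseline noise, so rare early-merge outliers keep the raw SD
        from shrinking monotonically even as the bulk concentrates.
        """
        spreads = []
        for n_onsets, dur in ((10, 130.0), (40, 480.0)):
            lats = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                bouts = [(10.0 + 11.0 * k, 16.0 + 11.0 * k) for k in range(n_onsets)]
                st = ic.simulate_unit(bouts, INCREASED, 6.0, -0.15, 4.0, dur, rng)
                prof = ic.onset_triggered_average(st, [b[0] for b in bouts], cfg)
                lat = ic.estimate_latency(prof, INCREASED, cfg)
                if lat.latency_ms is not None:
                    lats.append(lat.latency_ms)
            q75, q25 = np.percentile(lats, [75, 25])
            spreads.append(q75 - q25)
        assert spreads[1] < spreads[0]


class TestAdjustReference:
    def test_published_arithmetic(self):
        assert ic.adjust_latency_reference(-205.0, -125.0) == pytest.approx(-80.0)
        assert ic.adjust_latency_reference(-216.0, -125.0) == pytest.approx(-91.0)
        assert ic.adjust_latency_reference(-42.0, 0.0) == pytest.approx(-42.0)

    def test_round_trip_is_identity(self):
        x, d = -137.0, -125.0
        assert ic.adjust_latency_reference(ic.adjust_latency_reference(x, d), -d) == pytest.approx(x)


class TestBoutwise:
    def _trace_with_window(self, baseline, resp, onset=10.0, dur=20.0, hz=1000.0):
        """Trace whose [-1.5,-1.0) window has the given baseline samples
        (cycled) and [0, 0.5) window the given response value."""
        x = np.full(int(dur * hz), float(np.mean(baseline)))
        b0 = int((onset - 1.5) * hz)
        x[b0:b0 + 500] = np.resize(np.asarray(baseline, float), 500)
        r0 = int(onset * hz)
        x[r0:r0 + 500] = resp
        return make_signal(x, rate=hz, units="Hz")

    def test_response_equal_to_baseline_is_ns(self, cfg):
        trace = self._trace_with_window([5.0, 7.0], 6.0)
        st = ic.SpikeTrain(np.array([0.5]), 20.0)
        bm = ic.boutwise_classify(st, 10.0, 0, cfg, trace=trace)
        assert bm.label == "ns" and bm.latency_ms is None

    def test_twenty_percent_rule_when_sd_threshold_negative(self, cfg):
        # baseline mean 1 Hz, SD 2 Hz -> mean-1SD < 0, so 20 % rule applies:
        # response 0.7 < 0.8 -> decrease
        trace = self._trace_with_window([-1.0, 3.0], 0.7)
        st = ic.SpikeTrain(np.array([0.5]), 20.0)
        bm = ic.boutwise_classify(st, 10.0, 0, cfg, trace=trace)
        assert bm.label == "decrease"

    def test_truncated_window_is_skipped(self, cfg):
        st = ic.SpikeTrain(np.array([0.5]), 20.0)
        trace = ic.firing_rate_trace(st, cfg)
        bm = ic.boutwise_classify(st, 1.0, 0, cfg, trace=trace)
        assert bm.status == "skipped"

    def test_high_snr_bouts_match_unit_direction(self, cfg):
        """At high SNR nearly every bout carries the unit's true direction."""
        rng = np.random.default_rng(77)
        sensor, speed_raw, bouts = ic.simulate_locomotion(200.0, 12, rng, min_rest=3.0)
        correct = total = 0
        for seed in range(4):
            st = ic.simulate_unit(
                bouts, INCREASED, 6.0, -0.15, 10.0, 200.0, np.random.default_rng(seed)
            )
            trace = ic.firing_rate_trace(st, cfg)
            for j, (onset, _) in enumerate(bouts):
                bm = ic.boutwise_classify(st, onset, j, cfg, trace=trace)
                if bm.status == "ok":
                    total += 1
                    correct += bm.label == "increase"
        assert correct / total >= 0.90

    def test_increase_bout_latency_uses_two_sd(self, cfg):
        hz = 1000.0
        x = np.full(int(20 * hz), 10.0)
        b0 = int(8.5 * hz)
        x[b0:b0 + 500] = np.resize([9.0, 11.0], 500)   # mean 10, SD 1
        x[int(9.85 * hz):] = 30.0                      # departure at -150 ms
        st = ic.SpikeTrain(np.array([0.5]), 20.0)
        bm = ic.boutwise_classify(st, 10.0, 0, cfg, trace=make_signal(x, units="Hz"))
        assert bm.label == "increase"
        assert bm.latency_ms == pytest.approx(-150.0, abs=5.0)


class TestPopulationCompare:
    def test_identical_groups_midpoint_u(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = ic.latency_population_compare(a, a)
        assert res.statistic == pytest.approx(len(a) * len(a) / 2)

    def test_disjoint_supports_extreme_u(self):
        res = ic.latency_population_compare([1, 2, 3], [10, 11, 12, 13])
        assert res.statistic in (0.0, 12.0)

    def test_separated_medians_detected(self):
        """-216 vs -88 ms groups (n=17/7) separate in most draws."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = rng.normal(-216, 60, 17)
            b = rng.normal(-88, 50, 7)
            if ic.latency_population_compare(a, b).p < 0.05:
                hits += 1
        assert hits >= 40

    def test_paired_shift_recovered(self, cfg):
        """Treadmill- vs EMG-referenced latencies differ by the injected delay."""
        rng = np.random.default_rng(31)
        sensor, speed_raw, bouts = ic.simulate_locomotion(260.0, 16, rng, min_rest=3.0)
        onsets = [b[0] for b in bouts]
        delay = -0.125
        emg_onsets = [t + delay for t in onsets]
        diffs = []
        for seed in range(10):
            st = ic.simulate_unit(
                bouts, INCREASED, 6.0, -0.2, 4.0, 260.0, np.random.default_rng(seed)
            )
            trace = ic.firing_rate_trace(st, cfg)
            lt = ic.estimate_latency(
                ic.onset_triggered_average(st, onsets, cfg, trace=trace), INCREASED, cfg
            )
            le = ic.estimate_latency(
                ic.onset_triggered_average(st, emg_onsets, cfg, trace=trace),
                INCREASED, cfg, reference="emg",
            )
            if lt.latency_ms is not None and le.latency_ms is not None:
                diffs.append(lt.latency_ms - le.latency_ms)
        assert len(diffs) >= 8
        assert np.median(diffs) == pytest.approx(delay * 1000.0, abs=15.0)
        comp = ic.group_compare(
            np.array(diffs) - 0.0, np.zeros(len(diffs)), "paired_t"
        )
        assert comp["p"] < 0.01
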