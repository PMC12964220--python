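"""Reproduction studies: self-contained runs of the full method on
paper-matched synthetic presets.

Each function generates its inputs from a seed, runs the relevant slice
of the pipeline, and returns the headline quantity plus the problem
size.  They are used both by the test suite and by the repository's
acceptance script, and are convenient entry points for exploring how
the estimators behave under known ground truth.
"""

from __future__ import annotations

import numpy as np

from .acoustics import detect_footsteps, measure_calibration_tone, vibration_speed_correlation
from .config import AnalysisConfig
from .emg import delay_distribution, detect_emg_onset, emg_envelope
from .errors import EligibilityError
from .latency import estimate_latency, onset_triggered_average
from .locomotion import compute_speed, detect_treadmill_onsets, label_segments, walking_periods
from .modulation import classify_modulation, population_summary
from .signals import firing_rate_trace, passes_isi_qc
from .synth import (
    SessionBundle,
    build_paper_matched_session,
    simulate_locomotion,
    simulate_unit,
)


def _segmented(bundle: SessionBundle, cfg: AnalysisConfig):
    speed = compute_speed(bundle.signals["speed"], cfg)
    periods = walking_periods(speed, cfg)
    labels = label_segments(speed.duration, periods, cfg)
    onsets = detect_treadmill_onsets(bundle.signals["treadmill_sensor"], cfg)
    return speed, labels, onsets


def population_proportions(seed: int, cfg: AnalysisConfig | None = None) -> dict:
    """Direction composition (%) recovered from the deaf_population preset."""
    cfg = cfg or AnalysisConfig()
    bundle = build_paper_matched_session("deaf_population", seed, cfg)
    speed, labels, _ = _segmented(bundle, cfg)
    results = [
        classify_modulation(st, labels, cfg)
        for st in bundle.units
        if passes_isi_qc(st, cfg)
    ]
    summary = population_summary(results)
    f = summary["fractions"]
    return {
        "pct_increased": 100.0 * f["increased"],
        "pct_decreased": 100.0 * f["decreased"],
        "pct_ns": 100.0 * f["ns"],
        "n_units": summary["n_eligible"],
    }


def latency_median_ms(direction: str, seed: int, cfg: AnalysisConfig | None = None) -> dict:
    """Median onset-aligned latency (ms) over a latency preset population."""
    cfg = cfg or AnalysisConfig()
    preset = {"increased": "latency_deaf_increased", "decreased": "latency_deaf_decreased"}[direction]
    bundle = build_paper_matched_session(preset, seed, cfg)
    speed, labels, onsets = _segmented(bundle, cfg)
    latencies = []
    for st in bundle.units:
        res = classify_modulation(st, labels, cfg)
        if res.status != "ok" or res.direction not in ("increased", "decreased"):
            continue
        try:
            prof = onset_triggered_average(st, onsets, cfg, trace=firing_rate_trace(st, cfg))
        except EligibilityError:
            continue
        lat = estimate_latency(prof, res.direction, cfg)
        if lat.latency_ms is not None:
            latencies.append(lat.latency_ms)
    if not latencies:
        raise RuntimeError("no unit produced a latency estimate")
    return {"median_latency_ms": float(np.median(latencies)), "n_units": len(latencies)}


def emg_delay_median_ms(seed: int, cfg: AnalysisConfig | None = None) -> dict:
    """Median EMG-to-treadmill onset delay (ms) over the emg_delay preset."""
    cfg = cfg or AnalysisConfig()
    bundle = build_paper_matched_session("emg_delay", seed, cfg)
    onsets = detect_treadmill_onsets(bundle.signals["treadmill_sensor"], cfg)
    env = emg_envelope(bundle.signals["emg"], cfg)
    tread = [o.time for o in onsets]
    emg_times = [detect_emg_onset(env, t, cfg) for t in tread]
    dist = delay_distribution([e for e in emg_times if e is not None], tread, cfg)
    return {
        "median_delay_ms": dist.median_delay * 1000.0,
        "n_onsets": int(dist.delays.size),
    }


def footstep_spl_mean_db(seed: int, cfg: AnalysisConfig | None = None) -> dict:
    """Mean detected-footstep SPL (dB) for the footstep_audio preset."""
    cfg = cfg or AnalysisConfig()
    bundle = build_paper_matched_session("footstep_audio", seed, cfg)
    audio = bundle.signals["audio"]
    info = bundle.meta["audio"]
    ref = measure_calibration_tone(audio, tuple(info["tone_interval"]), info["tone_spl_db"])
    events = detect_footsteps(
        audio, [tuple(info["quiet_interval"])], cfg, ref=ref,
        exclude_intervals=[tuple(info["tone_interval"])],
    )
    if not events:
        raise RuntimeError("no footstep events detected")
    return {
        "mean_spl_db": float(np.mean([e.spl_db for e in events])),
        "n_events": len(events),
    }


def vibration_r(seed: int, cfg: AnalysisConfig | None = None) -> dict:
    """Vibration-envelope vs speed Pearson r for the vibration preset."""
    cfg = cfg or AnalysisConfig()
    bundle = build_paper_matched_session("vibration_coupling", seed, cfg)
    speed = compute_speed(bundle.signals["speed"], cfg)
    r = vibration_speed_correlation(bundle.signals["vibration"], speed, cfg, is_envelope=True)
    n_bins = int(speed.duration / cfg.corr_bin)
    return {"r": r, "n_bins": n_bins}


def null_modulated_fraction(
    seed: int,
    n_units: int = 1000,
    duration: float = 300.0,
    cfg: AnalysisConfig | None = None,
) -> dict:
    """Type-I calibration: fraction of unmodulated units flagged at p_mod.

    Simulates ``n_units`` homogeneous Poisson units (gain = 1) on one
    bout-structured session and reports the fraction classified
    increased or decreased -- the empirical false-positive rate of the
    per-unit modulation test, which should sit near its nominal level.
    """
    cfg = cfg or AnalysisConfig()
    ss = np.random.SeedSequence(seed)
    keys = ss.spawn(n_units + 1)
    rng = np.random.default_rng(keys[0])
    sensor, speed_raw, bouts = simulate_locomotion(duration, int(duration / 13), rng)
    speed = compute_speed(speed_raw, cfg)
    labels = label_segments(speed.duration, walking_periods(speed, cfg), cfg)
    n_flagged = n_eligible = 0
    for i in range(n_units):
        rng_u = np.random.default_rng(keys[i + 1])
        base = float(np.clip(np.exp(rng_u.normal(np.log(6.0), 0.8)), 0.5, 30.0))
        st = simulate_unit(bouts, "ns", 1.0, 0.0, base, duration, rng_u, f"n{i:04d}")
        res = classify_modulation(st, labels, cfg)
        if res.status == "ok":
            n_eligible += 1
            if res.direction in ("increased", "decreased"):
                n_flagged += 1
    if n_eligible == 0:
        raise RuntimeError("no eligible null units")
    return {"fraction_flagged": n_flagged / n_eligible, "n_units": n_eligible}
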