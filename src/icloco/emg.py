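"""EMG envelope extraction, onset detection, EMG-to-treadmill delays.

Raw EMG is bandpassed 20-450 Hz, 60-Hz notch filtered, downsampled to
2 kHz, rectified, smoothed with a 100-ms moving average, and normalized
to its maximum (so the envelope lives in [0, 1]).  For each treadmill
onset, the EMG onset is the first envelope sample within +/-0.5 s of the
treadmill onset that exceeds the baseline mean by 2x the baseline SD,
where the baseline is the 0.5-1.0 s window preceding the treadmill
onset and the SD is floored at 0.03 (3 % of the normalized maximum) so
that very quiet baselines do not produce hair-trigger thresholds.
Delays are EMG onset minus treadmill onset; negative values mean muscle
activation precedes detectable treadmill motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .errors import DegenerateInputError
from .signals import ContinuousSignal, moving_average_envelope


@dataclass
class EMGOnsetResult:
    emg_onsets: np.ndarray            # s, matched EMG onsets
    treadmill_onsets: np.ndarray      # s, their paired treadmill onsets
    delays: np.ndarray                # s, emg - treadmill (negative = EMG first)
    median_delay: float               # s
    n_unmatched: int = 0


def emg_envelope(
    emg_raw: ContinuousSignal, cfg: AnalysisConfig | None = None, causal: bool = False
) -> ContinuousSignal:
    """Normalized EMG envelope in [0, 1].

    Bandpass 20-450 Hz (4th-order Butterworth, zero-phase), 60-Hz notch,
    downsample to ``emg_rate`` (2 kHz), rectify, 100-ms moving average,
    divide by the maximum.  Raises on an all-zero signal (normalization
    undefined) and on rates too low for the 450 Hz band edge.
    """
    cfg = cfg or AnalysisConfig()
    x = emg_raw.samples
    if x.size == 0 or np.max(np.abs(x)) == 0:
        raise DegenerateInputError("EMG signal is empty or all zero")
    if emg_raw.rate <= 2 * 450:
        raise ValueError("EMG sample rate too low for the 20-450 Hz band")
    sos = sps.butter(4, [20.0, 450.0], btype="bandpass", fs=emg_raw.rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    b, a = sps.iirnotch(60.0, Q=30.0, fs=emg_raw.rate)
    y = sps.filtfilt(b, a, y)
    target = min(cfg.emg_rate, emg_raw.rate)
    factor_f = emg_raw.rate / target
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9:
        raise ValueError("EMG rate must be an integer multiple of the target rate")
    if factor > 1:
        y = sps.decimate(y, factor, ftype="fir", zero_phase=True)
    env_sig = ContinuousSignal(y, target, units="a.u.", t0=emg_raw.t0)
    env = moving_average_envelope(env_sig, cfg.emg_smooth_win, target, causal=causal)
    peak = env.samples.max()
    if peak <= 0:
        raise DegenerateInputError("EMG envelope is identically zero")
    env.samples = env.samples / peak
    env.units = "norm"
    return env


def detect_emg_onset(
    envelope: ContinuousSignal, treadmill_onset: float, cfg: AnalysisConfig | None = None
) -> float | None:
    """EMG onset time near one treadmill onset, or None when absent.

    Baseline mean/SD come from the ``emg_baseline_win`` window
    ([-1.0, -0.5) s) before the treadmill onset; the effective SD is
    floored at ``emg_min_sd``.  The onset is the first sample within
    +/- ``emg_search_win`` of the treadmill onset whose envelope exceeds
    mean + 2 x SD_eff.  Returns None when the windows are truncated by
    the recording edge or no crossing occurs.
    """
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.emg_baseline_win
    i_b0 = envelope.index_at(treadmill_onset + lo)
    i_b1 = envelope.index_at(treadmill_onset + hi)
    i_s0 = envelope.index_at(treadmill_onset - cfg.emg_search_win)
    i_s1 = envelope.index_at(treadmill_onset + cfg.emg_search_win) + 1
    if i_b0 < 0 or i_s0 < 0 or i_s1 > envelope.n or i_b1 <= i_b0:
        return None  # truncated window
    base = envelope.samples[i_b0:i_b1]
    mu = float(base.mean())
    sd_eff = max(float(base.std()), cfg.emg_min_sd)
    thr = mu + cfg.emg_sd_mult * sd_eff
    above = envelope.samples[i_s0:i_s1] > thr
    hits = np.flatnonzero(above)
    if hits.size == 0:
        return None
    return float(envelope.t0 + (i_s0 + hits[0]) / envelope.rate)


def delay_distribution(
    emg_onsets, treadmill_onsets, cfg: AnalysisConfig | None = None
) -> EMGOnsetResult:
    """Pair EMG onsets with the nearest treadmill onset and report delays.

    Each EMG onset is matched to its nearest treadmill onset within
    +/- ``emg_pair_max_gap`` (0.5 s); each treadmill onset is used at
    most once.  Raises when no pairs match.
    """
    cfg = cfg or AnalysisConfig()
    emg = np.sort(np.asarray([t for t in emg_onsets if t is not None], dtype=float))
    tread = np.sort(np.asarray(treadmill_onsets, dtype=float))
    used = np.zeros(tread.size, dtype=bool)
    pairs: list[tuple[float, float]] = []
    n_unmatched = 0
    for e in emg:
        if tread.size == 0:
            n_unmatched += 1
            continue
        j = int(np.argmin(np.abs(tread - e) + np.where(used, np.inf, 0.0)))
        if not used[j] and abs(tread[j] - e) <= cfg.emg_pair_max_gap:
            used[j] = True
            pairs.append((e, tread[j]))
        else:
            n_unmatched += 1
    if not pairs:
        raise ValueError("no EMG onset could be paired with a treadmill onset")
    e_arr = np.array([p[0] for p in pairs])
    t_arr = np.array([p[1] for p in pairs])
    delays = e_arr - t_arr
    return EMGOnsetResult(
        emg_onsets=e_arr,
        treadmill_onsets=t_arr,
        delays=delays,
        median_delay=float(np.median(delays)),
        n_unmatched=n_unmatched,
    )
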