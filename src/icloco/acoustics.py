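"""Footstep sound detection with SPL calibration; vibration-speed coupling.

Locomotion-generated sounds are quantified against a 4-kHz calibration
tone of known sound pressure level: for any detected event,
SPL = tone_SPL + 20*log10(rms_event / rms_tone).  Footstep events are
found on the analytic-signal (Hilbert) envelope of the 1-50 kHz
bandpassed audio with a threshold of mean + 4*SD of the envelope during
stationary reference periods, a 50-ms refractory interval between
events, and an event extent equal to the supra-threshold span padded by
5 ms on each side (the span over which the event RMS is computed).

Skull-vibration coupling to walking speed is measured as the Pearson
correlation between the vibration envelope and the speed trace after
both are averaged in 100-ms bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .config import AnalysisConfig
from .errors import DegenerateInputError
from .signals import ContinuousSignal, moving_average_envelope


@dataclass
class CalibrationRef:
    tone_rms: float          # linear amplitude of the reference tone
    tone_spl_db: float       # its known SPL in dB
    tone_freq: float = 4000.0

    def __post_init__(self) -> None:
        if not self.tone_rms > 0:
            raise ValueError("tone_rms must be strictly positive")


@dataclass
class FootstepEvent:
    time: float              # s, first supra-threshold sample
    rms: float               # linear amplitude over the event extent
    spl_db: float | None = None
    extent: tuple[float, float] | None = None


def measure_calibration_tone(
    audio: ContinuousSignal, interval: tuple[float, float], tone_spl_db: float,
    tone_freq: float = 4000.0,
) -> CalibrationRef:
    """Build a CalibrationRef from the RMS of the recorded tone segment."""
    seg = audio.view(*interval)
    if seg.size == 0:
        raise DegenerateInputError("calibration interval is empty")
    return CalibrationRef(float(np.sqrt(np.mean(seg ** 2))), tone_spl_db, tone_freq)


def bandpass_audio(audio: ContinuousSignal, lo: float = 1000.0, hi: float = 50000.0) -> ContinuousSignal:
    """1-50 kHz bandpass; falls back to a highpass when Nyquist < hi."""
    nyq = audio.rate / 2.0
    if hi >= 0.95 * nyq:
        sos = sps.butter(4, lo, btype="highpass", fs=audio.rate, output="sos")
    else:
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=audio.rate, output="sos")
    y = sps.sosfiltfilt(sos, audio.samples)
    return ContinuousSignal(y, audio.rate, units=audio.units, t0=audio.t0)


def _analytic_envelope(x: np.ndarray) -> np.ndarray:
    from scipy.fft import next_fast_len

    n = x.size
    return np.abs(sps.hilbert(x, N=next_fast_len(n))[:n])


def detect_footsteps(
    audio: ContinuousSignal,
    stationary_intervals: list[tuple[float, float]],
    cfg: AnalysisConfig | None = None,
    ref: CalibrationRef | None = None,
    exclude_intervals: list[tuple[float, float]] | None = None,
    prefiltered: bool = False,
) -> list[FootstepEvent]:
    """Threshold the analytic envelope to find footstep transients.

    ``stationary_intervals`` provide the quiet reference for the
    threshold -- mean + footstep_threshold_sd * SD of the raw analytic
    envelope there -- raising when absent.  Crossings are evaluated on a
    lightly smoothed envelope (``footstep_env_smooth``, 2 ms): the
    threshold characterizes the noise-floor amplitude, while smoothing
    the detection statistic removes the sub-millisecond Rayleigh tail of
    the noise envelope that would otherwise fire on a megasample
    recording.  Supra-threshold runs separated by less than
    ``footstep_refractory`` (50 ms) merge into one event, and an event's
    merged span must last at least ``footstep_min_dur`` (5 ms).  The
    event extent is the supra-threshold span padded by ``footstep_pad``
    (5 ms) per side, and the event RMS is computed over that extent of
    the bandpassed waveform.  Events overlapping ``exclude_intervals``
    (e.g. the calibration tone) are dropped.  When ``ref`` is given,
    each event's SPL is attached.
    """
    cfg = cfg or AnalysisConfig()
    if not stationary_intervals:
        raise ValueError("a stationary reference interval is required for the threshold")
    band = audio if prefiltered else bandpass_audio(audio)
    env = _analytic_envelope(band.samples)
    ref_mask = np.zeros(band.n, dtype=bool)
    for a, b in stationary_intervals:
        ref_mask[max(band.index_at(a), 0):min(band.index_at(b), band.n)] = True
    if not ref_mask.any():
        raise ValueError("stationary reference intervals lie outside the recording")
    mu, sd = float(env[ref_mask].mean()), float(env[ref_mask].std())
    if sd == 0:
        return []
    thr = mu + cfg.footstep_threshold_sd * sd
    smooth_n = int(round(cfg.footstep_env_smooth * band.rate))
    if smooth_n > 1:
        from scipy import ndimage

        env = ndimage.uniform_filter1d(env, size=smooth_n, mode="reflect")
    supra = env > thr
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return []
    refractory_n = int(round(cfg.footstep_refractory * band.rate))
    pad_n = int(round(cfg.footstep_pad * band.rate))
    min_dur_n = int(round(cfg.footstep_min_dur * band.rate))
    # group supra-threshold samples separated by < refractory into events
    breaks = np.flatnonzero(np.diff(idx) >= refractory_n) + 1
    groups = np.split(idx, breaks)
    events: list[FootstepEvent] = []
    for g in groups:
        a, b = int(g[0]), int(g[-1])
        if b - a + 1 < min_dur_n:
            continue  # too brief to be a footstep
        e0, e1 = max(a - pad_n, 0), min(b + pad_n + 1, band.n)
        t_start = band.t0 + a / band.rate
        t_ext = (band.t0 + e0 / band.rate, band.t0 + e1 / band.rate)
        if exclude_intervals and any(
            t_ext[0] < hi and t_ext[1] > lo for lo, hi in exclude_intervals
        ):
            continue
        rms = float(np.sqrt(np.mean(band.samples[e0:e1] ** 2)))
        spl = event_spl(rms, ref) if ref is not None else None
        events.append(FootstepEvent(time=t_start, rms=rms, spl_db=spl, extent=t_ext))
    return events


def event_spl(rms: float, ref: CalibrationRef) -> float:
    """Convert an event RMS amplitude to dB SPL against the calibration tone."""
    if not rms > 0:
        raise ValueError("event rms must be strictly positive")
    return float(ref.tone_spl_db + 20.0 * np.log10(rms / ref.tone_rms))


def vibration_speed_correlation(
    vibration: ContinuousSignal,
    speed: ContinuousSignal,
    cfg: AnalysisConfig | None = None,
    is_envelope: bool = False,
) -> float:
    """Pearson r between the vibration envelope and walking speed (100-ms bins).

    For a raw sensor signal the envelope is extracted first (60-Hz
    notch, rectification, 200-ms moving average at 1 kHz); pass
    ``is_envelope=True`` for a signal that is already an envelope.
    Both series are averaged in ``corr_bin`` (100 ms) bins anchored at
    t = 0 before correlating; fewer than 20 common bins is an error.
    """
    cfg = cfg or AnalysisConfig()
    if is_envelope:
        env = vibration
    else:
        b, a = sps.iirnotch(60.0, Q=30.0, fs=vibration.rate)
        notched = ContinuousSignal(
            sps.filtfilt(b, a, vibration.samples), vibration.rate,
            units=vibration.units, t0=vibration.t0,
        )
        out_rate = min(1000.0, vibration.rate)
        env = moving_average_envelope(notched, cfg.vib_smooth_win, out_rate)
    ve = _bin_mean(env, cfg.corr_bin)
    sp = _bin_mean(speed, cfg.corr_bin)
    n = min(ve.size, sp.size)
    if n < 20:
        raise ValueError("need at least 20 common 100-ms bins for a correlation")
    return float(stats.pearsonr(ve[:n], sp[:n]).statistic)


def _bin_mean(x: ContinuousSignal, bin_s: float) -> np.ndarray:
    per = int(round(bin_s * x.rate))
    if per < 1:
        raise ValueError("bin shorter than one sample")
    n = (x.n // per) * per
    return x.samples[:n].reshape(-1, per).mean(axis=1)


def band_psd(
    audio: ContinuousSignal,
    intervals: list[tuple[float, float]],
    cfg: AnalysisConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density averaged over labeled intervals.

    Each interval contributes a Welch periodogram (segment length
    ``psd_nperseg`` capped at the interval length, 50 % overlap); the
    returned PSD is the duration-weighted average.
    """
    cfg = cfg or AnalysisConfig()
    psds, weights, freqs = [], [], None
    for a, b in intervals:
        seg = audio.view(a, b)
        if seg.size < 16:
            continue
        nper = min(cfg.psd_nperseg, seg.size)
        f, p = sps.welch(seg, fs=audio.rate, nperseg=nper, noverlap=nper // 2)
        if freqs is None or f.size > freqs.size:
            # keep the finest frequency grid; interpolate coarser ones onto it
            freqs = f
        psds.append((f, p))
        weights.append(seg.size)
    if not psds:
        raise DegenerateInputError("no interval long enough for a PSD estimate")
    acc = np.zeros_like(freqs)
    for (f, p), w in zip(psds, weights):
        acc += w * np.interp(freqs, f, p)
    return freqs, acc / sum(weights)
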