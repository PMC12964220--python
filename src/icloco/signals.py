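"""Signal containers and the smoothing/envelope primitives used everywhere.

A :class:`ContinuousSignal` is a uniformly sampled trace (treadmill
sensor, walking speed, EMG, skull vibration, audio) with a sample rate,
units, and a session-relative start time.  A :class:`SpikeTrain` holds
the sorted spike times of one unit.  The primitives here are the shared
building blocks of the analysis:

* :func:`smooth_hanning` -- zero-phase convolution with a unit-area
  Hanning window (used for speed traces and firing-rate traces),
* :func:`moving_average_envelope` -- rectify, boxcar-average, decimate
  (used for EMG and skull-vibration envelopes),
* :func:`firing_rate_trace` -- 1-kHz binned, Hanning-smoothed rate in Hz,
* :func:`isi_violation_rate` -- refractory-violation unit QC.

Smoothing is zero-phase by default (symmetric kernels, reflect padding);
each primitive also exposes a causal variant for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import windows

from .config import AnalysisConfig
from .errors import DegenerateInputError


@dataclass
class ContinuousSignal:
    """A uniformly sampled real-valued trace.

    Parameters
    ----------
    samples : array-like of float
        The trace. Must be finite.
    rate : float
        Sampling rate in samples/s. Strictly positive.
    units : str
        Free-text units ("cm/s", "V", "Hz", "a.u.", ...).
    t0 : float
        Session-relative time of the first sample, in seconds.
    """

    samples: np.ndarray
    rate: float
    units: str = "a.u."
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.rate > 0:
            raise ValueError("rate must be strictly positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n_samples / rate)."""
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    def index_at(self, t: float) -> int:
        """Index of the sample whose bin [k/rate, (k+1)/rate) contains t."""
        return int(np.floor((t - self.t0) * self.rate + 1e-9))

    def view(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples covering [t_start, t_end) (half-open, session-relative)."""
        i0 = max(self.index_at(t_start), 0)
        i1 = min(self.index_at(t_end), self.n)
        return self.samples[i0:i1]


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one unit over a session of known duration."""

    times: np.ndarray
    duration: float
    unit_id: str = "u0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if not self.duration > 0:
            raise ValueError("duration must be strictly positive")
        if self.times.size:
            if np.any(np.diff(self.times) < 0):
                raise ValueError("spike times must be nondecreasing")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def mean_rate(self) -> float:
        return self.times.size / self.duration


def _hann_kernel(n: int) -> np.ndarray:
    """Unit-area symmetric Hanning kernel of odd length >= n."""
    if n % 2 == 0:
        n += 1  # odd length keeps the kernel centered (exact affine preservation)
    k = windows.hann(n, sym=True)
    s = k.sum()
    if s <= 0:  # n <= 2 degenerates to an identity kernel
        k = np.zeros(max(n, 1))
        k[k.size // 2] = 1.0
        return k
    return k / s


def smooth_hanning(x: ContinuousSignal, win: float, causal: bool = False) -> ContinuousSignal:
    """Convolve with a unit-area Hanning window of duration ``win`` seconds.

    Zero-phase by default (reflect padding, symmetric odd-length kernel),
    so constants and -- away from the edges -- affine trends are preserved
    exactly.  With ``causal=True`` the same kernel is applied trailing,
    delaying features by about half the window.
    """
    n = int(round(win * x.rate))
    if n < 2:
        raise DegenerateInputError("window must span at least 2 samples (win >= 2/rate)")
    k = _hann_kernel(n)
    if k.size > x.samples.size:
        raise DegenerateInputError(
            f"window ({k.size} samples) is longer than the signal ({x.samples.size})"
        )
    if causal:
        pad = np.concatenate([x.samples[k.size - 1:0:-1], x.samples])
        y = np.convolve(pad, k, mode="valid")
    else:
        y = ndimage.convolve1d(x.samples, k, mode="reflect")
    return ContinuousSignal(y, x.rate, units=x.units, t0=x.t0)


def moving_average_envelope(
    x: ContinuousSignal, win: float, out_rate: float, causal: bool = False
) -> ContinuousSignal:
    """Rectified, boxcar-averaged envelope, decimated by bin-mean binning.

    The signal is rectified (|x|), averaged with a moving window of
    ``win`` seconds, then decimated to ``out_rate`` by averaging
    consecutive blocks of rate/out_rate samples (an integer factor is
    required; bin-mean decimation is robust against aliasing of the
    already-smoothed envelope).
    """
    if out_rate > x.rate:
        raise ValueError("out_rate must not exceed the input rate")
    if x.samples.size == 0:
        raise DegenerateInputError("empty signal")
    w = max(int(round(win * x.rate)), 1)
    if w > x.samples.size:
        raise DegenerateInputError("window is longer than the signal")
    rect = np.abs(x.samples)
    origin = -((w - 1) // 2) if causal else 0
    env = ndimage.uniform_filter1d(rect, size=w, mode="reflect", origin=origin)
    factor_f = x.rate / out_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9:
        raise ValueError("rate / out_rate must be an integer decimation factor")
    if factor > 1:
        n_keep = (env.size // factor) * factor
        env = env[:n_keep].reshape(-1, factor).mean(axis=1)
    return ContinuousSignal(env, out_rate, units=x.units, t0=x.t0)


def firing_rate_trace(
    st: SpikeTrain, cfg: AnalysisConfig | None = None, causal: bool = False
) -> ContinuousSignal:
    """Smoothed firing-rate trace in Hz.

    Spikes are counted in 1/rate_trace_hz bins (1 kHz by default),
    scaled to Hz, and smoothed with a unit-area Hanning window of
    ``rate_smooth_win`` (100 ms).  Reflect padding conserves the total
    spike count, so the trace integrates to the number of spikes.
    An empty train yields an all-zero trace.
    """
    cfg = cfg or AnalysisConfig()
    hz = cfg.rate_trace_hz
    n_bins = int(round(st.duration * hz))
    if n_bins < 1:
        raise DegenerateInputError("session shorter than one rate-trace bin")
    counts = np.zeros(n_bins)
    if st.times.size:
        idx = np.minimum((st.times * hz).astype(np.int64), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    raw = ContinuousSignal(counts * hz, hz, units="Hz")
    if st.times.size == 0:
        return raw
    return smooth_hanning(raw, cfg.rate_smooth_win, causal=causal)


def isi_violation_rate(st: SpikeTrain, cfg: AnalysisConfig | None = None) -> float:
    """Fraction of inter-spike intervals strictly below the refractory period."""
    cfg = cfg or AnalysisConfig()
    if st.times.size < 2:
        raise DegenerateInputError("ISI violation rate undefined for < 2 spikes")
    isis = np.diff(st.times)
    return float(np.mean(isis < cfg.isi_refractory))


def passes_isi_qc(st: SpikeTrain, cfg: AnalysisConfig | None = None) -> bool:
    """Single-unit QC: violation rate strictly below ``max_isi_violation``."""
    cfg = cfg or AnalysisConfig()
    return isi_violation_rate(st, cfg) < cfg.max_isi_violation
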