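"""Walking-speed derivation, walking periods, 1-s segment labels, onsets.

Walking periods are maximal stretches with speed strictly above
2 cm/s, with sub-threshold breaks shorter than 200 ms absorbed.  The
session is tiled with half-open 1-s segments from t = 0; each segment is
stationary (zero overlap with any walking period), walking (entirely
inside one), or partial.  Locomotion onsets are detected on the raw
treadmill sensor rather than the smoothed speed: an onset is the first
sample deviating by more than 5 % of the session's sensor dynamic range
from the local stationary baseline (trailing 0.5-s median), after at
least 0.5 s within that band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .signals import ContinuousSignal, smooth_hanning

STATIONARY = "stationary"
WALKING = "walking"
PARTIAL = "partial"

_EPS = 1e-9


@dataclass(frozen=True)
class WalkPeriod:
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentLabel:
    index: int
    start: float
    label: str  # stationary | walking | partial


@dataclass(frozen=True)
class LocomotionOnset:
    time: float
    pre_stationary: float  # seconds of stillness preceding the onset


def compute_speed(
    treadmill: ContinuousSignal,
    cfg: AnalysisConfig | None = None,
    calibration: float | None = None,
) -> ContinuousSignal:
    """Walking speed in cm/s: calibrate, Hanning-smooth (200 ms), clip at 0.

    ``treadmill`` must either already be in cm/s (units == "cm/s") or a
    linear ``calibration`` factor (cm/s per sensor unit) must be given.
    """
    cfg = cfg or AnalysisConfig()
    if calibration is not None:
        samples = treadmill.samples * calibration
    elif treadmill.units == "cm/s":
        samples = treadmill.samples
    else:
        raise ValueError(
            "treadmill signal is not calibrated to cm/s; pass a calibration factor"
        )
    raw = ContinuousSignal(samples, treadmill.rate, units="cm/s", t0=treadmill.t0)
    smoothed = smooth_hanning(raw, cfg.speed_smooth_win)
    # optical sensors can jitter negative after smoothing
    smoothed.samples = np.clip(smoothed.samples, 0.0, None)
    return smoothed


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of True runs; stop is exclusive."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[0], mask.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def walking_periods(speed: ContinuousSignal, cfg: AnalysisConfig | None = None) -> list[WalkPeriod]:
    """Maximal intervals with speed strictly > threshold, short breaks merged.

    A sub-threshold gap strictly shorter than ``min_break`` (200 ms)
    between two supra-threshold stretches is absorbed into a single
    walking period.
    """
    cfg = cfg or AnalysisConfig()
    mask = speed.samples > cfg.speed_threshold
    raw = _runs(mask)
    if not raw:
        return []
    merged: list[list[int]] = [list(raw[0])]
    for start, stop in raw[1:]:
        gap = (start - merged[-1][1]) / speed.rate
        if gap < cfg.min_break - _EPS:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return [
        WalkPeriod(speed.t0 + a / speed.rate, speed.t0 + b / speed.rate)
        for a, b in merged
    ]


def label_segments(
    duration: float,
    periods: list[WalkPeriod],
    cfg: AnalysisConfig | None = None,
) -> list[SegmentLabel]:
    """Label consecutive half-open 1-s segments [k, k+1) from t = 0.

    walking: the segment lies entirely inside one walking period;
    stationary: zero overlap with every period; otherwise partial.
    A trailing remainder shorter than one segment is discarded.
    """
    cfg = cfg or AnalysisConfig()
    L = cfg.segment_len
    n_seg = int(np.floor(duration / L + _EPS))
    if n_seg < 1:
        raise ValueError("duration must cover at least one segment")
    starts = np.array([p.start for p in periods])
    ends = np.array([p.end for p in periods])
    labels = []
    for k in range(n_seg):
        s, e = k * L, (k + 1) * L
        if periods.__len__():
            inside = np.any((starts <= s + _EPS) & (ends >= e - _EPS))
            overlap = np.any((np.minimum(ends, e) - np.maximum(starts, s)) > _EPS)
        else:
            inside = overlap = False
        if inside:
            lab = WALKING
        elif overlap:
            lab = PARTIAL
        else:
            lab = STATIONARY
        labels.append(SegmentLabel(k, s, lab))
    return labels


def detect_treadmill_onsets(
    sensor: ContinuousSignal, cfg: AnalysisConfig | None = None
) -> list[LocomotionOnset]:
    """Locomotion onsets from the raw treadmill sensor.

    A sample is "moving" when it deviates from the stationary baseline
    (median of the trailing 0.5-s window) by more than
    ``onset_sensor_change`` (5 %) of the session's sensor dynamic range
    (max - min).  An onset is a stationary-to-moving transition preceded
    by at least ``onset_pre_stationary`` seconds within the band, and
    whose baseline sits at the session's resting level (10th percentile
    of the sensor) -- a steady plateau is locally constant but is not
    rest, so ramp-downs and mid-bout speed changes do not count as
    onsets.  The time spent within the band is reported as
    ``pre_stationary``.  A flat signal yields no onsets.
    """
    cfg = cfg or AnalysisConfig()
    s = sensor.samples
    if s.size < 2:
        return []
    dyn_range = float(s.max() - s.min())
    if dyn_range <= 0:
        return []
    thr = cfg.onset_sensor_change * dyn_range
    w = max(int(round(cfg.onset_pre_stationary * sensor.rate)), 1)
    baseline = (
        pd.Series(s).rolling(w, min_periods=1).median().shift(1).to_numpy()
    )
    baseline[0] = s[0]
    moving = np.abs(s - baseline) > thr
    rest_level = float(np.percentile(s, 10))
    rising = np.flatnonzero(moving[1:] & ~moving[:-1]) + 1
    # index of the most recent moving sample at or before each position
    last_moving = np.where(moving, np.arange(s.size), -1)
    last_moving = np.maximum.accumulate(last_moving)
    half_sample = 0.5 / sensor.rate
    onsets: list[LocomotionOnset] = []
    for i in rising:
        if abs(baseline[i] - rest_level) > thr:
            continue  # locally steady but not at rest (e.g. a bout plateau)
        prev = last_moving[i - 1]
        pre = (i - prev - 1) / sensor.rate if prev >= 0 else i / sensor.rate
        if pre + half_sample >= cfg.onset_pre_stationary:
            onsets.append(LocomotionOnset(sensor.t0 + i / sensor.rate, float(pre)))
    return onsets
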