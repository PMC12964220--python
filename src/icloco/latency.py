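"""Onset-aligned modulation latency and bout-wise modulation typing.

The population-level latency of a unit is estimated from its
onset-triggered average: the 100-ms-smoothed firing-rate trace is cut to
a +/-2 s window around each qualified locomotion onset and averaged
pointwise at 1 kHz.  Baseline mean and SD come from the 500 samples in
[-1.5, -1.0) s before the onset; latency is the first time in
(-1.0, +2.0] s at which the profile departs from baseline by more than
1 SD (above for increased units, below for decreased units), where the
departure must be sustained for at least one smoothing window and --
because locomotion-related modulation persists through the bout -- must
still be in effect at the movement onset itself.  The estimator is thus
the start of the threshold departure that the locomotion response
belongs to; brief pre-onset excursions of the baseline that die out
before movement begins do not count.  For increased units with a
baseline mean below 0.5 Hz, the baseline mean is replaced by the 0.5 Hz
floor before thresholding.  Negative latencies mean the modulation
precedes the reference onset.

The bout-wise path applies related rules to single bouts: a bout is an
"increase" when the mean rate in the 0 to +0.5 s response window
exceeds that bout's baseline mean by more than 1 SD, a "decrease" when
it falls more than 1 SD below it (or below 80 % of the mean when the
1-SD threshold would be negative), otherwise "ns".  Per-bout latencies
use a 2-SD crossing for increases and the first drop below mean - 1 SD
or below 0.5 Hz -- whichever happens first -- for decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .errors import EligibilityError
from .locomotion import LocomotionOnset
from .modulation import DECREASED, INCREASED
from .signals import ContinuousSignal, SpikeTrain, firing_rate_trace


@dataclass
class OnsetProfile:
    """Onset-triggered mean firing-rate profile of one unit."""

    t: np.ndarray          # s relative to onset (bin centers)
    rate: np.ndarray       # Hz
    n_onsets: int
    unit_id: str = "u0"


@dataclass
class LatencyResult:
    unit_id: str
    latency_ms: float | None   # negative = precedes the reference onset
    direction: str
    baseline_mean: float       # Hz (before any floor substitution)
    baseline_sd: float         # Hz
    n_onsets: int
    reference: str = "treadmill"   # treadmill | emg
    status: str = "ok"             # ok | no_crossing


@dataclass
class BoutModulation:
    unit_id: str
    onset_index: int
    label: str                  # increase | decrease | ns | skipped
    latency_ms: float | None = None
    status: str = "ok"          # ok | skipped


def _onset_times(onsets) -> list[float]:
    return [o.time if isinstance(o, LocomotionOnset) else float(o) for o in onsets]


def onset_triggered_average(
    st: SpikeTrain,
    onsets,
    cfg: AnalysisConfig | None = None,
    trace: ContinuousSignal | None = None,
) -> OnsetProfile:
    """Average the smoothed rate trace across onsets in a +/- bout_win window.

    ``onsets`` may be LocomotionOnset objects or plain times (s).  Onsets
    whose window does not fit inside the session are dropped; fewer than
    ``min_onsets`` remaining raises :class:`EligibilityError`.  Passing a
    precomputed ``trace`` (from :func:`firing_rate_trace`) avoids
    recomputing it per call.
    """
    cfg = cfg or AnalysisConfig()
    if trace is None:
        trace = firing_rate_trace(st, cfg)
    hz = trace.rate
    w = int(round(cfg.bout_win * hz))
    slices = []
    for t_on in _onset_times(onsets):
        i0 = int(round(t_on * hz)) - w
        if i0 < 0 or i0 + 2 * w > trace.n:
            continue
        slices.append(trace.samples[i0:i0 + 2 * w])
    if len(slices) < cfg.min_onsets:
        raise EligibilityError(
            f"unit {st.unit_id}: {len(slices)} qualified onsets < min_onsets={cfg.min_onsets}"
        )
    mean = np.mean(slices, axis=0)
    t = (np.arange(2 * w) - w + 0.5) / hz
    return OnsetProfile(t=t, rate=mean, n_onsets=len(slices), unit_id=st.unit_id)


def _first_sustained(mask: np.ndarray, hold_n: int, anchor: int | None = None) -> int | None:
    """Start index of the first qualifying True run, else None.

    A run qualifies when it lasts at least ``hold_n`` samples and --
    when ``anchor`` is given -- extends to or beyond the anchor index.
    The anchor (the movement onset) encodes that a modulation departure
    beginning before the onset must still be in effect at the onset;
    isolated pre-onset noise excursions that die out again do not
    qualify, so the returned crossing is the start of the departure the
    response itself belongs to.
    """
    padded = np.concatenate([[0], mask.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    for a, b in zip(starts, stops):
        if b - a >= hold_n and (anchor is None or b > anchor):
            return int(a)
    return None


def estimate_latency(
    profile: OnsetProfile,
    direction: str,
    cfg: AnalysisConfig | None = None,
    reference: str = "treadmill",
) -> LatencyResult:
    """First sustained 1-SD departure of the averaged profile from baseline."""
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.baseline_win
    base_mask = (profile.t >= lo) & (profile.t < hi)
    if not base_mask.any():
        raise ValueError("profile does not cover the baseline window")
    base = profile.rate[base_mask]
    mu, sd = float(base.mean()), float(base.std())
    search = (profile.t > hi) & (profile.t <= cfg.latency_search_end)
    t_search = profile.t[search]
    r_search = profile.rate[search]
    if direction == INCREASED:
        center = mu if mu >= cfg.baseline_rate_floor else cfg.baseline_rate_floor
        crossing = r_search > center + cfg.latency_sd_mult * sd
    elif direction == DECREASED:
        crossing = r_search < mu - cfg.latency_sd_mult * sd
    else:
        raise ValueError(f"direction must be increased or decreased, got {direction!r}")
    hold_n = max(int(round(cfg.latency_min_hold * cfg.rate_trace_hz)), 1)
    anchor = int(np.searchsorted(t_search, 0.0))
    start = _first_sustained(crossing, hold_n, anchor)
    latency_ms = None if start is None else float(t_search[start] * 1000.0)
    return LatencyResult(
        unit_id=profile.unit_id,
        latency_ms=latency_ms,
        direction=direction,
        baseline_mean=mu,
        baseline_sd=sd,
        n_onsets=profile.n_onsets,
        reference=reference,
        status="ok" if start is not None else "no_crossing",
    )


def adjust_latency_reference(latency_treadmill_ms: float, median_emg_delay_ms: float) -> float:
    """Re-express a treadmill-referenced latency relative to EMG onset.

    latency_emg = latency_treadmill - median_emg_delay.  With the
    typical negative EMG-treadmill delay (muscle activation precedes
    treadmill motion) latencies shift toward more positive values.
    """
    return latency_treadmill_ms - median_emg_delay_ms


def boutwise_classify(
    st: SpikeTrain,
    onset,
    onset_index: int = 0,
    cfg: AnalysisConfig | None = None,
    trace: ContinuousSignal | None = None,
) -> BoutModulation:
    """Classify a single locomotion bout as increase / decrease / ns.

    Uses the bout's own baseline ([-1.5, -1.0) s before its onset) and
    the 0 to +0.5 s response window of the smoothed rate trace, with the
    20 %-decrease fallback when the 1-SD decrease threshold is negative.
    A bout whose +/-2 s window is truncated by the session edge is
    skipped with an explicit status.
    """
    cfg = cfg or AnalysisConfig()
    if trace is None:
        trace = firing_rate_trace(st, cfg)
    hz = trace.rate
    t_on = onset.time if isinstance(onset, LocomotionOnset) else float(onset)
    w = int(round(cfg.bout_win * hz))
    i0 = int(round(t_on * hz)) - w
    if i0 < 0 or i0 + 2 * w > trace.n:
        return BoutModulation(st.unit_id, onset_index, "skipped", status="skipped")
    seg = trace.samples[i0:i0 + 2 * w]
    t = (np.arange(2 * w) - w + 0.5) / hz
    lo, hi = cfg.baseline_win
    base = seg[(t >= lo) & (t < hi)]
    mu, sd = float(base.mean()), float(base.std())
    r_lo, r_hi = cfg.bout_resp_win
    resp = float(seg[(t >= r_lo) & (t < r_hi)].mean())
    dec_threshold = mu - sd
    if dec_threshold < 0:
        dec_threshold = (1.0 - cfg.bout_dec_frac) * mu  # 20 % decrease fallback
    if resp > mu + sd:
        label = "increase"
    elif resp < dec_threshold:
        label = "decrease"
    else:
        return BoutModulation(st.unit_id, onset_index, "ns")
    search = (t > hi) & (t <= cfg.latency_search_end)
    hold_n = max(int(round(cfg.latency_min_hold * hz)), 1)
    if label == "increase":
        crossing = seg[search] > mu + cfg.bout_inc_lat_sd * sd
    else:
        # first drop below mean - 1 SD or below the 0.5 Hz floor, whichever first
        thr = max(mu - cfg.latency_sd_mult * sd, cfg.bout_dec_rate_floor)
        crossing = seg[search] < thr
    anchor = int(np.searchsorted(t[search], 0.0))
    start = _first_sustained(crossing, hold_n, anchor)
    latency = None if start is None else float(t[search][start] * 1000.0)
    return BoutModulation(st.unit_id, onset_index, label, latency_ms=latency)


@dataclass
class RankSumComparison:
    statistic: float
    p: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def latency_population_compare(a, b) -> RankSumComparison:
    """Two-sided Mann-Whitney U comparison of two latency samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RankSumComparison(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=int(a.size),
        n_b=int(b.size),
    )
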