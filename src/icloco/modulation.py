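"""Per-unit locomotion modulation classification and speed-rate correlation.

Each unit's spike counts in labeled 1-s segments are compared between
walking and stationary segments with a two-sample t test (Welch by
default; segment counts are typically unbalanced).  A unit is
"increased" or "decreased" when p < 0.01 with the corresponding sign of
the mean difference, "ns" otherwise.  Units with fewer than 4 walking
segments (or fewer than 2 stationary segments) are ineligible and are
reported as such, never silently folded into "ns", so population
denominators stay explicit.  The speed-rate correlation is the Pearson
correlation between per-segment mean speed and per-segment firing rate
over the included (stationary + walking) segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .locomotion import SegmentLabel, STATIONARY, WALKING
from .signals import ContinuousSignal, SpikeTrain

INCREASED = "increased"
DECREASED = "decreased"
NS = "ns"


@dataclass
class ModulationResult:
    unit_id: str
    status: str                      # "ok" | "ineligible"
    rate_stationary: float = np.nan  # Hz, mean over stationary segments
    rate_walking: float = np.nan     # Hz, mean over walking segments
    t_stat: float = np.nan
    df: float = np.nan
    p: float = np.nan
    direction: str | None = None     # increased | decreased | ns (None if ineligible)
    r_speed: float = np.nan          # Pearson r vs per-segment speed
    r_speed_reason: str | None = None
    n_walk_segments: int = 0
    n_stat_segments: int = 0


def segment_rates(
    st: SpikeTrain, labels: list[SegmentLabel], cfg: AnalysisConfig | None = None
) -> dict[str, np.ndarray]:
    """Per-segment firing rates (Hz) grouped by label.

    Returns a dict with keys "walking", "stationary" (rates) and
    "walking_idx", "stationary_idx" (segment indices).  Partial segments
    are excluded, as is any trailing remainder not covered by a label.
    """
    cfg = cfg or AnalysisConfig()
    L = cfg.segment_len
    n_seg = len(labels)
    counts = np.zeros(n_seg)
    if st.times.size:
        idx = np.floor(st.times / L + 1e-9).astype(np.int64)
        idx = idx[idx < n_seg]
        counts = np.bincount(idx, minlength=n_seg).astype(np.float64)
    rates = counts / L
    out: dict[str, np.ndarray] = {}
    for key in (WALKING, STATIONARY):
        sel = np.array([lab.index for lab in labels if lab.label == key], dtype=np.int64)
        out[key] = rates[sel] if sel.size else np.array([])
        out[key + "_idx"] = sel
    return out


def classify_modulation(
    st: SpikeTrain,
    labels: list[SegmentLabel],
    cfg: AnalysisConfig | None = None,
    speed: ContinuousSignal | None = None,
    equal_var: bool = False,
) -> ModulationResult:
    """Classify a unit's locomotion modulation from labeled 1-s segments.

    Welch's unequal-variance t test by default (``equal_var=True``
    recovers the pooled-variance Student version).  If both segment
    groups are constant the t statistic is undefined; equal means then
    count as "ns", distinct constant means as a zero-variance extreme.
    """
    cfg = cfg or AnalysisConfig()
    rates = segment_rates(st, labels, cfg)
    walk, stat = rates[WALKING], rates[STATIONARY]
    res = ModulationResult(
        unit_id=st.unit_id,
        status="ok",
        n_walk_segments=int(walk.size),
        n_stat_segments=int(stat.size),
    )
    if walk.size < cfg.min_walk_segments or stat.size < cfg.min_stationary_segments:
        res.status = "ineligible"
        return res
    res.rate_walking = float(walk.mean())
    res.rate_stationary = float(stat.mean())
    with warnings.catch_warnings():
        # constant segment groups trigger a precision warning; the NaN
        # outcome is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(walk, stat, equal_var=equal_var)
    res.t_stat, res.p = float(t.statistic), float(t.pvalue)
    res.df = float(getattr(t, "df", walk.size + stat.size - 2))
    if not np.isfinite(res.p):  # both groups constant
        equal = np.isclose(res.rate_walking, res.rate_stationary)
        res.p = 1.0 if equal else 0.0
        res.t_stat = 0.0 if equal else np.inf * np.sign(res.rate_walking - res.rate_stationary)
    diff = res.rate_walking - res.rate_stationary
    if res.p < cfg.p_mod and diff > 0:
        res.direction = INCREASED
    elif res.p < cfg.p_mod and diff < 0:
        res.direction = DECREASED
    else:
        res.direction = NS
    if speed is not None:
        r, reason = speed_rate_correlation(st, speed, labels, cfg)
        res.r_speed = np.nan if r is None else r
        res.r_speed_reason = reason
    return res


def speed_rate_correlation(
    st: SpikeTrain,
    speed: ContinuousSignal,
    labels: list[SegmentLabel],
    cfg: AnalysisConfig | None = None,
) -> tuple[float | None, str | None]:
    """Pearson r between per-segment mean speed and firing rate.

    Computed over stationary + walking segments (partial segments are
    excluded).  Returns (r, None), or (None, reason) when fewer than
    ``min_walk_segments + 1`` segments are included or either variable
    has zero variance.
    """
    cfg = cfg or AnalysisConfig()
    rates = segment_rates(st, labels, cfg)
    idx = np.concatenate([rates["walking_idx"], rates["stationary_idx"]])
    if idx.size < cfg.min_walk_segments + 1:
        return None, "too few included segments"
    vals = np.concatenate([rates[WALKING], rates[STATIONARY]])
    L = cfg.segment_len
    seg_speed = np.array(
        [speed.view(k * L, (k + 1) * L).mean() for k in idx]
    )
    if np.std(vals) == 0 or np.std(seg_speed) == 0:
        return None, "zero variance"
    r = stats.pearsonr(seg_speed, vals).statistic
    return float(r), None


def population_summary(results: list[ModulationResult]) -> dict:
    """Counts and fractions by direction over eligible units."""
    ok = [r for r in results if r.status == "ok"]
    if not ok:
        raise ValueError("no eligible units to summarize")
    counts = {d: sum(r.direction == d for r in ok) for d in (INCREASED, DECREASED, NS)}
    n = len(ok)
    return {
        "n_eligible": n,
        "n_ineligible": len(results) - n,
        "counts": counts,
        "fractions": {d: counts[d] / n for d in counts},
    }
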