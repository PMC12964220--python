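"""Analysis configuration.

Every numeric threshold used by the pipeline is collected in
:class:`AnalysisConfig`.  Defaults reproduce the analysis rules of the
head-fixed treadmill protocol this package targets: walking is speed
> 2 cm/s with sub-200-ms breaks merged, modulation is a per-unit t test
on 1-s segment rates at p < 0.01, onset-aligned latency uses a 1-SD
threshold on a 100-ms-smoothed average rate profile with a 0.5 Hz
baseline floor, EMG onsets use a 2-SD threshold with a 0.03 SD floor on
the max-normalized envelope, and single units must have an inter-spike
interval violation rate below 0.5 % (refractory period 0.7 ms).

Configs serialize to/from a flat ``key = value`` text file so that every
report can echo the exact thresholds it was produced with.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, fields, replace


@dataclass
class AnalysisConfig:
    # -- locomotion segmentation -------------------------------------------
    speed_threshold: float = 2.0        # cm/s; walking is strictly > this
    min_break: float = 0.2              # s; sub-threshold gaps shorter than this merge
    segment_len: float = 1.0            # s; fixed grid from t = 0
    speed_smooth_win: float = 0.2       # s; Hanning window for the speed trace
    onset_sensor_change: float = 0.05   # fraction of session sensor dynamic range
    onset_pre_stationary: float = 0.5   # s of stillness required before an onset

    # -- per-unit modulation test ------------------------------------------
    p_mod: float = 0.01                 # two-sided significance level
    min_walk_segments: int = 4
    min_stationary_segments: int = 2    # needed for a variance estimate
    corr_bin: float = 0.1               # s; bin width for envelope/speed correlations

    # -- firing-rate traces -------------------------------------------------
    rate_smooth_win: float = 0.1        # s; Hanning window for rate traces
    rate_trace_hz: float = 1000.0       # samples/s of the smoothed rate trace

    # -- onset-aligned latency ---------------------------------------------
    baseline_win: tuple[float, float] = (-1.5, -1.0)  # s relative to onset
    latency_sd_mult: float = 1.0
    baseline_rate_floor: float = 0.5    # Hz; replaces near-zero baseline means
    min_onsets: int = 10
    latency_search_end: float = 2.0     # s after onset; end of crossing search
    latency_min_hold: float = 0.1       # s a crossing must persist (sustained departure)

    # -- bout-wise classification ------------------------------------------
    bout_win: float = 2.0               # s; +/- window around each onset
    bout_resp_win: tuple[float, float] = (0.0, 0.5)
    bout_inc_lat_sd: float = 2.0        # SD multiple for per-bout increase latency
    bout_dec_frac: float = 0.2          # fallback: 20 % drop when mean-1SD < 0
    bout_dec_rate_floor: float = 0.5    # Hz
    boutwise_min_rate: float = 5.0      # Hz; overall rate needed for bout-wise analysis

    # -- EMG ----------------------------------------------------------------
    emg_smooth_win: float = 0.1         # s; moving average on the rectified EMG
    emg_rate: float = 2000.0            # samples/s after downsampling
    emg_sd_mult: float = 2.0
    emg_min_sd: float = 0.03            # floor on baseline SD of the normalized envelope
    emg_baseline_win: tuple[float, float] = (-1.0, -0.5)  # s before treadmill onset
    emg_search_win: float = 0.5         # s; EMG onset searched within +/- this of treadmill onset
    emg_pair_max_gap: float = 0.5       # s; max |EMG - treadmill| onset gap when pairing

    # -- vibration / acoustics ----------------------------------------------
    vib_smooth_win: float = 0.2         # s; moving average for the vibration envelope
    footstep_threshold_sd: float = 4.0  # k in (mean + k*SD) envelope threshold
    footstep_refractory: float = 0.05   # s between distinct footstep events
    footstep_pad: float = 0.005         # s added on each side of an event extent
    footstep_min_dur: float = 0.005     # s; shortest supra-threshold span counted
    footstep_env_smooth: float = 0.002  # s; envelope smoothing for the detection statistic
    psd_nperseg: int = 8192

    # -- unit quality control -----------------------------------------------
    isi_refractory: float = 0.0007      # s; intervals strictly below this are violations
    max_isi_violation: float = 0.005    # fraction; QC requires strictly below

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "speed_threshold min_break segment_len speed_smooth_win "
            "onset_pre_stationary rate_smooth_win rate_trace_hz corr_bin "
            "baseline_rate_floor latency_search_end latency_min_hold bout_win "
            "bout_inc_lat_sd bout_dec_rate_floor emg_smooth_win emg_rate "
            "emg_sd_mult emg_min_sd emg_search_win emg_pair_max_gap "
            "vib_smooth_win footstep_threshold_sd footstep_refractory "
            "footstep_min_dur footstep_env_smooth isi_refractory latency_sd_mult"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("onset_sensor_change", "p_mod", "bout_dec_frac", "max_isi_violation"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("min_walk_segments", "min_stationary_segments", "min_onsets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("baseline_win", "bout_resp_win", "emg_baseline_win"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} must be a well-ordered (low, high) window")
        if self.footstep_pad < 0:
            raise ValueError("footstep_pad must be >= 0")

    # -- serialization -------------------------------------------------------
    def to_text(self) -> str:
        lines = ["# icloco analysis configuration, schema 1"]
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "AnalysisConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"unknown configuration key: {key!r}")
            kwargs[key] = ast.literal_eval(value.strip())
        return cls(**kwargs)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = AnalysisConfig()
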