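"""End-to-end orchestration: QC, segmentation, modulation, latency, EMG,
bout-wise typing, acoustics, and the report tables that mirror them.

``run_all`` is deterministic given (session, config); every filtering
step logs counts in/out (the eligibility rules make population
denominators analysis-critical), and stages that only need independent
inputs still run when another stage fails.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .acoustics import (
    detect_footsteps,
    measure_calibration_tone,
    vibration_speed_correlation,
)
from .config import AnalysisConfig
from .emg import delay_distribution, detect_emg_onset, emg_envelope
from .errors import EligibilityError
from .latency import (
    adjust_latency_reference,
    boutwise_classify,
    estimate_latency,
    onset_triggered_average,
)
from .locomotion import (
    compute_speed,
    detect_treadmill_onsets,
    label_segments,
    walking_periods,
)
from .modulation import DECREASED, INCREASED, classify_modulation, population_summary
from .signals import firing_rate_trace, isi_violation_rate, passes_isi_qc
from .synth import SessionBundle


@dataclass
class ReportBundle:
    """All pipeline outputs for one session."""

    modulation: pd.DataFrame
    latency: pd.DataFrame
    bouts: pd.DataFrame
    emg: dict
    acoustics: dict
    comparisons: dict
    counts: dict
    config_text: str
    seed: int | None
    version: str = __version__

    def summary(self) -> dict:
        return {
            "counts": self.counts,
            "comparisons": self.comparisons,
            "emg": {k: v for k, v in self.emg.items() if k != "delays"},
            "acoustics": self.acoustics,
            "seed": self.seed,
            "version": self.version,
        }

    def to_dir(self, path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.modulation.to_csv(path / "modulation.csv", index=False, float_format="%.12g")
        self.latency.to_csv(path / "latency.csv", index=False, float_format="%.12g")
        self.bouts.to_csv(path / "bouts.csv", index=False, float_format="%.12g")
        if "delays" in self.emg:
            pd.DataFrame(self.emg["delays"]).to_csv(
                path / "emg_delays.csv", index=False, float_format="%.12g"
            )
        (path / "summary.json").write_text(
            json.dumps(_sanitize(self.summary()), sort_keys=True, indent=1) + "\n"
        )
        (path / "config.txt").write_text(self.config_text)
        return path

    def checksum(self) -> str:
        h = hashlib.sha256()
        for df in (self.modulation, self.latency, self.bouts):
            h.update(df.to_csv(index=False, float_format="%.12g").encode())
        h.update(json.dumps(_sanitize(self.summary()), sort_keys=True).encode())
        return h.hexdigest()


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    return obj


def group_compare(a, b, kind: str) -> dict:
    """Two-sided group comparison: ranksum | paired_t | welch_t."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if kind == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif kind == "paired_t":
        if a.size != b.size:
            raise ValueError("paired test requires equal lengths")
        if np.all(a == b):  # zero differences: t is 0/0, define as no effect
            return {"kind": kind, "statistic": 0.0, "p": 1.0, "n_a": int(a.size), "n_b": int(b.size)}
        res = stats.ttest_rel(a, b)
    elif kind == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown comparison kind {kind!r}")
    return {
        "kind": kind,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def run_all(bundle: SessionBundle, cfg: AnalysisConfig | None = None) -> ReportBundle:
    """Run every applicable analysis stage on a session."""
    cfg = cfg or AnalysisConfig()
    counts: dict = {"errors": {}}
    emg_out: dict = {"present": False}
    acoustics_out: dict = {}
    comparisons: dict = {}
    mod_rows: list[dict] = []
    lat_rows: list[dict] = []
    bout_rows: list[dict] = []

    has_loco = "speed" in bundle.signals and "treadmill_sensor" in bundle.signals

    # ---- locomotion segmentation -----------------------------------------
    labels = onsets = None
    speed = None
    if has_loco:
        speed = compute_speed(bundle.signals["speed"], cfg)
        periods = walking_periods(speed, cfg)
        labels = label_segments(speed.duration, periods, cfg)
        onsets = detect_treadmill_onsets(bundle.signals["treadmill_sensor"], cfg)
        counts["n_walk_periods"] = len(periods)
        counts["n_segments"] = len(labels)
        counts["n_onsets"] = len(onsets)

    # ---- unit QC ----------------------------------------------------------
    counts["units_in"] = len(bundle.units)
    qc_units = []
    n_qc_fail = 0
    for st in bundle.units:
        try:
            ok = passes_isi_qc(st, cfg)
        except Exception:
            ok = False
        if ok:
            qc_units.append(st)
        else:
            n_qc_fail += 1
    counts["units_qc_failed"] = n_qc_fail
    counts["units_qc_passed"] = len(qc_units)

    # ---- modulation --------------------------------------------------------
    results = []
    if labels is not None:
        for st in qc_units:
            res = classify_modulation(st, labels, cfg, speed=speed)
            results.append(res)
            mod_rows.append(
                {
                    "unit_id": res.unit_id,
                    "status": res.status,
                    "direction": res.direction,
                    "rate_stationary": res.rate_stationary,
                    "rate_walking": res.rate_walking,
                    "t_stat": res.t_stat,
                    "df": res.df,
                    "p": res.p,
                    "r_speed": res.r_speed,
                    "n_walk_segments": res.n_walk_segments,
                    "n_stat_segments": res.n_stat_segments,
                    "isi_violation": isi_violation_rate(st, cfg) if st.n_spikes >= 2 else np.nan,
                }
            )
        try:
            counts["population"] = population_summary(results)
        except ValueError as exc:
            counts["errors"]["population"] = str(exc)
        counts["units_ineligible"] = sum(r.status != "ok" for r in results)

    # ---- EMG delays --------------------------------------------------------
    median_delay_ms = None
    emg_env = None
    if "emg" in bundle.signals and onsets:
        try:
            emg_env = emg_envelope(bundle.signals["emg"], cfg)
            tread_times = [o.time for o in onsets]
            emg_times = [detect_emg_onset(emg_env, t, cfg) for t in tread_times]
            detected = [(e, t) for e, t in zip(emg_times, tread_times) if e is not None]
            counts["emg_onsets_detected"] = len(detected)
            counts["emg_onsets_missed"] = len(tread_times) - len(detected)
            dist = delay_distribution([e for e, _ in detected], tread_times, cfg)
            median_delay_ms = dist.median_delay * 1000.0
            emg_out = {
                "present": True,
                "median_delay_ms": median_delay_ms,
                "n_delays": int(dist.delays.size),
                "delays": {
                    "treadmill_onset_s": dist.treadmill_onsets,
                    "emg_onset_s": dist.emg_onsets,
                    "delay_s": dist.delays,
                },
            }
        except Exception as exc:  # EMG failure must not block other stages
            counts["errors"]["emg"] = str(exc)

    # ---- onset-aligned latency --------------------------------------------
    modulated = [r for r in results if r.status == "ok" and r.direction in (INCREASED, DECREASED)]
    by_id = {st.unit_id: st for st in qc_units}
    emg_onset_times = (
        emg_out["delays"]["emg_onset_s"].tolist() if emg_out.get("present") else None
    )
    if onsets:
        for res in modulated:
            st = by_id[res.unit_id]
            trace = firing_rate_trace(st, cfg)
            row = {
                "unit_id": res.unit_id,
                "direction": res.direction,
                "latency_treadmill_ms": np.nan,
                "latency_emg_ms": np.nan,
                "latency_adjusted_ms": np.nan,
                "baseline_mean": np.nan,
                "baseline_sd": np.nan,
                "n_onsets": 0,
                "status": "ok",
            }
            try:
                prof = onset_triggered_average(st, onsets, cfg, trace=trace)
                lat = estimate_latency(prof, res.direction, cfg)
                row.update(
                    latency_treadmill_ms=np.nan if lat.latency_ms is None else lat.latency_ms,
                    baseline_mean=lat.baseline_mean,
                    baseline_sd=lat.baseline_sd,
                    n_onsets=lat.n_onsets,
                    status=lat.status,
                )
                if lat.latency_ms is not None and median_delay_ms is not None:
                    row["latency_adjusted_ms"] = adjust_latency_reference(
                        lat.latency_ms, median_delay_ms
                    )
                if emg_onset_times:
                    try:
                        prof_e = onset_triggered_average(st, emg_onset_times, cfg, trace=trace)
                        lat_e = estimate_latency(prof_e, res.direction, cfg, reference="emg")
                        if lat_e.latency_ms is not None:
                            row["latency_emg_ms"] = lat_e.latency_ms
                    except EligibilityError:
                        pass
                # bout-wise typing needs sufficiently high firing rates
                if st.mean_rate >= cfg.boutwise_min_rate:
                    for j, onset in enumerate(onsets):
                        bm = boutwise_classify(st, onset, j, cfg, trace=trace)
                        bout_rows.append(
                            {
                                "unit_id": bm.unit_id,
                                "onset_index": bm.onset_index,
                                "label": bm.label,
                                "latency_ms": np.nan if bm.latency_ms is None else bm.latency_ms,
                                "status": bm.status,
                            }
                        )
            except EligibilityError as exc:
                row["status"] = "ineligible"
                counts["errors"].setdefault("latency", {})[res.unit_id] = str(exc)
            lat_rows.append(row)

    latency_df = pd.DataFrame(
        lat_rows,
        columns=[
            "unit_id", "direction", "latency_treadmill_ms", "latency_emg_ms",
            "latency_adjusted_ms", "baseline_mean", "baseline_sd", "n_onsets", "status",
        ],
    )
    if len(latency_df):
        inc = latency_df.query("direction == 'increased'")["latency_treadmill_ms"].dropna()
        dec = latency_df.query("direction == 'decreased'")["latency_treadmill_ms"].dropna()
        if len(inc):
            comparisons["median_latency_increased_ms"] = float(inc.median())
        if len(dec):
            comparisons["median_latency_decreased_ms"] = float(dec.median())
        if len(inc) >= 2 and len(dec) >= 2:
            comparisons["latency_increased_vs_decreased"] = group_compare(inc, dec, "ranksum")
        paired = latency_df.dropna(subset=["latency_treadmill_ms", "latency_emg_ms"])
        if len(paired) >= 2:
            comparisons["latency_treadmill_vs_emg"] = group_compare(
                paired["latency_treadmill_ms"], paired["latency_emg_ms"], "paired_t"
            )

    # ---- acoustics ---------------------------------------------------------
    if "vibration" in bundle.signals and speed is not None:
        try:
            acoustics_out["vibration_speed_r"] = vibration_speed_correlation(
                bundle.signals["vibration"], speed, cfg, is_envelope=True
            )
        except Exception as exc:
            counts["errors"]["vibration"] = str(exc)
    if "audio" in bundle.signals and "audio" in bundle.meta:
        try:
            info = bundle.meta["audio"]
            audio = bundle.signals["audio"]
            ref = measure_calibration_tone(
                audio, tuple(info["tone_interval"]), info["tone_spl_db"],
                info.get("tone_freq", 4000.0),
            )
            events = detect_footsteps(
                audio, [tuple(info["quiet_interval"])], cfg, ref=ref,
                exclude_intervals=[tuple(info["tone_interval"])],
            )
            spls = [e.spl_db for e in events]
            acoustics_out["n_footsteps"] = len(events)
            if spls:
                acoustics_out["footstep_spl_mean_db"] = float(np.mean(spls))
                acoustics_out["footstep_spl_sd_db"] = float(np.std(spls))
        except Exception as exc:
            counts["errors"]["audio"] = str(exc)

    # filter accounting: everything in must be reported or dropped
    counts["units_reported"] = len(mod_rows)
    assert counts["units_in"] == counts["units_reported"] + counts["units_qc_failed"] or not has_loco

    return ReportBundle(
        modulation=pd.DataFrame(
            mod_rows,
            columns=[
                "unit_id", "status", "direction", "rate_stationary", "rate_walking",
                "t_stat", "df", "p", "r_speed", "n_walk_segments", "n_stat_segments",
                "isi_violation",
            ],
        ),
        latency=latency_df,
        bouts=pd.DataFrame(
            bout_rows, columns=["unit_id", "onset_index", "label", "latency_ms", "status"]
        ),
        emg=emg_out,
        acoustics=acoustics_out,
        comparisons=comparisons,
        counts=counts,
        config_text=cfg.to_text(),
        seed=bundle.meta.get("seed"),
    )
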