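"""Session container I/O.

A session is a directory:

    manifest.json          inventory + metadata (schema_version 1)
    signals/<name>.bin     float64 little-endian raw samples
    signals/<name>.json    sidecar: rate, units, t0, n
    spikes.csv             unit_id,time_s (one row per spike)
    truth.json             optional ground truth (synthetic sessions)

Floats in text files are written with shortest-round-trip repr and JSON
keys are sorted, so save -> load is bit-exact for arrays and
field-exact for metadata, and identical bundles serialize to identical
bytes (the determinism contract the pipeline's checksum test relies on).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import MissingFileError, RateMismatchError, SchemaVersionError, SessionFormatError
from .signals import ContinuousSignal, SpikeTrain
from .synth import GroundTruth, SessionBundle, UnitTruth

SCHEMA_VERSION = 1


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    return obj


def save_session(bundle: SessionBundle, path) -> Path:
    """Write a SessionBundle to ``path`` (created if needed)."""
    path = Path(path)
    (path / "signals").mkdir(parents=True, exist_ok=True)
    inventory = []
    for name, sig in sorted(bundle.signals.items()):
        sig.samples.astype("<f8").tofile(path / "signals" / f"{name}.bin")
        sidecar = {"rate": sig.rate, "units": sig.units, "t0": sig.t0, "n": sig.n}
        (path / "signals" / f"{name}.json").write_text(
            json.dumps(sidecar, sort_keys=True, indent=1) + "\n"
        )
        inventory.append({"name": name, "file": f"signals/{name}.bin", **sidecar})
    lines = ["unit_id,time_s"]
    unit_rows = []
    for st in bundle.units:
        unit_rows.append(
            {"unit_id": st.unit_id, "duration": st.duration, "n_spikes": st.n_spikes}
        )
        lines.extend(f"{st.unit_id},{t!r}" for t in st.times.tolist())
    (path / "spikes.csv").write_text("\n".join(lines) + "\n")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "signals": inventory,
        "spikes": "spikes.csv",
        "units": unit_rows,
        "meta": _jsonable(bundle.meta),
        "truth": "truth.json" if bundle.truth is not None else None,
    }
    if bundle.truth is not None:
        (path / "truth.json").write_text(
            json.dumps(_jsonable(bundle.truth), sort_keys=True, indent=1) + "\n"
        )
    (path / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return path


def load_session(path) -> SessionBundle:
    """Load a session directory saved by :func:`save_session`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise MissingFileError(f"no manifest.json in {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"manifest.json is not valid JSON: {exc}") from exc
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unknown session schema version {version!r} (expected {SCHEMA_VERSION})"
        )
    signals: dict[str, ContinuousSignal] = {}
    for entry in manifest.get("signals", []):
        f = path / entry["file"]
        if not f.exists():
            raise MissingFileError(f"signal file listed in manifest is missing: {f}")
        sidecar_path = f.with_suffix(".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            if abs(sidecar["rate"] - entry["rate"]) > 1e-9:
                raise RateMismatchError(
                    f"rate mismatch for signal {entry['name']!r}: "
                    f"manifest {entry['rate']} vs sidecar {sidecar['rate']}"
                )
        samples = np.fromfile(f, dtype="<f8")
        if samples.size != entry["n"]:
            raise SessionFormatError(
                f"signal {entry['name']!r} has {samples.size} samples, manifest says {entry['n']}"
            )
        signals[entry["name"]] = ContinuousSignal(
            samples, entry["rate"], units=entry["units"], t0=entry["t0"]
        )
    spikes_file = path / manifest.get("spikes", "spikes.csv")
    if not spikes_file.exists():
        raise MissingFileError(f"spike file missing: {spikes_file}")
    by_unit: dict[str, list[float]] = {}
    for line in spikes_file.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        uid, t = line.split(",")
        by_unit.setdefault(uid, []).append(float(t))
    units = [
        SpikeTrain(np.array(by_unit.get(row["unit_id"], [])), row["duration"], row["unit_id"])
        for row in manifest.get("units", [])
    ]
    truth = None
    if manifest.get("truth"):
        truth_path = path / manifest["truth"]
        if not truth_path.exists():
            raise MissingFileError(f"truth file missing: {truth_path}")
        raw = json.loads(truth_path.read_text())
        unit_truths = [UnitTruth(**u) for u in raw.pop("units", [])]
        raw["bouts"] = [tuple(b) for b in raw.get("bouts", [])]
        for key in ("tone_interval", "quiet_interval"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        truth = GroundTruth(**raw)
        truth.units = unit_truths
    return SessionBundle(signals=signals, units=units, meta=manifest.get("meta", {}), truth=truth)
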