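"""Readers and writers for the on-disk formats.

Native trace container: one raw little-endian float32 sample file
(``*.dat``) plus a JSON sidecar (``*.json``) per sweep or channel. Tables
(events, intervals, spikes, DSI trials, results) are headered CSV.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .core import (
    EventSeries,
    FormatError,
    IntegrityError,
    IntervalSet,
    SessionBundle,
    Sweep,
    Trace,
    UnitRecord,
    ValidationError,
)

_SWEEP_FIELDS = ("dt_ms", "step_amplitude", "step_onset_ms", "step_offset_ms", "mode")


def _require(sidecar: dict, field: str, path: Path):
    if field not in sidecar:
        raise FormatError(f"{path}: sidecar missing required field {field!r}")
    return sidecar[field]


# ---------------------------------------------------------------- sweeps

def write_sweep_set(directory, sweeps: List[Sweep]) -> None:
    """Write sweeps as ``sweep_###.dat`` (float32 LE) + ``sweep_###.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, sw in enumerate(sweeps):
        stem = directory / f"sweep_{i:03d}"
        np.asarray(sw.samples, dtype="<f4").tofile(stem.with_suffix(".dat"))
        sidecar = {
            "dt_ms": sw.dt,
            "step_amplitude": sw.step_amplitude,
            "step_onset_ms": sw.step_onset,
            "step_offset_ms": sw.step_offset,
            "mode": sw.mode,
            "n_samples": sw.n_samples,
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_sweep_set(directory) -> List[Sweep]:
    """Read a sweep container written by :func:`write_sweep_set`.

    Sweeps are returned in acquisition (file-name) order. A missing sidecar
    field raises :class:`FormatError`; a sample-count mismatch between the
    sidecar and the binary file raises :class:`IntegrityError`.
    """
    directory = Path(directory)
    if directory.suffix == ".nwb":
        raise FormatError("NWB containers are not supported by this build")
    sidecars = sorted(directory.glob("sweep_*.json"))
    if not sidecars:
        raise FormatError(f"{directory}: no sweep sidecars found")
    sweeps = []
    for sc_path in sidecars:
        sidecar = json.loads(sc_path.read_text())
        for field in _SWEEP_FIELDS:
            _require(sidecar, field, sc_path)
        samples = np.fromfile(sc_path.with_suffix(".dat"), dtype="<f4")
        n_expected = sidecar.get("n_samples", samples.size)
        if samples.size != n_expected:
            raise IntegrityError(
                f"{sc_path}: sidecar declares {n_expected} samples, "
                f"file holds {samples.size}"
            )
        sweeps.append(
            Sweep(
                samples=samples.astype(np.float64),
                dt=sidecar["dt_ms"],
                step_amplitude=sidecar["step_amplitude"],
                step_onset=sidecar["step_onset_ms"],
                step_offset=sidecar["step_offset_ms"],
                mode=sidecar["mode"],
            )
        )
    return sweeps


# ---------------------------------------------------------------- tables

def write_events(path, events: EventSeries) -> None:
    pd.DataFrame({"time": events.times, "label": events.label}).to_csv(
        path, index=False
    )


def read_events(path, label: Optional[str] = None) -> EventSeries:
    """Read a headered CSV with a ``time`` column; output is sorted."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise FormatError(f"{path}: events CSV requires a 'time' column")
    times = np.sort(df["time"].to_numpy(dtype=float))
    if label is None:
        label = str(df["label"].iloc[0]) if "label" in df.columns and len(df) else "event"
    return EventSeries(times=times, label=label)


def write_intervals(path, intervals: IntervalSet) -> None:
    pd.DataFrame(
        {"start": intervals.starts, "stop": intervals.stops, "label": intervals.labels}
    ).to_csv(path, index=False)


def read_intervals(path) -> IntervalSet:
    df = pd.read_csv(path)
    for col in ("start", "stop", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: intervals CSV requires a {col!r} column")
    try:
        return IntervalSet(
            starts=df["start"].to_numpy(dtype=float),
            stops=df["stop"].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=object),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_units(path, units: List[UnitRecord], waveform_path=None) -> None:
    """Write spikes as (unit_id, time) CSV; waveforms to a JSON sidecar."""
    rows = [
        {"unit_id": u.unit_id, "time": t} for u in units for t in u.spike_times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time"]).to_csv(path, index=False)
    if waveform_path is not None:
        meta = {}
        for u in units:
            entry = {"depth_um": u.depth_um, "ground_truth": u.ground_truth}
            if u.waveform is not None:
                entry["waveform"] = [round(float(v), 4) for v in u.waveform]
                entry["waveform_fs"] = u.waveform_fs
            meta[str(u.unit_id)] = entry
        Path(waveform_path).write_text(json.dumps(meta))


def read_units(path, waveform_path=None) -> List[UnitRecord]:
    df = pd.read_csv(path)
    for col in ("unit_id", "time"):
        if col not in df.columns:
            raise FormatError(f"{path}: spikes CSV requires a {col!r} column")
    meta = {}
    if waveform_path is not None and Path(waveform_path).exists():
        meta = json.loads(Path(waveform_path).read_text())
    units = []
    ids = df["unit_id"].astype(str)
    for uid in ids.unique():
        m = meta.get(uid, {})
        wf = m.get("waveform")
        units.append(
            UnitRecord(
                unit_id=uid,
                spike_times=np.sort(df.loc[ids == uid, "time"].to_numpy(dtype=float)),
                waveform=np.asarray(wf, dtype=float) if wf is not None else None,
                waveform_fs=m.get("waveform_fs"),
                depth_um=m.get("depth_um"),
                ground_truth=m.get("ground_truth"),
            )
        )
    return units


# ---------------------------------------------------------------- traces

def write_trace(stem, trace: Trace) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.asarray(trace.samples, dtype="<f4").tofile(stem.with_suffix(".dat"))
    stem.with_suffix(".json").write_text(
        json.dumps({"fs_hz": trace.fs, "n_samples": int(trace.samples.size)})
    )


def read_trace(stem) -> Trace:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    fs = _require(sidecar, "fs_hz", stem)
    samples = np.fromfile(stem.with_suffix(".dat"), dtype="<f4")
    if samples.size != sidecar.get("n_samples", samples.size):
        raise IntegrityError(f"{stem}: sample count mismatch")
    return Trace(samples=samples.astype(np.float64), fs=fs)


# ---------------------------------------------------------------- session

def write_session(directory, bundle: SessionBundle) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_units(directory / "spikes.csv", bundle.units, directory / "units.json")
    for label, ev in bundle.events.items():
        write_events(directory / f"events_{label}.csv", ev)
    if bundle.intervals is not None:
        write_intervals(directory / "intervals.csv", bundle.intervals)
    if bundle.lfp is not None:
        write_trace(directory / "lfp", bundle.lfp)
    for name, tr in bundle.aux.items():
        write_trace(directory / f"aux_{name}", tr)
    meta = {"duration_s": bundle.duration_s, "ground_truth": _jsonable(bundle.ground_truth)}
    (directory / "session.json").write_text(json.dumps(meta))


def read_session(directory) -> SessionBundle:
    directory = Path(directory)
    meta = json.loads((directory / "session.json").read_text())
    units = read_units(directory / "spikes.csv", directory / "units.json")
    events = {}
    for p in sorted(directory.glob("events_*.csv")):
        label = p.stem[len("events_"):]
        events[label] = read_events(p, label=label)
    intervals = None
    if (directory / "intervals.csv").exists():
        intervals = read_intervals(directory / "intervals.csv")
    lfp = read_trace(directory / "lfp") if (directory / "lfp.json").exists() else None
    aux = {
        p.stem[len("aux_"):]: read_trace(p.with_suffix(""))
        for p in sorted(directory.glob("aux_*.json"))
    }
    return SessionBundle(
        units=units,
        events=events,
        intervals=intervals,
        lfp=lfp,
        aux=aux,
        duration_s=meta["duration_s"],
        ground_truth=meta.get("ground_truth", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
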