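"""On-disk cell container and feature-table I/O.

Each cell is a directory holding ``meta.json`` (sampling rate, units,
protocol and stimulus schedule, condition) plus one trace file per sweep,
either raw little-endian float32 (``.f32``, the default) or a single-column
CSV.  Canonical units (mV, pA, ms, s for stimulus events, Hz) are fixed at
this boundary; traces round-trip bit-identically in float32 form.

Feature tables are plain CSV (UTF-8, header row, empty fields for missing
values) handled through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .recording import GratingRecording, IVRecording, StimEvents, Sweep

META_NAME = "meta.json"

#: canonical feature-table columns, one row per cell
FEATURE_COLUMNS = [
    "cell_id", "condition", "rmp", "rheobase", "spike_threshold",
    "rest_to_threshold", "r_in_hyp", "r_in_dep", "ahp_amplitude",
    "ahp_latency", "is_rs", "vm0_pref", "vm1_pref", "f0_pref",
    "osi_vm0", "osi_vm1", "osi_f0", "responsive",
]


def _trace_path(cell_dir: Path, name: str, fmt: str) -> Path:
    return cell_dir / f"{name}.{'f32' if fmt == 'f32' else 'csv'}"


def _write_trace(path: Path, vm: np.ndarray, fmt: str) -> None:
    if fmt == "f32":
        np.asarray(vm, dtype="<f4").tofile(path)
    else:
        np.savetxt(path, np.asarray(vm, dtype=float), fmt="%.7g", header="vm_mv")


def _read_trace(path: Path, fmt: str) -> np.ndarray:
    if fmt == "f32":
        return np.fromfile(path, dtype="<f4").astype(np.float64)
    return np.loadtxt(path, dtype=float)


def write_cell_record(path, iv: Optional[IVRecording] = None,
                      grating: Optional[GratingRecording] = None,
                      cell_id: str = "cell", condition: str = "control",
                      fmt: str = "f32", extra_meta: Optional[dict] = None) -> Path:
    """Write one cell directory; returns the directory path."""
    if fmt not in ("f32", "csv"):
        raise ValueError("fmt must be 'f32' or 'csv'")
    cell_dir = Path(path)
    cell_dir.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "cell_id": cell_id, "condition": condition, "format": fmt,
        "units": {"vm": "mV", "current": "pA", "time": "ms",
                  "stim_events": "s"},
    }
    if extra_meta:
        meta["extra"] = extra_meta
    if iv is not None:
        meta["fs_iv"] = iv.sweeps[0].fs
        meta["iv"] = []
        for j, sw in enumerate(iv.sweeps):
            name = f"iv_{j:03d}"
            _write_trace(_trace_path(cell_dir, name, fmt), sw.vm, fmt)
            meta["iv"].append({"trace": name, "i_pa": sw.i_inj,
                               "step_window_ms": list(sw.step_window)
                               if sw.step_window else None})
    if grating is not None:
        any_sweep = next(iter(grating.trials.values()))
        meta["fs_grating"] = any_sweep.fs
        meta["grating"] = []
        for (i, theta), sw in sorted(grating.trials.items()):
            name = f"grating_r{i:02d}_d{int(round(theta)):03d}"
            _write_trace(_trace_path(cell_dir, name, fmt), sw.vm, fmt)
            st = sw.stim
            meta["grating"].append({
                "trace": name, "repeat": i, "direction_deg": theta,
                "static_onset_s": st.static_onset if st else None,
                "drift_onset_s": st.drift_onset if st else None,
                "drift_offset_s": st.drift_offset if st else None,
            })
    with open(cell_dir / META_NAME, "w") as fh:
        json.dump(meta, fh, indent=1)
    return cell_dir


def read_cell_record(path) -> tuple[Optional[IVRecording],
                                    Optional[GratingRecording], dict]:
    """Read a cell directory; returns (iv, grating, meta).

    Hard error when the sampling rate is missing; an IV block without a
    zero-current sweep is returned but callers see it flagged by
    :func:`vcephys.recording.validate_recording`.
    """
    cell_dir = Path(path)
    meta_path = cell_dir / META_NAME
    if not meta_path.exists():
        raise FileNotFoundError(f"no {META_NAME} in {cell_dir}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    fmt = meta.get("format", "f32")

    iv = None
    if "iv" in meta:
        fs = meta.get("fs_iv")
        if not fs:
            raise ValueError("sampling rate required (fs_iv missing)")
        sweeps = []
        for entry in meta["iv"]:
            vm = _read_trace(_trace_path(cell_dir, entry["trace"], fmt), fmt)
            win = entry.get("step_window_ms")
            sweeps.append(Sweep(vm=vm, fs=fs, i_inj=entry["i_pa"],
                                step_window=tuple(win) if win else None))
        iv = IVRecording(sweeps=sweeps, meta={"cell_id": meta.get("cell_id")})

    grating = None
    if "grating" in meta:
        fs = meta.get("fs_grating")
        if not fs:
            raise ValueError("sampling rate required (fs_grating missing)")
        trials = {}
        for entry in meta["grating"]:
            vm = _read_trace(_trace_path(cell_dir, entry["trace"], fmt), fmt)
            stim = StimEvents(direction_deg=entry["direction_deg"],
                              static_onset=entry["static_onset_s"],
                              drift_onset=entry["drift_onset_s"],
                              drift_offset=entry["drift_offset_s"])
            trials[(entry["repeat"], float(entry["direction_deg"]))] = Sweep(
                vm=vm, fs=fs, i_inj=0.0, stim=stim)
        grating = GratingRecording(trials=trials,
                                   meta={"cell_id": meta.get("cell_id")})
    return iv, grating, meta


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the per-cell feature table as CSV; missing values stay empty."""
    if len(table) == 0:
        raise ValueError("feature table is empty")
    table.to_csv(path, index=False, float_format="%.6g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df
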