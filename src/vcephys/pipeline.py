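"""End-to-end orchestration: simulate/load -> detect -> clip -> intrinsic ->
evoked -> tuning -> group statistics.

The pipeline consumes either a directory of cell containers or a cohort
simulation spec, produces one feature-table row per regular-spiking cell,
and emits the group-comparison report and a QC report listing exclusions
(non-RS cells, unclassifiable cells, per-cell stage errors).  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as vio
from .evoked import analyze_grating
from .intrinsic import extract_intrinsic_features
from .recording import validate_recording
from .stats import comparison_report, proportion_test
from .synth import CohortSpec, simulate_cohort

RANKSUM_VARS = ["rmp", "spike_threshold", "rest_to_threshold", "r_in_hyp",
                "r_in_dep", "rheobase", "vm0_pref", "vm1_pref", "f0_pref"]
KS_VARS = ["osi_vm0", "osi_vm1", "osi_f0"]
CORR_VARS = ["rmp", "spike_threshold", "rest_to_threshold", "vm1_pref",
             "osi_vm0", "osi_vm1"]
CORR_TARGET = "osi_f0"


@dataclass
class PipelineConfig:
    """One of ``input_dir`` / ``cohort`` must be set (exactly one)."""

    input_dir: Optional[str] = None
    cohort: Optional[CohortSpec] = None
    k: float = 8.0
    baseline_ms: float = 100.0
    alpha: float = 0.05
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.cohort is None):
            raise ValueError("set exactly one of input_dir / cohort")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = json.load(fh)
        cohort = cfg.pop("cohort", None)
        if cohort is not None:
            cohort = CohortSpec(**cohort)
        return cls(cohort=cohort, **cfg)


@dataclass
class PipelineResult:
    features: pd.DataFrame
    report: dict
    qc: dict


def process_cell(cell_id: str, condition: str, iv, grating,
                 k: float = 8.0, baseline_ms: float = 100.0,
                 alpha: float = 0.05) -> tuple[Optional[dict], dict]:
    """Analyze one cell; returns (feature_row | None, qc_entry).

    The row is None when the cell is excluded (not classifiable as regular
    spiking, or invalid recording)."""
    qc: dict = {"cell_id": cell_id, "condition": condition, "violations": [],
                "excluded": None, "flags": []}
    row: dict = {c: np.nan for c in vio.FEATURE_COLUMNS}
    row["cell_id"], row["condition"] = cell_id, condition

    for rec in (iv, grating):
        if rec is not None:
            for v in validate_recording(rec):
                qc["violations"].append(str(v))
                if v.level == "error":
                    qc["excluded"] = f"invalid recording: {v.rule}"
    if qc["excluded"]:
        return None, qc

    if iv is not None:
        feats = extract_intrinsic_features(iv, baseline_ms=baseline_ms, k=k)
        qc["flags"] += list(feats.flags)
        if feats.is_rs is None:
            qc["excluded"] = "unclassified (no rheobase spike waveform)"
            return None, qc
        if not feats.is_rs:
            qc["excluded"] = "not regular-spiking (AHP criterion)"
            return None, qc
        for name in ("rmp", "rheobase", "spike_threshold", "rest_to_threshold",
                     "r_in_hyp", "r_in_dep", "ahp_amplitude", "ahp_latency"):
            row[name] = getattr(feats, name)
        row["is_rs"] = feats.is_rs

    if grating is not None:
        ev = analyze_grating(grating, baseline_ms=baseline_ms, k=k, alpha=alpha)
        qc["flags"] += list(ev.flags)
        qc["baseline_tuning_p"] = ev.baseline_tuning_p
        qc["responsive_p"] = ev.responsive_p
        row["responsive"] = ev.responsive
        row["vm0_pref"] = ev.vm0_at_pref
        row["vm1_pref"] = ev.vm1_at_pref
        row["f0_pref"] = ev.f0_at_pref
        row["has_evoked_spikes"] = ev.has_evoked_spikes
        if ev.tuning_vm0 is not None:
            row["osi_vm0"] = ev.tuning_vm0.osi
        if ev.tuning_vm1 is not None:
            row["osi_vm1"] = ev.tuning_vm1.osi
        # OSI_F0 only for responsive cells with defined tuning
        if ev.responsive and ev.tuning_f0 is not None:
            row["osi_f0"] = ev.tuning_f0.osi
    return row, qc


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; per-cell errors are recorded and skipped."""
    cells = []
    if config.cohort is not None:
        for rec in simulate_cohort(config.cohort):
            cells.append((rec.cell_id, rec.ground_truth.condition,
                          rec.iv, rec.grating))
    else:
        root = Path(config.input_dir)
        for cell_dir in sorted(p.parent for p in root.glob("*/meta.json")):
            iv, grating, meta = vio.read_cell_record(cell_dir)
            cells.append((meta.get("cell_id", cell_dir.name),
                          meta.get("condition", "control"), iv, grating))

    rows, qc_cells = [], []
    for cell_id, condition, iv, grating in cells:
        try:
            row, qc = process_cell(cell_id, condition, iv, grating,
                                   k=config.k, baseline_ms=config.baseline_ms,
                                   alpha=config.alpha)
        except Exception as exc:  # keep going over remaining cells
            row = None
            qc = {"cell_id": cell_id, "condition": condition,
                  "excluded": f"stage error: {exc}"}
        qc_cells.append(qc)
        if row is not None:
            rows.append(row)

    columns = vio.FEATURE_COLUMNS + ["has_evoked_spikes"]
    features = pd.DataFrame(rows, columns=columns)

    report = {}
    if len(features):
        report = comparison_report(
            features, ranksum_vars=RANKSUM_VARS, ks_vars=KS_VARS,
            corr_vars=CORR_VARS, corr_target=CORR_TARGET)
        by_group = features.groupby("condition")["has_evoked_spikes"]
        counts = {g: (int((~grp.astype(bool)).sum()), int(grp.size))
                  for g, grp in by_group}
        if len(counts) == 2 and "control" in counts and "deprived" in counts:
            k1, n1 = counts["control"]
            k2, n2 = counts["deprived"]
            report["no_evoked_spikes"] = {
                "control": f"{k1}/{n1}", "deprived": f"{k2}/{n2}",
                "fisher_exact_p": proportion_test(k1, n1, k2, n2)}

    qc = {
        "n_cells": len(cells),
        "n_included": len(rows),
        "exclusions": [q for q in qc_cells if q.get("excluded")],
        "cells": qc_cells,
        "provenance": {
            "seed": config.seed,
            "detection": {"k": config.k, "baseline_ms": config.baseline_ms},
            "alpha": config.alpha,
        },
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if len(features):
            vio.write_feature_table(features, out / "features.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_json_default)
        with open(out / "qc.json", "w") as fh:
            json.dump(qc, fh, indent=1, default=_json_default)
    return PipelineResult(features=features, report=report, qc=qc)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
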