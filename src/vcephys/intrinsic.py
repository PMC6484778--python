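"""Intrinsic membrane properties from the IV protocol.

Definitions: the steady-state Vm (``Vm_ss``) of a step is the mean over the
window 250 to 50 ms before the end of the step, on the spike-clipped trace;
the resting membrane potential (RMP) is the Vm_ss of the zero-current sweep;
rheobase is the first positive step to elicit a spike; the spike threshold
is the threshold of the first spike at rheobase; hyperpolarizing input
resistance is measured at the -200 pA step and depolarizing input resistance
at +150 pA (reported only for cells with rheobase > 150 pA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .recording import IVRecording, Sweep
from .spikes import (SpikeEvent, ahp_metrics, classify_regular_spiking,
                     clip_spikes, detect_spikes)

VMSS_WINDOW_BEFORE_END_MS = (250.0, 50.0)
R_HYP_CURRENT_PA = -200.0
R_DEP_CURRENT_PA = 150.0
R_DEP_MIN_RHEOBASE_PA = 150.0
COVERAGE_FACTOR = 1.5


@dataclass
class IntrinsicFeatures:
    """Per-cell intrinsic excitability features (Fig-1-style quantities)."""

    rmp: float = np.nan  # mV
    rheobase: float = np.nan  # pA
    spike_threshold: float = np.nan  # mV
    rest_to_threshold: float = np.nan  # mV
    r_in_hyp: float = np.nan  # MOhm
    r_in_dep: float = np.nan  # MOhm; NaN when rheobase <= 150 pA
    vm_ss_rheobase: float = np.nan  # mV (AHP reference)
    ahp_amplitude: float = np.nan  # mV
    ahp_latency: float = np.nan  # ms
    is_rs: Optional[bool] = None
    flags: tuple = ()


def steady_state_vm(sweep: Sweep) -> float:
    """Mean Vm over [step_end - 250 ms, step_end - 50 ms).

    The input must already be spike-clipped; pass sweeps through
    :func:`vcephys.spikes.clip_spikes` first.
    """
    if sweep.step_window is None:
        raise ValueError("sweep has no step_window")
    _, end = sweep.step_window
    a, b = end - VMSS_WINDOW_BEFORE_END_MS[0], end - VMSS_WINDOW_BEFORE_END_MS[1]
    if a < 0:
        raise ValueError("Vm_ss window extends before the start of the trace")
    seg = sweep.vm[sweep.window_slice(a, b)]
    if seg.size == 0:
        raise ValueError("empty Vm_ss window")
    if float(seg.max()) - float(seg.min()) > 20.0:
        raise ValueError(
            "Vm spans >20 mV inside the steady-state window; the trace "
            "appears to contain unclipped spikes (clip first)")
    return float(np.mean(seg, dtype=np.float64))


def input_resistance(vm_ss_at_current: float, rmp: float, at_current_pa: float,
                     rheobase_pa: Optional[float] = None) -> Optional[float]:
    """Input resistance (MOhm) from one step's steady-state deflection.

    ``R = (Vm_ss - RMP) / I``; for the +150 pA depolarizing measurement the
    value is withheld (None) unless rheobase > 150 pA, so that the step is
    strictly subthreshold.
    """
    if at_current_pa == 0:
        raise ValueError("input resistance undefined at zero current")
    if at_current_pa > 0 and (
        rheobase_pa is None or not rheobase_pa > R_DEP_MIN_RHEOBASE_PA
    ):
        if at_current_pa == R_DEP_CURRENT_PA:
            return None
    return float((vm_ss_at_current - rmp) / at_current_pa * 1e3)  # mV/pA -> MOhm


def extract_intrinsic_features(
    iv: IVRecording,
    events_by_sweep: Optional[dict[int, list[SpikeEvent]]] = None,
    baseline_ms: float = 100.0,
    k: float = 8.0,
) -> IntrinsicFeatures:
    """Full intrinsic-feature extraction for one validated IV recording.

    Spike detection runs per sweep (unless precomputed events are supplied);
    Vm statistics use clipped traces, AHP metrics the raw trace.
    """
    flags: list[str] = []
    if not iv.has_zero_sweep:
        raise ValueError("IV recording lacks a zero-current sweep")

    if events_by_sweep is None:
        events_by_sweep = {
            j: detect_spikes(s, baseline_ms=baseline_ms, k=k)
            for j, s in enumerate(iv.sweeps)
        }
    clipped = [
        clip_spikes(s, events_by_sweep.get(j, [])) for j, s in enumerate(iv.sweeps)
    ]

    currents = iv.currents
    zero_idx = int(np.argmin(np.abs(currents)))
    feats = IntrinsicFeatures()
    feats.rmp = steady_state_vm(clipped[zero_idx])

    # rheobase: first positive step with at least one detected spike
    rheo_idx = None
    for j in np.argsort(currents):
        if currents[j] > 0 and events_by_sweep.get(j):
            rheo_idx = int(j)
            break
    if rheo_idx is None:
        flags.append("no_spiking_sweep")
    else:
        feats.rheobase = float(currents[rheo_idx])
        first = events_by_sweep[rheo_idx][0]
        feats.spike_threshold = first.thresh_vm
        feats.rest_to_threshold = feats.spike_threshold - feats.rmp
        feats.vm_ss_rheobase = steady_state_vm(clipped[rheo_idx])
        amp, lat, truncated = ahp_metrics(
            iv.sweeps[rheo_idx], first, feats.vm_ss_rheobase
        )
        feats.ahp_amplitude, feats.ahp_latency = amp, lat
        if truncated:
            flags.append("ahp_window_truncated")
        feats.is_rs = classify_regular_spiking(amp, lat)
        if currents.max() < COVERAGE_FACTOR * feats.rheobase - 1e-9:
            flags.append("suprathreshold_coverage_below_1.5x_rheobase")

    # input resistances
    try:
        hyp_idx = int(np.flatnonzero(np.abs(currents - R_HYP_CURRENT_PA) < 1e-6)[0])
        feats.r_in_hyp = input_resistance(
            steady_state_vm(clipped[hyp_idx]), feats.rmp, R_HYP_CURRENT_PA
        )
    except IndexError:
        flags.append(f"no_sweep_at_{R_HYP_CURRENT_PA:g}pA")
    rheo = feats.rheobase if np.isfinite(feats.rheobase) else None
    if rheo is not None and rheo > R_DEP_MIN_RHEOBASE_PA:
        try:
            dep_idx = int(np.flatnonzero(np.abs(currents - R_DEP_CURRENT_PA) < 1e-6)[0])
            r = input_resistance(
                steady_state_vm(clipped[dep_idx]), feats.rmp,
                R_DEP_CURRENT_PA, rheobase_pa=rheo,
            )
            feats.r_in_dep = np.nan if r is None else r
        except IndexError:
            flags.append(f"no_sweep_at_+{R_DEP_CURRENT_PA:g}pA")
    feats.flags = tuple(flags)
    return feats
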