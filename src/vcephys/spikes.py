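"""Action-potential detection, threshold location, clipping and RS classification.

Detection is the classic two-step dV/dt procedure used for in vivo
current-clamp data: candidate spikes are peaks of dV/dt exceeding ``k`` times
the standard deviation of dV/dt over a baseline window at the start of the
trace, and the spike threshold ("kink") is the sample of maximal d2V/dt2 in
the 4 ms preceding the dV/dt peak.  Derivatives are central finite
differences on raw samples; no smoothing is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .recording import Sweep

#: absolute dV/dt floor (mV/ms) under the adaptive k*SD rule.  Spike upstrokes
#: exceed ~100 mV/ms while passive charging transients stay below ~5 mV/ms, so
#: the floor only matters for noise-free traces where the baseline SD is 0.
MIN_DVDT_PEAK = 10.0

#: minimum separation between dV/dt peaks (ms); below any physiological ISI.
PEAK_SEPARATION_MS = 2.0

#: search window for the spike (Vm) peak after threshold (ms).
PEAK_SEARCH_MS = 5.0

#: spike-threshold search extent before the dV/dt peak (ms).
THRESH_SEARCH_MS = 4.0

#: clip window around the spike threshold (ms before, ms after).
CLIP_BEFORE_MS = 1.0
CLIP_AFTER_MS = 10.0

#: AHP trough search extent after the spike peak (ms).
AHP_WINDOW_MS = 10.0

#: regular-spiking criterion: AHP amplitude below this (mV) within the window.
RS_AHP_MAX_MV = 5.0


@dataclass(frozen=True)
class SpikeEvent:
    """One detected action potential.

    ``ahp_amplitude`` is positive when Vm undershoots the reference
    (steady-state Vm at rheobase); metrics are filled by :func:`ahp_metrics`.
    """

    peak_time: float  # ms, time of Vm maximum
    thresh_time: float  # ms, time of max d2V/dt2 before the upstroke
    thresh_vm: float  # mV
    peak_vm: float = np.nan  # mV
    ahp_amplitude: float = np.nan  # mV
    ahp_latency: float = np.nan  # ms from spike peak
    truncated: bool = False


def _dvdt(vm: np.ndarray, dt_ms: float) -> np.ndarray:
    """Central-difference first derivative (one-sided at the ends)."""
    out = np.empty_like(vm)
    out[1:-1] = (vm[2:] - vm[:-2]) * (0.5 / dt_ms)
    out[0] = (vm[1] - vm[0]) / dt_ms
    out[-1] = (vm[-1] - vm[-2]) / dt_ms
    return out


def detect_spikes(
    sweep: Sweep,
    baseline_ms: float = 100.0,
    k: float = 8.0,
    min_dvdt: float = MIN_DVDT_PEAK,
) -> list[SpikeEvent]:
    """Detect action potentials in one sweep.

    Parameters
    ----------
    sweep : Sweep
        Raw (unclipped) trace.
    baseline_ms : float
        Length of the baseline window at the start of the trace over which
        the dV/dt standard deviation is estimated.
    k : float
        Detection threshold in baseline SDs of dV/dt.
    min_dvdt : float
        Absolute floor (mV/ms) on the detection threshold; guards noise-free
        traces whose baseline SD is zero.

    Returns
    -------
    list of SpikeEvent, in time order.
    """
    dt = sweep.dt_ms
    vm = np.asarray(sweep.vm)
    nb = int(round(baseline_ms / dt))
    if nb >= vm.size:
        raise ValueError("sweep shorter than the baseline window")
    dv = _dvdt(vm, dt)

    sd = float(np.std(dv[:nb]))
    height = max(k * sd, min_dvdt)
    distance = max(int(round(PEAK_SEPARATION_MS / dt)), 1)
    peaks, _ = find_peaks(dv, height=height, distance=distance)

    # A spike inside the baseline window inflates the SD estimate; exclude it
    # and re-estimate once, warning the caller.
    if peaks.size and peaks[0] < nb and sd > 0:
        warnings.warn(
            "baseline window contains a detected event; SD re-estimated "
            "after excluding it",
            stacklevel=2,
        )
        half = int(round(CLIP_AFTER_MS / dt))
        mask = np.ones(nb, dtype=bool)
        for p in peaks[peaks < nb]:
            mask[max(p - half, 0) : min(p + half, nb)] = False
        if mask.any():
            sd = float(np.std(dv[:nb][mask]))
            height = max(k * sd, min_dvdt)
            peaks, _ = find_peaks(dv, height=height, distance=distance)

    if peaks.size == 0:
        return []

    w_thr = int(round(THRESH_SEARCH_MS / dt))
    w_pk = int(round(PEAK_SEARCH_MS / dt))

    # twice-applied central difference; evaluated around each peak only, or
    # over the whole trace when spikes are dense enough that this is cheaper
    d2v_full = _dvdt(dv, dt) if peaks.size * w_thr > vm.size else None

    events: list[SpikeEvent] = []
    last_peak_idx = -10 ** 9
    for p in peaks:
        lo = max(p - w_thr, 0)
        if d2v_full is not None:
            ti = lo + int(np.argmax(d2v_full[lo : p + 1]))
        else:
            a = max(lo - 2, 0)
            b = min(p + 3, vm.size)
            d2v_local = _dvdt(_dvdt(vm[a:b].astype(np.float64), dt), dt)
            ti = lo + int(np.argmax(d2v_local[lo - a : p + 1 - a]))
        hi = min(ti + w_pk + 1, vm.size)
        pi = ti + int(np.argmax(vm[ti:hi]))
        if pi - last_peak_idx < distance:  # duplicate within refractory window
            continue
        last_peak_idx = pi
        events.append(
            SpikeEvent(
                peak_time=pi * dt,
                thresh_time=ti * dt,
                thresh_vm=float(vm[ti]),
                peak_vm=float(vm[pi]),
            )
        )
    events.sort(key=lambda e: e.peak_time)
    return events


def clip_spikes(sweep: Sweep, events: Sequence[SpikeEvent]) -> Sweep:
    """Remove spike waveforms by linear interpolation.

    Samples from ``CLIP_BEFORE_MS`` before each spike threshold to
    ``CLIP_AFTER_MS`` after are replaced by the straight line between the
    samples bounding the (merged) window.  All subthreshold Vm statistics in
    this package consume clipped traces.
    """
    if not events:
        return sweep
    vm = np.array(sweep.vm, copy=True)
    dt = sweep.dt_ms
    n = vm.size

    windows = []
    for ev in sorted(events, key=lambda e: e.thresh_time):
        a = int(np.floor((ev.thresh_time - CLIP_BEFORE_MS) / dt))
        b = int(np.ceil((ev.thresh_time + CLIP_AFTER_MS) / dt))
        a, b = max(a, 0), min(b, n - 1)
        if windows and a <= windows[-1][1] + 1:  # merge overlapping/adjacent
            windows[-1][1] = max(windows[-1][1], b)
        else:
            windows.append([a, b])

    for a, b in windows:
        lo = max(a - 1, 0)
        hi = min(b + 1, n - 1)
        if hi == lo:
            vm[a : b + 1] = vm[lo]
        else:
            frac = (np.arange(a, b + 1) - lo) / (hi - lo)
            vm[a : b + 1] = vm[lo] + (vm[hi] - vm[lo]) * frac
    return sweep.with_vm(vm)


def ahp_metrics(
    sweep: Sweep, event: SpikeEvent, vm_ss_rheobase: float
) -> tuple[float, float, bool]:
    """After-hyperpolarization amplitude and latency for one spike.

    Amplitude is the depth of the Vm minimum within ``AHP_WINDOW_MS`` after
    the spike peak, measured relative to the steady-state Vm of the neuron at
    rheobase (may be <= 0 when there is no undershoot).  Returns
    ``(amplitude_mv, latency_ms, truncated)``; ``truncated`` flags a window
    cut short by the end of the trace.
    """
    dt = sweep.dt_ms
    pi = int(round(event.peak_time / dt))
    lo = pi + 1
    hi = int(round((event.peak_time + AHP_WINDOW_MS) / dt)) + 1
    truncated = hi > sweep.n_samples
    hi = min(hi, sweep.n_samples)
    if lo >= hi:
        return np.nan, np.nan, True
    seg = sweep.vm[lo:hi]
    mi = int(np.argmin(seg))
    amplitude = float(vm_ss_rheobase - seg[mi])
    latency = (lo + mi - pi) * dt
    return amplitude, latency, truncated


def classify_regular_spiking(
    ahp_amplitude: float, ahp_latency: float
) -> Optional[bool]:
    """Regular-spiking test on the first evoked spike at rheobase.

    True iff the AHP amplitude is < 5 mV and its trough occurs within 10 ms
    of the spike peak.  Undefined metrics return ``None`` (unclassified; such
    cells are excluded from analysis).
    """
    if not (np.isfinite(ahp_amplitude) and np.isfinite(ahp_latency)):
        return None
    return bool(ahp_amplitude < RS_AHP_MAX_MV and ahp_latency <= AHP_WINDOW_MS)


def spike_qc_report(events_by_sweep: dict, k: float, baseline_ms: float) -> dict:
    """Summary of detection results, replacing interactive verification."""
    counts = {key: len(evs) for key, evs in events_by_sweep.items()}
    amps = [
        ev.peak_vm - ev.thresh_vm
        for evs in events_by_sweep.values()
        for ev in evs
        if np.isfinite(ev.peak_vm)
    ]
    hist, edges = np.histogram(amps, bins=10) if amps else (np.array([]), np.array([]))
    return {
        "params": {"k": k, "baseline_ms": baseline_ms},
        "n_sweeps": len(events_by_sweep),
        "n_spikes": int(sum(counts.values())),
        "spikes_per_sweep": counts,
        "amplitude_hist": {
            "counts": hist.tolist(),
            "edges_mv": np.round(edges, 3).tolist(),
        },
    }
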