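"""Grating-evoked response statistics: Vm0, Vm1, F0 and responsiveness.

Per trial, the response to each direction is split into a baseline window
(final 500 ms of the static hold, before drift onset) and a stimulus-evoked
window (0.5-2.5 s after drift onset).  Vm0 is the evoked-minus-baseline mean
Vm (spike-clipped); Vm1 the peak-to-trough amplitude of the trial-averaged
evoked trace folded into one 2 Hz cycle; F0 the evoked firing rate minus the
session-wide baseline rate (may be negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .recording import GratingRecording, StimEvents, Sweep
from .spikes import SpikeEvent, clip_spikes, detect_spikes
from .tuning import TuningCurve, TuningSummary, summarize_tuning

BASELINE_S = 0.5
EVOKED_START_AFTER_DRIFT_S = 0.5
EVOKED_LEN_S = 2.0
N_FOLDS = 4  # 2 s evoked window -> four 0.5 s segments (one 2 Hz cycle)


@dataclass(frozen=True)
class TrialResponse:
    """Per-trial response measures for one (repeat, direction) sweep."""

    i: int
    theta: float
    vm_baseline: float  # mV
    vm_evoked: float  # mV
    vm0: float  # mV
    f_evoked: float  # Hz
    f0: float  # Hz


@dataclass(frozen=True)
class DirectionResponse:
    theta: float
    vm0_mean: float
    vm1: float
    f0_mean: float
    n_trials: int


@dataclass(frozen=True)
class SessionBaseline:
    """Firing rate over all baseline periods (all trials, all directions)."""

    f_baseline_bar: float  # Hz
    n_spikes: int
    total_s: float


def trial_windows(stim: StimEvents) -> tuple[tuple[float, float], tuple[float, float]]:
    """Baseline and evoked windows (s) for one trial.

    Baseline is the final 500 ms of the static hold; the evoked window runs
    0.5-2.5 s after drift onset.  Both half-open [start, end).
    """
    hold = stim.drift_onset - stim.static_onset
    if hold < BASELINE_S - 1e-12:
        raise ValueError(f"static hold {hold:.3f} s shorter than the 0.5 s baseline window")
    baseline = (stim.drift_onset - BASELINE_S, stim.drift_onset)
    evoked = (
        stim.drift_onset + EVOKED_START_AFTER_DRIFT_S,
        stim.drift_onset + EVOKED_START_AFTER_DRIFT_S + EVOKED_LEN_S,
    )
    if evoked[1] > stim.drift_offset + 1e-9:
        raise ValueError("drift period shorter than the 2.5 s the evoked window requires")
    return baseline, evoked


def _window_mean(sweep: Sweep, win_s: tuple[float, float]) -> float:
    sl = sweep.window_slice(win_s[0] * 1000.0, win_s[1] * 1000.0)
    if sl.start < 0 or sl.stop > sweep.n_samples or sl.start >= sl.stop:
        raise ValueError(f"window {win_s} s outside trace")
    return float(np.mean(sweep.vm[sl], dtype=np.float64))


def compute_vm0(clipped: Sweep, windows=None) -> tuple[float, float, float]:
    """(vm_baseline, vm_evoked, vm0) for one spike-clipped trial."""
    if windows is None:
        if clipped.stim is None:
            raise ValueError("sweep has no stimulus annotation")
        windows = trial_windows(clipped.stim)
    (b, e) = windows
    vb = _window_mean(clipped, b)
    ve = _window_mean(clipped, e)
    return vb, ve, ve - vb


def compute_vm1(clipped_trials: Sequence[Sweep], windows=None) -> float:
    """Membrane-potential modulation for one direction.

    Average the evoked-window traces across trials, fold the 2 s average
    into four 0.5 s segments and average those (one full grating cycle),
    then return max - min of the folded trace.  Assumes phase-locked trials;
    with random phase the fold cancels by design.
    """
    if not clipped_trials:
        raise ValueError("need at least one trial")
    if windows is None:
        windows = trial_windows(clipped_trials[0].stim)
    (_, e) = windows
    segs = []
    for sw in clipped_trials:
        seg = sw.vm[sw.window_slice(e[0] * 1000.0, e[1] * 1000.0)]
        segs.append(np.asarray(seg, dtype=np.float64))
    n = {s.size for s in segs}
    if len(n) != 1:
        raise ValueError("inconsistent trial lengths in evoked window")
    avg = np.mean(segs, axis=0)
    m = avg.size - avg.size % N_FOLDS
    folded = avg[:m].reshape(N_FOLDS, m // N_FOLDS).mean(axis=0)
    return float(folded.max() - folded.min())


def evoked_rate(events: Sequence[SpikeEvent], win_s: tuple[float, float]) -> float:
    """Firing rate (Hz) over a window from detected spike peak times."""
    t0, t1 = win_s[0] * 1000.0, win_s[1] * 1000.0
    n = sum(1 for ev in events if t0 <= ev.peak_time < t1)
    return n / (win_s[1] - win_s[0])


def session_baseline(events_by_trial: dict, windows_by_trial: dict) -> SessionBaseline:
    """Pooled baseline rate across all trials and directions."""
    n, total = 0, 0.0
    for key, events in events_by_trial.items():
        (b, _) = windows_by_trial[key]
        t0, t1 = b[0] * 1000.0, b[1] * 1000.0
        n += sum(1 for ev in events if t0 <= ev.peak_time < t1)
        total += b[1] - b[0]
    rate = n / total if total > 0 else 0.0
    return SessionBaseline(f_baseline_bar=rate, n_spikes=n, total_s=total)


def compute_f0(events: Sequence[SpikeEvent], windows,
               baseline: SessionBaseline) -> tuple[float, float]:
    """(f_evoked, f0) for one trial; F0 = Fevoked - pooled baseline rate."""
    (_, e) = windows
    fe = evoked_rate(events, e)
    return fe, fe - baseline.f_baseline_bar


def classify_responsive(f0_values: Sequence[float], alpha: float = 0.05,
                        use_signed: bool = False) -> tuple[bool, float]:
    """Visual responsiveness from the distribution of trial F0 values.

    A one-sample Wilcoxon signed-rank test of |F0| against zero, as the
    classification is defined; since |F0| >= 0 the test is one of whether
    any trials deviate from baseline at all.  ``use_signed=True`` tests the
    signed F0 values instead (sensitivity variant).
    """
    vals = np.asarray(f0_values, dtype=float)
    if vals.size < 12:
        warnings.warn("fewer than 12 trials for responsiveness test", stacklevel=2)
    if not use_signed:
        vals = np.abs(vals)
    if np.all(vals == 0):
        return False, 1.0
    res = sps.wilcoxon(vals, zero_method="wilcox", alternative="two-sided")
    p = float(res.pvalue)
    return bool(p < alpha), p


def baseline_tuning_check(baselines_by_direction: dict[float, Sequence[float]]) -> float:
    """One-way ANOVA p for baseline Vm differing across direction conditions.

    A control analysis: a tuned *baseline* would contaminate Vm0 tuning.
    Directions with fewer than 2 trials are dropped with a warning.
    """
    groups = []
    for theta, vals in sorted(baselines_by_direction.items()):
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            warnings.warn(f"direction {theta} deg has <2 trials; dropped from "
                          "baseline-tuning ANOVA", stacklevel=2)
            continue
        groups.append(vals)
    if len(groups) < 2:
        return 1.0
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return 1.0  # identical baselines: no evidence of tuning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.f_oneway(*groups)
    return 1.0 if np.isnan(p) else float(p)


@dataclass
class EvokedSummary:
    """Everything the evoked analysis produces for one cell."""

    trials: list[TrialResponse]
    directions: list[DirectionResponse]
    baseline: SessionBaseline
    responsive: bool
    responsive_p: float
    baseline_tuning_p: float
    curve_vm0: TuningCurve
    curve_vm1: TuningCurve
    curve_f0: TuningCurve
    tuning_vm0: Optional[TuningSummary]
    tuning_vm1: Optional[TuningSummary]
    tuning_f0: Optional[TuningSummary]
    pref_direction: float = np.nan  # spiking-preferred; Vm-preferred fallback
    pref_source: str = "none"  # "F0" | "Vm0" | "none"
    vm0_at_pref: float = np.nan
    vm1_at_pref: float = np.nan
    f0_at_pref: float = np.nan
    has_evoked_spikes: bool = False
    flags: list = field(default_factory=list)


def analyze_grating(rec: GratingRecording, baseline_ms: float = 100.0,
                    k: float = 8.0, alpha: float = 0.05,
                    use_signed_f0: bool = False) -> EvokedSummary:
    """Per-cell evoked analysis: spike detection, clipping, Vm0/Vm1/F0,
    responsiveness, baseline-tuning control and the three tuning curves.

    The preferred direction is taken from the spiking (F0) tuning; for cells
    where it is undefined (no spikes / degenerate curve) the Vm0-preferred
    direction is substituted and flagged.
    """
    flags: list[str] = []
    keys = sorted(rec.trials.keys())
    events_by_trial: dict = {}
    windows_by_trial: dict = {}
    clipped_by_trial: dict = {}
    for key in keys:
        sw = rec.trials[key]
        ev = detect_spikes(sw, baseline_ms=baseline_ms, k=k)
        events_by_trial[key] = ev
        windows_by_trial[key] = trial_windows(sw.stim)
        clipped_by_trial[key] = clip_spikes(sw, ev)

    base = session_baseline(events_by_trial, windows_by_trial)

    trials: list[TrialResponse] = []
    baselines_by_dir: dict[float, list[float]] = {}
    for key in keys:
        i, theta = key
        win = windows_by_trial[key]
        vb, ve, vm0 = compute_vm0(clipped_by_trial[key], win)
        fe, f0 = compute_f0(events_by_trial[key], win, base)
        trials.append(TrialResponse(i=i, theta=theta, vm_baseline=vb,
                                    vm_evoked=ve, vm0=vm0, f_evoked=fe, f0=f0))
        baselines_by_dir.setdefault(theta, []).append(vb)

    thetas = sorted(baselines_by_dir.keys())
    directions: list[DirectionResponse] = []
    for theta in thetas:
        sub = [t for t in trials if t.theta == theta]
        vm1 = compute_vm1([clipped_by_trial[(t.i, theta)] for t in sub])
        directions.append(DirectionResponse(
            theta=theta,
            vm0_mean=float(np.mean([t.vm0 for t in sub])),
            vm1=vm1,
            f0_mean=float(np.mean([t.f0 for t in sub])),
            n_trials=len(sub),
        ))

    responsive, p_resp = classify_responsive(
        [t.f0 for t in trials], alpha=alpha, use_signed=use_signed_f0)
    p_base = baseline_tuning_check(baselines_by_dir)

    th = np.array(thetas, dtype=float)
    curve_vm0 = TuningCurve(th, np.array([d.vm0_mean for d in directions]), "Vm0")
    curve_vm1 = TuningCurve(th, np.array([d.vm1 for d in directions]), "Vm1")
    curve_f0 = TuningCurve(th, np.array([d.f0_mean for d in directions]), "F0")

    tuning_vm0 = summarize_tuning(curve_vm0)
    tuning_vm1 = summarize_tuning(curve_vm1)
    # OSI_F0 is only defined for cells classified as responsive
    tuning_f0 = summarize_tuning(curve_f0) if responsive else None
    if responsive and tuning_f0 is None:
        flags.append("f0_tuning_undefined")

    has_spikes = any(
        any(w[1][0] * 1000.0 <= ev.peak_time < w[1][1] * 1000.0
            for ev in events_by_trial[key])
        for key, w in windows_by_trial.items()
    )

    summary = EvokedSummary(
        trials=trials, directions=directions, baseline=base,
        responsive=responsive, responsive_p=p_resp, baseline_tuning_p=p_base,
        curve_vm0=curve_vm0, curve_vm1=curve_vm1, curve_f0=curve_f0,
        tuning_vm0=tuning_vm0, tuning_vm1=tuning_vm1, tuning_f0=tuning_f0,
        has_evoked_spikes=has_spikes, flags=flags,
    )

    # responses "at the preferred direction": spiking-preferred when defined
    if tuning_f0 is not None and np.isfinite(tuning_f0.pref_direction):
        summary.pref_direction = tuning_f0.pref_direction
        summary.pref_source = "F0"
    elif tuning_vm0 is not None and np.isfinite(tuning_vm0.pref_direction):
        summary.pref_direction = tuning_vm0.pref_direction
        summary.pref_source = "Vm0"
        flags.append("vm_preferred_substituted")
    if np.isfinite(summary.pref_direction):
        j = int(np.argmin(np.abs(th - summary.pref_direction)))
        summary.vm0_at_pref = float(curve_vm0.r[j])
        summary.vm1_at_pref = float(curve_vm1.r[j])
        summary.f0_at_pref = float(curve_f0.r[j])
    return summary
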