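import numpy as np
import pytest

from vcephys import (SpikeEvent, StimEvents, Sweep, baseline_tuning_check,
                     classify_responsive, compute_f0, compute_vm0,
                     compute_vm1, trial_windows)
from vcephys.evoked import SessionBaseline, analyze_grating
from vcephys.synth import CellGroundTruth, simulate_grating_recording

FS = 10000.0


def _stim(static=0.0, drift=2.0, off=4.5, theta=0.0):
    return StimEvents(direction_deg=theta, static_onset=static,
                      drift_onset=drift, drift_offset=off)


def _trial_sweep(fn, duration_s=4.5, fs=FS, stim=None):
    """Sweep whose Vm is fn(t_seconds)."""
    t = np.arange(int(duration_s * fs)) / fs
    return Sweep(vm=fn(t), fs=fs, stim=stim or _stim())


# --- windows ----------------------------------------------------------------

def test_trial_windows_standard_protocol():
    b, e = trial_windows(_stim(static=0.0, drift=2.0))
    assert b == (1.5, 2.0)
    assert e == (2.5, 4.5)


def test_trial_windows_translate_with_drift_onset():
    b, e = trial_windows(_stim(static=1.0, drift=3.0, off=5.5))
    assert b == (2.5, 3.0)
    assert e == (3.5, 5.5)


def test_short_hold_rejected():
    with pytest.raises(ValueError, match="hold"):
        trial_windows(_stim(static=1.6, drift=2.0))


def test_short_drift_rejected():
    with pytest.raises(ValueError, match="drift"):
        trial_windows(_stim(static=0.0, drift=2.0, off=4.0))


# --- Vm0 --------------------------------------------------------------------

def test_vm0_constant_windows():
    sw = _trial_sweep(lambda t: np.where(t < 2.0, -70.0, -60.0))
    vb, ve, vm0 = compute_vm0(sw)
    assert (vb, ve, vm0) == (-70.0, -60.0, 10.0)


def test_vm0_ignores_integer_cycle_modulation():
    """A 2 Hz sinusoid integrates out of the 2 s evoked window exactly."""
    sw = _trial_sweep(
        lambda t: np.where(t < 2.0, -70.0,
                           -60.0 + 5.0 * np.sin(2 * np.pi * 2.0 * (t - 2.0))))
    _, _, vm0 = compute_vm0(sw)
    assert vm0 == pytest.approx(10.0, abs=1e-9)


def test_vm0_windows_outside_trace_rejected():
    sw = _trial_sweep(lambda t: np.full_like(t, -70.0), duration_s=3.0,
                      stim=_stim(off=3.0))
    with pytest.raises(ValueError):
        compute_vm0(sw, windows=((1.5, 2.0), (2.5, 4.5)))


# --- Vm1 --------------------------------------------------------------------

def test_vm1_single_sinusoidal_trial():
    sw = _trial_sweep(
        lambda t: -65.0 + np.where(t >= 2.0,
                                   4.0 * np.sin(2 * np.pi * 2.0 * (t - 2.0)),
                                   0.0))
    assert compute_vm1([sw]) == pytest.approx(8.0, rel=1e-6)


def test_vm1_constant_trace_is_zero():
    sw = _trial_sweep(lambda t: np.full_like(t, -64.0))
    assert compute_vm1([sw]) == 0.0


def test_vm1_noisy_phase_locked_trials():
    """15 phase-locked trials with 2 mV white noise: the folded average
    recovers the 8 mV modulation (its 2 Hz Fourier amplitude within 0.5 mV),
    while the max-minus-min readout carries its known positive extreme-value
    bias, bounded by 2 * sigma_f * sqrt(2 ln n) above the true value."""
    rng = np.random.default_rng(6)
    sigma = 2.0
    n_trials = 15
    trials = [
        _trial_sweep(lambda t: -65.0 + np.where(
            t >= 2.0, 4.0 * np.sin(2 * np.pi * 2.0 * (t - 2.0)), 0.0)
            + sigma * rng.standard_normal(t.size))
        for _ in range(n_trials)
    ]
    vm1 = compute_vm1(trials)
    # folded-average per-sample noise and number of folded samples
    n_fold = int(0.5 * FS)
    sigma_f = sigma / np.sqrt(4 * n_trials)
    bias_bound = 2.0 * sigma_f * np.sqrt(2.0 * np.log(n_fold))
    assert 8.0 - 0.2 <= vm1 <= 8.0 + bias_bound

    segs = [sw.vm[sw.window_slice(2500.0, 4500.0)] for sw in trials]
    folded = np.mean(segs, axis=0).reshape(4, -1).mean(axis=0)
    t = np.arange(folded.size) / FS
    fourier_amp = 2.0 * np.abs(
        2.0 * np.mean(folded * np.exp(-2j * np.pi * 2.0 * t)))
    assert fourier_amp == pytest.approx(8.0, abs=0.5)


def test_vm1_invariant_to_offset_and_trial_order():
    rng = np.random.default_rng(7)
    base = [
        _trial_sweep(lambda t: -65.0 + np.where(
            t >= 2.0, 3.0 * np.sin(2 * np.pi * 2.0 * (t - 2.0)), 0.0)
            + rng.standard_normal(t.size))
        for _ in range(5)
    ]
    shifted = [sw.with_vm(sw.vm + 11.5) for sw in base]
    assert compute_vm1(base) == pytest.approx(compute_vm1(shifted), abs=1e-9)
    assert compute_vm1(base) == pytest.approx(compute_vm1(base[::-1]), abs=1e-12)


def test_vm1_inconsistent_lengths_rejected():
    a = _trial_sweep(lambda t: np.full_like(t, -65.0))
    b = _trial_sweep(lambda t: np.full_like(t, -65.0), fs=5000.0)
    with pytest.raises(ValueError, match="inconsistent"):
        compute_vm1([a, b])


# --- F0 ---------------------------------------------------------------------

def _events(times_ms):
    return [SpikeEvent(peak_time=t, thresh_time=t - 1.0, thresh_vm=-40.0)
            for t in times_ms]


def test_f0_from_counts():
    """6 spikes in the 2 s evoked window against a 1 Hz session baseline."""
    windows = trial_windows(_stim())
    ev = _events([2600.0, 2700.0, 2900.0, 3200.0, 3900.0, 4400.0])
    fe, f0 = compute_f0(ev, windows, SessionBaseline(1.0, 0, 0.0))
    assert fe == pytest.approx(3.0) and f0 == pytest.approx(2.0)


def test_f0_no_spikes_zero_baseline():
    windows = trial_windows(_stim())
    fe, f0 = compute_f0([], windows, SessionBaseline(0.0, 0, 0.0))
    assert fe == 0.0 and f0 == 0.0


def test_f0_can_be_negative():
    windows = trial_windows(_stim())
    _, f0 = compute_f0([], windows, SessionBaseline(1.5, 3, 2.0))
    assert f0 == -1.5


# --- responsiveness ---------------------------------------------------------

def test_all_zero_f0_not_responsive():
    assert classify_responsive([0.0] * 24) == (False, 1.0)


def test_responsiveness_power_on_strong_cells():
    """Cells with 5 Hz evoked vs 0.5 Hz baseline rates are classified
    responsive in >= 95% of seeded sessions."""
    rng = np.random.default_rng(10)
    hits = 0
    n_runs = 100
    for _ in range(n_runs):
        f_evoked = rng.poisson(5.0 * 2.0, 120) / 2.0
        f0 = f_evoked - 0.5
        responsive, _ = classify_responsive(f0)
        hits += responsive
    assert hits >= 95


def test_f0_linearity_pools_exactly():
    """Mean F0 over all trials equals overall evoked rate minus baseline."""
    gt = CellGroundTruth(noise_sd=0.5, theta_pref=90.0)
    ev = analyze_grating(simulate_grating_recording(gt, T=4, fs=FS, seed=3))
    mean_f0 = np.mean([t.f0 for t in ev.trials])
    mean_fe = np.mean([t.f_evoked for t in ev.trials])
    assert mean_f0 == pytest.approx(mean_fe - ev.baseline.f_baseline_bar,
                                    abs=1e-9)


def test_zero_gain_cell_not_responsive_and_no_f0_tuning():
    gt = CellGroundTruth(noise_sd=0.3, r_max=1e-9)
    ev = analyze_grating(simulate_grating_recording(gt, T=3, fs=FS, seed=2))
    assert not ev.responsive
    assert ev.tuning_f0 is None
    assert not ev.has_evoked_spikes
    assert ev.pref_source == "Vm0"  # Vm-preferred substituted, flagged
    assert "vm_preferred_substituted" in ev.flags


# --- baseline tuning control ------------------------------------------------

def test_identical_baselines_report_p_one():
    groups = {th: [-70.0] * 5 for th in range(0, 360, 30)}
    assert baseline_tuning_check(groups) == 1.0


def test_baseline_shift_detected_with_power():
    """A +5 mV baseline shift for one orientation pair is detected in
    >= 95% of seeded runs at sigma = 1 mV, T = 10."""
    rng = np.random.default_rng(12)
    hits = 0
    for _ in range(100):
        groups = {th: list(-70.0 + rng.standard_normal(10))
                  for th in range(0, 360, 30)}
        groups[90] = list(-65.0 + rng.standard_normal(10))
        groups[270] = list(-65.0 + rng.standard_normal(10))
        hits += baseline_tuning_check(groups) < 0.05
    assert hits >= 95


def test_single_trial_direction_dropped_with_warning():
    groups = {th: list(np.random.default_rng(th).normal(-70, 1, 5))
              for th in range(0, 360, 30)}
    groups[30] = [-70.0]
    with pytest.warns(UserWarning, match="dropped"):
        p = baseline_tuning_check(groups)
    assert 0.0 <= p <= 1.0
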