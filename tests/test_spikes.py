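import numpy as np
import pytest

from vcephys import (CellGroundTruth, SpikeEvent, Sweep, ahp_metrics,
                     classify_regular_spiking, clip_spikes, detect_spikes)
from vcephys.synth import spike_template
from vcephys.validation import detection_score, make_spiking_trace

FS = 10000.0


def test_constant_trace_has_no_events(make_flat_sweep):
    assert detect_spikes(make_flat_sweep(-75.0)) == []


def test_three_inserted_spikes_found_with_accurate_thresholds(rng):
    """Template spikes at 200/500/800 ms on a noisy baseline are all found,
    with threshold times at the template kink."""
    gt = CellGroundTruth(noise_sd=0.3)
    sweep = make_spiking_trace(gt, [200.0, 500.0, 800.0], 1000.0, FS, rng)
    events = detect_spikes(sweep)
    assert len(events) == 3
    for ev, truth in zip(events, [200.0, 500.0, 800.0]):
        assert abs(ev.thresh_time - truth) <= 0.2
        assert abs(ev.thresh_vm - gt.rmp) <= 1.5  # kink voltage ~ baseline


@pytest.mark.parametrize("fs", [10000.0, 25000.0])
def test_threshold_voltage_matches_template_kink(fs):
    """On noiseless template spikes the detected threshold voltage equals
    the configured kink voltage to within 1 mV at 10 and 25 kHz."""
    gt = CellGroundTruth(noise_sd=0.0)
    rng = np.random.default_rng(0)
    sweep = make_spiking_trace(gt, [300.0, 700.0], 1000.0, fs, rng)
    events = detect_spikes(sweep)
    assert len(events) == 2
    for ev in events:
        assert abs(ev.thresh_vm - gt.rmp) <= 1.0


def test_subthreshold_epsp_not_detected(rng):
    """A 2 mV EPSP-like bump with a 10 ms rise stays far below 8x the
    baseline dV/dt SD."""
    n = int(FS)
    t = np.arange(n) / FS * 1000.0
    bump = 2.0 * np.exp(-0.5 * ((t - 500.0) / 10.0) ** 2)
    vm = -75.0 + bump + 0.3 * rng.standard_normal(n)
    assert detect_spikes(Sweep(vm=vm, fs=FS)) == []


def test_baseline_spike_triggers_warning_and_still_detects(rng):
    gt = CellGroundTruth(noise_sd=0.3)
    sweep = make_spiking_trace(gt, [50.0, 500.0], 1000.0, FS, rng)
    with pytest.warns(UserWarning, match="baseline window"):
        events = detect_spikes(sweep)
    assert len(events) == 2


def test_detection_f1_perfect_at_moderate_noise():
    """F1 = 1.0 over 40 seeded traces at 0.5 mV noise (both rates)."""
    for fs in (10000.0, 25000.0):
        score = detection_score(n_traces=40, noise_sd=0.5, fs=fs, seed=11)
        assert score["f1"] == 1.0


# --- clipping ---------------------------------------------------------------

def test_clip_no_events_is_identity(make_flat_sweep):
    sw = make_flat_sweep(-60.0)
    assert clip_spikes(sw, []) is sw


def test_clip_single_spike_on_flat_trace_restores_flat():
    gt = CellGroundTruth(noise_sd=0.0)
    rng = np.random.default_rng(0)
    sweep = make_spiking_trace(gt, [500.0], 1000.0, FS, rng)
    events = detect_spikes(sweep)
    clipped = clip_spikes(sweep, events)
    np.testing.assert_allclose(clipped.vm, gt.rmp, atol=1e-9)


def test_clip_windows_merge_and_interpolate_between_outer_samples():
    """Two events 6 ms apart produce one merged window whose interpolant
    runs between the pre-first and post-second boundary samples."""
    fs = 1000.0  # 1 ms per sample: hand-checkable
    vm = np.sin(np.arange(40) * 0.7) * 5.0 - 60.0
    sw = Sweep(vm=vm.copy(), fs=fs)
    ev = [SpikeEvent(peak_time=6.0, thresh_time=5.0, thresh_vm=0.0),
          SpikeEvent(peak_time=12.0, thresh_time=11.0, thresh_vm=0.0)]
    clipped = clip_spikes(sw, ev)
    a, b = 4, 21  # [5-1, 11+10] ms at 1 kHz
    lo, hi = a - 1, b + 1
    expected = vm.copy()
    expected[a:b + 1] = vm[lo] + (vm[hi] - vm[lo]) * \
        (np.arange(a, b + 1) - lo) / (hi - lo)
    np.testing.assert_allclose(clipped.vm, expected)


def test_clip_is_idempotent(rng):
    gt = CellGroundTruth(noise_sd=0.4)
    sweep = make_spiking_trace(gt, [300.0, 600.0], 1000.0, FS, rng)
    events = detect_spikes(sweep)
    once = clip_spikes(sweep, events)
    twice = clip_spikes(once, events)
    np.testing.assert_array_equal(once.vm, twice.vm)


def test_clip_window_clamped_at_trace_end():
    gt = CellGroundTruth(noise_sd=0.0)
    rng = np.random.default_rng(0)
    sweep = make_spiking_trace(gt, [995.0], 1000.0, FS, rng)
    ev = [SpikeEvent(peak_time=996.0, thresh_time=995.0, thresh_vm=gt.rmp)]
    clipped = clip_spikes(sweep, ev)
    assert clipped.n_samples == sweep.n_samples


# --- AHP metrics and RS classification --------------------------------------

def _dip_sweep(dip_mv, dip_at_ms, fs=FS):
    """Flat -60 mV trace with a spike-like peak at 500 ms and a smooth dip
    of ``dip_mv`` below -60 centred ``dip_at_ms`` after the peak."""
    n = int(fs)
    t = np.arange(n) / fs * 1000.0
    vm = np.full(n, -60.0)
    vm += 40.0 * np.exp(-0.5 * ((t - 500.0) / 0.3) ** 2)
    vm -= dip_mv * np.exp(-0.5 * ((t - 500.0 - dip_at_ms) / 1.0) ** 2)
    return Sweep(vm=vm, fs=fs)


def test_ahp_amplitude_and_latency_from_dip():
    sweep = _dip_sweep(3.0, 4.0)
    ev = SpikeEvent(peak_time=500.0, thresh_time=499.0, thresh_vm=-60.0)
    amp, lat, truncated = ahp_metrics(sweep, ev, vm_ss_rheobase=-60.0)
    assert amp == pytest.approx(3.0, abs=0.01)
    assert lat == pytest.approx(4.0, abs=0.2)
    assert not truncated


def test_monotone_decay_gives_nonpositive_amplitude():
    sweep = _dip_sweep(0.0, 4.0)
    ev = SpikeEvent(peak_time=500.0, thresh_time=499.0, thresh_vm=-60.0)
    amp, _, _ = ahp_metrics(sweep, ev, vm_ss_rheobase=-60.0)
    assert amp <= 0.0


def test_dip_outside_10ms_window_ignored():
    sweep = _dip_sweep(5.0, 12.0)
    ev = SpikeEvent(peak_time=500.0, thresh_time=499.0, thresh_vm=-60.0)
    amp, _, _ = ahp_metrics(sweep, ev, vm_ss_rheobase=-60.0)
    assert amp < 4.0  # the 12 ms dip is not reached within the window


@pytest.mark.parametrize(
    "amp,lat,expected",
    [(3.0, 4.0, True), (8.0, 3.0, False), (3.0, 12.0, False),
     (4.99, 10.0, True), (5.0, 4.0, False)],
)
def test_regular_spiking_criterion(amp, lat, expected):
    assert classify_regular_spiking(amp, lat) is expected


def test_undefined_metrics_are_unclassified():
    assert classify_regular_spiking(np.nan, 4.0) is None


def test_template_fits_inside_clip_window():
    """The pasted spike waveform ends exactly at the clip boundary, so
    clipping removes a spike without residue."""
    gt = CellGroundTruth()
    for fs in (10000.0, 25000.0):
        tmpl = spike_template(gt, fs, with_recovery=True)
        assert tmpl.size <= int(round(10.0 * fs / 1000.0)) + 1
        assert abs(tmpl[-1]) < 1e-9
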