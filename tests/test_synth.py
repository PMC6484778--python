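import numpy as np
import pytest

from vcephys import (CellGroundTruth, CohortSpec, TuningCurve,
                     analytic_rheobase, osi, simulate_cohort,
                     simulate_grating_recording, simulate_iv_recording)
from vcephys.evoked import trial_windows
from vcephys.intrinsic import extract_intrinsic_features, steady_state_vm
from vcephys.recording import DIRECTIONS_DEG
from vcephys.spikes import clip_spikes, detect_spikes
from vcephys.synth import draw_ground_truth, simulate_iv_sweep


def test_ohms_law_plateau():
    """-200 pA through 50 MOhm hyperpolarizes a -70 mV cell to exactly -80."""
    gt = CellGroundTruth(rmp=-70.0, r_hyp=50.0, r_dep=50.0, noise_sd=0.0)
    sweep, spikes = simulate_iv_sweep(gt, -200.0, fs=10000.0)
    assert spikes == []
    assert steady_state_vm(sweep) == pytest.approx(-80.0, abs=1e-9)


def test_first_spiking_sweep_at_closed_form_rheobase():
    """rmp -75, r_dep 100 MOhm, threshold -45: a 30 mV climb needs >= 300 pA
    in 25 pA steps (closed-form V_inf = rmp + I*R)."""
    gt = CellGroundTruth(rmp=-75.0, r_hyp=60.0, r_dep=100.0, v_thresh=-45.0,
                         noise_sd=0.0)
    assert analytic_rheobase(gt) == 300.0
    iv = simulate_iv_recording(gt, fs=10000.0, seed=0)
    spiking = [s.i_inj for j, s in enumerate(iv.sweeps)
               if iv.meta["spike_times_ms"][j]]
    assert min(spiking) == 300.0


def test_same_seed_bit_identical():
    gt = CellGroundTruth(noise_sd=0.5)
    a = simulate_iv_recording(gt, fs=10000.0, seed=9)
    b = simulate_iv_recording(gt, fs=10000.0, seed=9)
    for sa, sb in zip(a.sweeps, b.sweeps):
        np.testing.assert_array_equal(sa.vm, sb.vm)
    ga = simulate_grating_recording(gt, T=3, fs=10000.0, seed=9)
    gb = simulate_grating_recording(gt, T=3, fs=10000.0, seed=9)
    for key in ga.trials:
        np.testing.assert_array_equal(ga.trials[key].vm, gb.trials[key].vm)


def test_unmodulated_noiseless_drift_window_is_constant():
    """With a1 = 0 and no noise, the drift-window trace sits at rmp + a0."""
    gt = CellGroundTruth(a1_peak=0.0, noise_sd=0.0, r_max=1e-9, kappa=2.0)
    rec = simulate_grating_recording(gt, T=2, fs=10000.0, seed=0)
    for (i, theta), sw in rec.trials.items():
        _, evoked = trial_windows(sw.stim)
        seg = sw.vm[sw.window_slice(evoked[0] * 1e3, evoked[1] * 1e3)]
        np.testing.assert_allclose(seg, gt.rmp + gt.a0(theta), atol=1e-4)


def test_flat_tuning_gives_zero_osi():
    """kappa = 0 makes a0 identical across directions and OSI exactly 0."""
    gt = CellGroundTruth(kappa=0.0, asym=0.0, noise_sd=0.0)
    a0 = gt.a0(np.array(DIRECTIONS_DEG, dtype=float))
    assert np.ptp(a0) == 0.0
    val, clamped = osi(TuningCurve(np.array(DIRECTIONS_DEG, float), a0))
    assert val == pytest.approx(0.0, abs=1e-12) and not clamped


def test_noiseless_recovery_is_exact():
    """With no noise and no spikes, every stage recovers the generative
    parameters: Vm_ss, R(I), Vm0 = a0, Vm1 = 2 a1."""
    gt = CellGroundTruth(rmp=-76.8, r_hyp=50.0, r_dep=90.0, noise_sd=0.0,
                         r_max=1e-9, theta_pref=210.0, kappa=1.5, asym=0.3)
    iv = simulate_iv_recording(gt, fs=10000.0, seed=0)
    feats = extract_intrinsic_features(iv)
    assert feats.rmp == pytest.approx(gt.rmp, abs=1e-9)
    assert feats.r_in_hyp == pytest.approx(50.0, abs=1e-9)
    assert feats.r_in_dep == pytest.approx(90.0, abs=1e-9)
    assert feats.rheobase == analytic_rheobase(gt)

    from vcephys.evoked import analyze_grating
    ev = analyze_grating(simulate_grating_recording(gt, T=2, fs=10000.0, seed=0))
    for d in ev.directions:
        assert d.vm0_mean == pytest.approx(gt.a0(d.theta), abs=1e-4)
        assert d.vm1 == pytest.approx(2.0 * gt.a1(d.theta), abs=1e-4)


def test_intrinsic_estimates_unbiased_under_noise():
    """Mean error of rmp and r_hyp over many noisy cells within 2 SE of 0."""
    children = np.random.SeedSequence(21).spawn(120)
    e_rmp, e_rhyp = [], []
    for child in children:
        rng = np.random.default_rng(child)
        gt = draw_ground_truth("control", rng)
        iv = simulate_iv_recording(
            gt, protocol=[-400, -200, 0], fs=10000.0, rng=rng)
        zero = clip_spikes(iv.sweeps[2], detect_spikes(iv.sweeps[2]))
        hyp = clip_spikes(iv.sweeps[1], detect_spikes(iv.sweeps[1]))
        rmp_hat = steady_state_vm(zero)
        e_rmp.append(rmp_hat - gt.rmp)
        e_rhyp.append((steady_state_vm(hyp) - rmp_hat) / -200.0 * 1e3 - gt.r_hyp)
    for errs in (np.asarray(e_rmp), np.asarray(e_rhyp)):
        se = errs.std(ddof=1) / np.sqrt(errs.size)
        assert abs(errs.mean()) <= 2.0 * se


def test_modulation_amplitude_unbiased_by_fourier():
    """The generated 2 Hz modulation has amplitude a1: the Fourier amplitude
    of the folded trial-average recovers it without the max-min bias."""
    children = np.random.SeedSequence(31).spawn(80)
    errs = []
    for child in children:
        rng = np.random.default_rng(child)
        gt = draw_ground_truth("control", rng)
        rec = simulate_grating_recording(gt, T=4, fs=10000.0, rng=rng)
        theta = gt.theta_pref
        segs = []
        for sw in rec.trials_for_direction(theta):
            sw = clip_spikes(sw, detect_spikes(sw))
            _, evoked = trial_windows(sw.stim)
            seg = sw.vm[sw.window_slice(evoked[0] * 1e3, evoked[1] * 1e3)]
            segs.append(np.asarray(seg, dtype=np.float64))
        avg = np.mean(segs, axis=0)
        folded = avg.reshape(4, -1).mean(axis=0)
        t = np.arange(folded.size) / 10000.0
        z = 2.0 * np.mean(folded * np.exp(-2j * np.pi * 2.0 * t))
        errs.append(abs(z) - gt.a1(theta))
    errs = np.asarray(errs)
    se = errs.std(ddof=1) / np.sqrt(errs.size)
    assert abs(errs.mean()) <= max(2.0 * se, 0.01)


def test_zero_spread_cohort_is_deterministic_at_medians():
    """Point-mass distributions give every cell exactly the configured
    parameters, identically across seeds."""
    dists = {
        cond: {
            "rmp": (("fixed", -76.8 if cond == "control" else -71.6), None),
            "rest_to_threshold": (("fixed", 49.1), None),
            "r_hyp": (("fixed", 51.4), None),
            "r_dep": (("fixed", 87.0), None),
            "a0_peak": (("fixed", 11.2), None),
            "a1_peak": (("fixed", 5.5), None),
            "noise_sd": (("fixed", 0.0), None),
            "r_max": (("fixed", 1e-9), None),
        }
        for cond in ("control", "deprived")
    }
    spec = CohortSpec(n_control=1, n_deprived=1, seed=5, n_repeats=1,
                      field_dists=dists)
    cells = simulate_cohort(spec)
    assert cells[0].ground_truth.rmp == -76.8
    assert cells[1].ground_truth.rmp == -71.6
    for rec in cells:
        assert rec.ground_truth.v_thresh == rec.ground_truth.rmp + 49.1
        feats = extract_intrinsic_features(rec.iv)
        assert feats.rmp == pytest.approx(rec.ground_truth.rmp, abs=1e-9)


def test_different_seeds_same_population_distributions():
    """Two seeds give different draws but matching distributional summaries
    within Monte-Carlo error."""
    rng_a = np.random.default_rng(1)
    rng_b = np.random.default_rng(2)
    a = np.array([draw_ground_truth("control", rng_a).rmp for _ in range(400)])
    b = np.array([draw_ground_truth("control", rng_b).rmp for _ in range(400)])
    assert not np.array_equal(a, b)
    # medians agree within ~3 combined standard errors of the median
    se = 1.25 * a.std() / np.sqrt(a.size) * np.sqrt(2)
    assert abs(np.median(a) - np.median(b)) < 3 * se


def test_cohort_ground_truth_shifts_match_configuration():
    rng = np.random.default_rng(3)
    ctrl = [draw_ground_truth("control", rng) for _ in range(300)]
    depr = [draw_ground_truth("deprived", rng) for _ in range(300)]
    med = lambda xs: float(np.median(xs))
    assert med([g.rmp for g in depr]) - med([g.rmp for g in ctrl]) == \
        pytest.approx(5.2, abs=1.5)
    assert med([g.r_dep for g in depr]) / med([g.r_dep for g in ctrl]) == \
        pytest.approx(104.7 / 87.0, rel=0.1)
    assert med([g.a1_peak for g in depr]) / med([g.a1_peak for g in ctrl]) == \
        pytest.approx(0.65, rel=0.15)


def test_rejects_bad_arguments():
    with pytest.raises(ValueError):
        simulate_grating_recording(CellGroundTruth(), T=0, seed=0)
    with pytest.raises(ValueError):
        simulate_iv_recording(CellGroundTruth(), fs=2000.0, seed=0)
    with pytest.raises(ValueError):
        CellGroundTruth(r_hyp=100.0, r_dep=50.0)
    with pytest.raises(ValueError):
        CohortSpec(n_control=0, n_deprived=0)
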