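"""Seeded synthetic whole-cell recordings with exact ground truth.

The generator emulates the statistical structure the analysis assumes for
mouse V1 layer 2/3 regular-spiking cells recorded in vivo:

* a passive membrane with rectifying input resistance (``r_dep >= r_hyp``)
  charging exponentially toward ``rmp + I*R(I)`` during square current steps;
* stereotyped spike waveforms inserted as templates (raised-cosine upstroke
  from the threshold "kink" to the peak, raised-cosine fall to the AHP
  trough, exponential recovery), so threshold/peak/AHP ground truth is exact;
* grating-evoked subthreshold responses: a tuned mean depolarization
  ``a0(theta)`` plus a 2 Hz sinusoidal modulation of amplitude ``a1(theta)``
  during the drift period, with a von Mises tuning profile in doubled-angle
  space and a multiplicative direction asymmetry;
* evoked spiking as an inhomogeneous Poisson process whose rate follows the
  deterministic Vm through an exponential escape-rate transfer
  ``r_max * exp((Vm - v_thresh)/dv_escape)`` (a linear-rectified transfer is
  available via ``transfer="linear"``), with a 5 ms refractory period
  enforced by thinning.

All randomness flows from one root seed through per-cell substreams, so any
cell and any cohort is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .recording import DIRECTIONS_DEG, GratingRecording, IVRecording, StimEvents, Sweep

REFRACTORY_MS = 5.0
ONSET_RAMP_MS = 50.0  # smooth rise of the evoked envelope at drift onset
TEMPORAL_FREQ_HZ = 2.0
CLIP_SPAN_MS = 10.0  # spike-clip extent after threshold; templates fit inside


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGroundTruth:
    """Generative parameters of one synthetic cell.

    Voltages in mV, resistances in MOhm, times in ms, rates in Hz.
    ``gain`` (Hz/mV) is used by the linear-rectified transfer; ``r_max`` (Hz)
    and ``dv_escape`` (mV) by the default exponential escape transfer.
    """

    rmp: float = -76.8
    r_hyp: float = 51.4
    r_dep: float = 87.0
    tau_m: float = 20.0
    v_thresh: float = -27.7
    # spike template
    rise_ms: float = 0.6
    peak_amp: float = 55.0  # mV above threshold
    ahp_depth: float = 3.0  # mV below threshold at the trough
    ahp_latency: float = 4.0  # ms, spike peak -> AHP trough
    decay_ms: float = 2.0  # AHP recovery time constant (template insertion)
    # evoked-response parameters
    a0_peak: float = 11.2  # mV, evoked mean depolarization at preferred
    a1_peak: float = 5.5  # mV, 2 Hz modulation amplitude at preferred
    kappa: float = 1.5  # von Mises concentration (doubled-angle space)
    theta_pref: float = 0.0  # deg
    asym: float = 0.25  # direction asymmetry (0 = orientation-only tuning)
    # spiking transfer
    transfer: str = "escape"  # "escape" | "linear"
    r_max: float = 220.0  # Hz (escape transfer ceiling)
    dv_escape: float = 8.0  # mV
    gain: float = 5.0  # Hz/mV (linear transfer)
    noise_sd: float = 0.5  # mV, white Gaussian recording noise
    condition: str = "control"

    def __post_init__(self) -> None:
        if not (self.r_dep >= self.r_hyp > 0):
            raise ValueError("require r_dep >= r_hyp > 0")
        if self.a0_peak < 0 or self.a1_peak < 0:
            raise ValueError("a0_peak and a1_peak must be >= 0")
        if self.kappa < 0 or self.noise_sd < 0:
            raise ValueError("kappa and noise_sd must be >= 0")
        if not 0 <= self.theta_pref < 360:
            raise ValueError("theta_pref must lie in [0, 360)")
        if self.transfer not in ("escape", "linear"):
            raise ValueError("transfer must be 'escape' or 'linear'")

    # -- tuning profile ----------------------------------------------------
    def tuning_weight(self, theta_deg) -> np.ndarray:
        """Normalized tuning profile, 1 at ``theta_pref``.

        Von Mises in the doubled angle (orientation tuning) times a
        ``(1 + asym*cos(dtheta))`` direction factor, renormalized so the
        peak stays at 1.
        """
        d = np.deg2rad(np.asarray(theta_deg, dtype=float) - self.theta_pref)
        orient = np.exp(self.kappa * (np.cos(2 * d) - 1.0))
        direction = (1.0 + self.asym * np.cos(d)) / (1.0 + self.asym)
        return orient * direction

    def a0(self, theta_deg):
        return self.a0_peak * self.tuning_weight(theta_deg)

    def a1(self, theta_deg):
        return self.a1_peak * self.tuning_weight(theta_deg)

    @property
    def rest_to_threshold(self) -> float:
        return self.v_thresh - self.rmp

    def firing_rate(self, vm) -> np.ndarray:
        """Instantaneous rate (Hz) from deterministic (spike-free) Vm."""
        vm = np.asarray(vm, dtype=float)
        if self.transfer == "linear":
            return self.gain * np.maximum(vm - self.v_thresh, 0.0)
        z = np.minimum((vm - self.v_thresh) / self.dv_escape, 4.0)
        return self.r_max * np.exp(z)


def default_iv_protocol(gt: CellGroundTruth, step_ms: float = 1000.0,
                        coverage: float = 1.5, max_pa: float = 2000.0) -> list[float]:
    """Standard IV protocol: -400:+50:0 pA then +25 pA increments up to
    ``coverage`` times the cell's analytic rheobase (capped)."""
    rheo = analytic_rheobase(gt, step_ms=step_ms)
    top = max_pa if rheo is None else min(math.ceil(coverage * rheo / 25.0) * 25.0, max_pa)
    neg = list(np.arange(-400.0, 0.0, 50.0))
    pos = list(np.arange(25.0, top + 12.5, 25.0))
    return neg + [0.0] + pos


CROSS_EPS_MV = 1e-9  # a step whose asymptote touches threshold counts as
#                      spiking once Vm is within this margin of v_thresh


def _crossing_time_ms(gt: CellGroundTruth, v0: float, v_inf: float) -> float:
    """Time for exponential charge from v0 toward v_inf to come within
    ``CROSS_EPS_MV`` of threshold; inf if it never does."""
    gap = v_inf - (gt.v_thresh - CROSS_EPS_MV)
    if gap <= 0 or v_inf <= v0:
        return math.inf
    return gt.tau_m * math.log((v_inf - v0) / gap)


def analytic_rheobase(gt: CellGroundTruth, step_ms: float = 1000.0,
                      increment: float = 25.0, max_pa: float = 5000.0) -> Optional[float]:
    """First positive step (multiple of ``increment``) whose exponential
    charge toward ``rmp + I*r_dep`` reaches threshold within the step.

    A step whose asymptote equals threshold exactly (the closed-form
    V_inf = rmp + I*R boundary case) counts as spiking, provided the
    epsilon-crossing occurs inside the step."""
    i = increment
    while i <= max_pa:
        v_inf = gt.rmp + i * gt.r_dep * 1e-3
        if _crossing_time_ms(gt, gt.rmp, v_inf) <= step_ms:
            return i
        i += increment
    return None


# ---------------------------------------------------------------------------
# spike templates
# ---------------------------------------------------------------------------

def _upstroke(t: np.ndarray, rise_ms: float, peak: float) -> np.ndarray:
    """Upstroke 0 -> peak: linear ramp to 80% amplitude, concave cubic cap.

    The onset is a genuine corner (instantaneous acceleration), so the
    discrete d2V/dt2 is strictly maximal at the kink sample itself at any
    sampling rate and dominates baseline noise by an order of magnitude;
    the cap is concave throughout, so no later sample competes.
    """
    t1 = rise_ms / 1.5  # linear phase; the cap takes the remaining third
    s = 0.8 * peak / t1
    w = np.empty_like(t, dtype=np.float64)
    lin = t <= t1 + 1e-12
    w[lin] = s * t[lin]
    tau = (t[~lin] - t1) / (rise_ms - t1)
    m0 = s * (rise_ms - t1)
    w[~lin] = (
        0.8 * peak * (2 * tau**3 - 3 * tau**2 + 1)
        + m0 * (tau**3 - 2 * tau**2 + tau)
        + peak * (-2 * tau**3 + 3 * tau**2)
    )
    return w


def spike_template(gt: CellGroundTruth, fs: float, with_recovery: bool = True
                   ) -> np.ndarray:
    """Spike waveform relative to the threshold-kink voltage.

    Index 0 is the kink (value 0).  The upstroke starts with a parabolic
    (constant-acceleration) segment, so the discrete d2V/dt2 is maximal at
    the kink sample itself at any sampling rate, then completes to
    ``peak_amp`` with a concave cubic; the downstroke is a raised cosine to
    ``-ahp_depth`` at ``ahp_latency`` after the peak, followed (optionally)
    by exponential recovery toward 0 with time constant ``decay_ms``.
    """
    dt = 1000.0 / fs
    n_r = max(int(round(gt.rise_ms / dt)), 1)
    n_f = max(int(round(gt.ahp_latency / dt)), 1)
    t_r = np.arange(n_r + 1) * dt
    rise = _upstroke(t_r, n_r * dt, gt.peak_amp)
    t_f = np.arange(1, n_f + 1) * dt
    fall = -gt.ahp_depth + (gt.peak_amp + gt.ahp_depth) * 0.5 * (
        1.0 + np.cos(np.pi * t_f / (n_f * dt))
    )
    parts = [rise, fall]
    if with_recovery:
        # Recovery is truncated at 10 ms after the kink -- the span the
        # clipping convention excises -- and blended linearly to exactly 0
        # there, so a pasted spike leaves no residual outside its clip
        # window and subthreshold Vm statistics stay unbiased.
        rec_ms = CLIP_SPAN_MS - (n_r + n_f) * dt
        n_rec = max(int(round(rec_ms / dt)), 1)
        t_rec = np.arange(1, n_rec + 1) * dt
        rec = -gt.ahp_depth * np.exp(-t_rec / gt.decay_ms)
        rec -= rec[-1] * (t_rec / t_rec[-1])
        parts.append(rec)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# IV simulation
# ---------------------------------------------------------------------------

def _relax(v0: float, v_inf: float, tau_ms: float, n: int, dt: float) -> np.ndarray:
    t = np.arange(n) * dt
    return v_inf + (v0 - v_inf) * np.exp(-t / tau_ms)


def simulate_iv_sweep(gt: CellGroundTruth, i_pa: float, fs: float,
                      step_ms: float = 1000.0, pre_ms: float = 100.0,
                      post_ms: float = 150.0,
                      rng: Optional[np.random.Generator] = None,
                      ) -> tuple[Sweep, list[float]]:
    """One noisy current-step sweep; returns the sweep and the ground-truth
    spike (kink) times in ms.  Spike insertion uses the deterministic
    trajectory, so rheobase is exact even with noise."""
    dt = 1000.0 / fs
    n_pre = int(round(pre_ms / dt))
    n_step = int(round(step_ms / dt))
    n_post = int(round(post_ms / dt))
    n_tot = n_pre + n_step + n_post
    step_end = n_pre + n_step

    r = gt.r_hyp if i_pa < 0 else gt.r_dep
    v_inf = gt.rmp + i_pa * r * 1e-3  # pA * MOhm -> mV
    tmpl = spike_template(gt, fs, with_recovery=False)  # rise + fall to trough
    n_tmpl = tmpl.size

    v = np.empty(n_tot, dtype=np.float64)
    v[:n_pre] = gt.rmp

    spike_times: list[float] = []
    i0, v0 = n_pre, gt.rmp
    while i0 < step_end:
        t_c = _crossing_time_ms(gt, v0, v_inf)
        if not math.isfinite(t_c):
            v[i0:step_end] = _relax(v0, v_inf, gt.tau_m, step_end - i0, dt)
            i0 = step_end
            break
        i_c = i0 + int(math.ceil(t_c / dt - 1e-9))
        if i_c >= step_end:
            v[i0:step_end] = _relax(v0, v_inf, gt.tau_m, step_end - i0, dt)
            i0 = step_end
            break
        v[i0:i_c] = _relax(v0, v_inf, gt.tau_m, i_c - i0, dt)
        spike_times.append(i_c * dt)
        i_end = min(i_c + n_tmpl, n_tot)
        v[i_c:i_end] = gt.v_thresh + tmpl[: i_end - i_c]
        i0 = i_c + n_tmpl
        v0 = gt.v_thresh - gt.ahp_depth
    # after the step (or after a template that straddles the boundary)
    i_post = max(i0, step_end)
    if i_post < n_tot:
        v0_post = v[i_post - 1] if i_post > 0 else gt.rmp
        v[i_post:] = _relax(v0_post, gt.rmp, gt.tau_m, n_tot - i_post, dt)

    if gt.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        v = v + gt.noise_sd * rng.standard_normal(n_tot)
    sweep = Sweep(vm=v, fs=fs, i_inj=i_pa,
                  step_window=(n_pre * dt, step_end * dt))
    return sweep, spike_times


def simulate_iv_recording(gt: CellGroundTruth,
                          protocol: Optional[Sequence[float]] = None,
                          duration_ms: float = 1000.0, fs: float = 10000.0,
                          seed: Optional[int] = None,
                          rng: Optional[np.random.Generator] = None,
                          ) -> IVRecording:
    """Full IV protocol for one cell.  Ground truth (parameters and inserted
    spike times per sweep) is stored in ``recording.meta``."""
    if fs < 5000:
        raise ValueError("fs must be at least 5 kHz")
    if rng is None:
        rng = np.random.default_rng(seed)
    if protocol is None:
        protocol = default_iv_protocol(gt, step_ms=duration_ms)
    sweeps, truth_spikes = [], {}
    for j, i_pa in enumerate(protocol):
        sw, st = simulate_iv_sweep(gt, float(i_pa), fs, step_ms=duration_ms, rng=rng)
        sweeps.append(sw)
        truth_spikes[j] = st
    return IVRecording(
        sweeps=sweeps,
        meta={"ground_truth": asdict(gt), "spike_times_ms": truth_spikes,
              "analytic_rheobase_pa": analytic_rheobase(gt, step_ms=duration_ms)},
    )


# ---------------------------------------------------------------------------
# grating simulation
# ---------------------------------------------------------------------------

def _evoked_envelope(gt: CellGroundTruth, theta: float, fs: float,
                     hold_s: float, drift_s: float, phase: float) -> np.ndarray:
    """Deterministic Vm for one direction (no spikes, no noise)."""
    n_hold = int(round(hold_s * fs))
    n_drift = int(round(drift_s * fs))
    t = np.arange(n_drift) / fs
    a0 = float(gt.a0(theta))
    a1 = float(gt.a1(theta))
    ev = a0 + a1 * np.sin(2 * np.pi * TEMPORAL_FREQ_HZ * t + phase)
    n_ramp = int(round(ONSET_RAMP_MS / 1000.0 * fs))
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        ev[:n_ramp] *= ramp
    v = np.full(n_hold + n_drift, gt.rmp, dtype=np.float64)
    v[n_hold:] += ev
    return v


def _draw_spike_times(rate_hz: np.ndarray, grid_dt_s: float, duration_s: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson times (s) by thinning, with a refractory period."""
    m = float(rate_hz.max(initial=0.0))
    if m <= 0:
        return np.empty(0)
    n = rng.poisson(m * duration_s)
    if n == 0:
        return np.empty(0)
    times = np.sort(rng.uniform(0.0, duration_s, n))
    idx = np.minimum((times / grid_dt_s).astype(int), rate_hz.size - 1)
    keep = rng.uniform(0.0, 1.0, n) < rate_hz[idx] / m
    times = times[keep]
    out, last = [], -np.inf
    for tt in times:
        if (tt - last) * 1000.0 >= REFRACTORY_MS:
            out.append(tt)
            last = tt
    return np.asarray(out)


def simulate_grating_recording(gt: CellGroundTruth, T: int = 6,
                               fs: float = 10000.0,
                               seed: Optional[int] = None,
                               rng: Optional[np.random.Generator] = None,
                               hold_s: float = 2.0, drift_s: float = 2.5,
                               phase_locked: bool = True,
                               ) -> GratingRecording:
    """Drifting-grating session: 12 directions x ``T`` repeats.

    With ``phase_locked=True`` (default) the 2 Hz modulation phase is 0 at
    drift onset in every trial, so the trial-average-then-fold estimator
    recovers ``2*a1``.  ``phase_locked=False`` randomizes the phase per
    trial (a stress mode under which the folded average cancels).
    """
    if T < 1:
        raise ValueError("need at least one repeat")
    if fs < 5000:
        raise ValueError("fs must be at least 5 kHz")
    if rng is None:
        rng = np.random.default_rng(seed)

    duration_s = hold_s + drift_s
    grid_dt = 1e-3  # 1 ms rate grid for the Poisson draw
    decim = max(int(round(fs * grid_dt)), 1)
    tmpl = spike_template(gt, fs, with_recovery=True).astype(np.float32)
    n_tmpl = tmpl.size
    stim_proto = dict(static_onset=0.0, drift_onset=hold_s,
                      drift_offset=hold_s + drift_s)

    trials: dict[tuple[int, float], Sweep] = {}
    truth_spikes: dict[str, list[float]] = {}
    for theta in DIRECTIONS_DEG:
        env = None
        if phase_locked:
            env = _evoked_envelope(gt, theta, fs, hold_s, drift_s, 0.0)
            rate = gt.firing_rate(env[::decim])
        for i in range(1, T + 1):
            if not phase_locked:
                env = _evoked_envelope(gt, theta, fs, hold_s, drift_s,
                                       rng.uniform(0, 2 * np.pi))
                rate = gt.firing_rate(env[::decim])
            spikes_s = _draw_spike_times(rate, grid_dt, duration_s, rng)
            vm = env.astype(np.float32, copy=True)
            if gt.noise_sd > 0:
                vm += gt.noise_sd * rng.standard_normal(vm.size, dtype=np.float32)
            for ts in spikes_s:
                k = int(round(ts * fs))
                k_end = min(k + n_tmpl, vm.size)
                vm[k:k_end] += tmpl[: k_end - k]
            trials[(i, float(theta))] = Sweep(
                vm=vm, fs=fs, i_inj=0.0,
                stim=StimEvents(direction_deg=float(theta), **stim_proto),
            )
            truth_spikes[f"{i}:{theta}"] = (spikes_s * 1000.0).tolist()
    return GratingRecording(
        trials=trials,
        meta={"ground_truth": asdict(gt), "spike_times_ms": truth_spikes,
              "phase_locked": phase_locked},
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

Dist = tuple  # ("normal", mean, sd) | ("lognormal", median, sigma_log) |
#               ("uniform", lo, hi) | ("choice", values) | ("fixed", value)


def draw(dist: Dist, rng: np.random.Generator,
         clip: Optional[tuple[float, float]] = None) -> float:
    kind = dist[0]
    if kind == "normal":
        x = rng.normal(dist[1], dist[2])
    elif kind == "lognormal":
        x = dist[1] * math.exp(rng.normal(0.0, dist[2]))
    elif kind == "uniform":
        x = rng.uniform(dist[1], dist[2])
    elif kind == "choice":
        x = float(rng.choice(np.asarray(dist[1], dtype=float)))
    elif kind == "fixed":
        x = float(dist[1])
    else:  # pragma: no cover - config validation
        raise ValueError(f"unknown distribution kind {kind!r}")
    if clip is not None:
        x = float(np.clip(x, clip[0], clip[1]))
    return float(x)


#: Per-condition generative distributions.  Location parameters follow the
#: published medians for control and dark-reared (visually deprived) cohorts:
#: rmp -76.8 -> -71.6 mV, rest-to-threshold distance ~49 mV in both,
#: r_dep 87.0 -> 104.7 MOhm, r_hyp unchanged, Vm1 (= 2*a1) 11.0 -> 7.2 mV,
#: evoked rate 2.15 -> 0.95 Hz; tuning (kappa, asymmetry) identical across
#: conditions so OSI distributions are unchanged.  Spreads are chosen as
#: realistic within-condition variability (see docs/methods.md).
DEFAULT_FIELD_DISTS: dict[str, dict[str, tuple[Dist, Optional[tuple]]]] = {
    "control": {
        "rmp": (("normal", -76.8, 4.5), None),
        "rest_to_threshold": (("normal", 49.1, 4.0), (30.0, 70.0)),
        "r_hyp": (("lognormal", 51.4, 0.28), (15.0, 200.0)),
        "r_dep": (("lognormal", 87.0, 0.22), (20.0, 400.0)),
        "tau_m": (("normal", 20.0, 3.0), (8.0, 35.0)),
        "peak_amp": (("normal", 55.0, 5.0), (35.0, 80.0)),
        "ahp_depth": (("normal", 3.0, 0.8), (0.5, 4.5)),
        "ahp_latency": (("normal", 4.0, 1.0), (2.0, 8.0)),
        "a0_peak": (("lognormal", 11.2, 0.44), (0.5, 60.0)),
        "a1_peak": (("lognormal", 5.5, 0.52), (0.2, 40.0)),
        "kappa": (("lognormal", 1.5, 0.6), (0.0, 12.0)),
        "asym": (("uniform", 0.1, 0.4), None),
        "theta_pref": (("choice", list(DIRECTIONS_DEG)), None),
        "r_max": (("lognormal", 220.0, 1.0), (1.0, 20000.0)),
        "noise_sd": (("fixed", 0.5), None),
    },
    "deprived": {
        "rmp": (("normal", -71.6, 4.5), None),
        "rest_to_threshold": (("normal", 48.9, 4.0), (30.0, 70.0)),
        "r_hyp": (("lognormal", 51.4, 0.28), (15.0, 200.0)),
        "r_dep": (("lognormal", 104.7, 0.22), (20.0, 400.0)),
        "tau_m": (("normal", 20.0, 3.0), (8.0, 35.0)),
        "peak_amp": (("normal", 55.0, 5.0), (35.0, 80.0)),
        "ahp_depth": (("normal", 3.0, 0.8), (0.5, 4.5)),
        "ahp_latency": (("normal", 4.0, 1.0), (2.0, 8.0)),
        "a0_peak": (("lognormal", 10.1, 0.44), (0.5, 60.0)),
        "a1_peak": (("lognormal", 3.575, 0.52), (0.2, 40.0)),
        "kappa": (("lognormal", 1.5, 0.6), (0.0, 12.0)),
        "asym": (("uniform", 0.1, 0.4), None),
        "theta_pref": (("choice", list(DIRECTIONS_DEG)), None),
        "r_max": (("lognormal", 116.0, 1.0), (1.0, 20000.0)),
        "noise_sd": (("fixed", 0.5), None),
    },
}


@dataclass
class CohortSpec:
    """Cohort recipe: cell counts, per-condition parameter distributions and
    acquisition settings.  ``field_dists`` maps condition -> field ->
    (distribution, clip-range)."""

    n_control: int = 60
    n_deprived: int = 60
    seed: int = 0
    fs: float = 10000.0
    n_repeats: int = 6
    iv_step_ms: float = 1000.0
    phase_locked: bool = True
    field_dists: dict = field(default_factory=lambda: DEFAULT_FIELD_DISTS)

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_deprived < 0 or \
                self.n_control + self.n_deprived < 1:
            raise ValueError("cohort must contain at least one cell")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            cfg = json.load(fh)
        fd = cfg.pop("field_dists", None)
        spec = cls(**cfg)
        if fd is not None:
            spec.field_dists = {
                cond: {k: (tuple(v[0]), tuple(v[1]) if v[1] else None)
                       for k, v in fields.items()}
                for cond, fields in fd.items()
            }
        return spec


def draw_ground_truth(condition: str, rng: np.random.Generator,
                      field_dists: Optional[dict] = None) -> CellGroundTruth:
    """Draw one cell's generative parameters for a condition."""
    dists = (field_dists or DEFAULT_FIELD_DISTS)[condition]
    vals = {name: draw(d, rng, clip) for name, (d, clip) in dists.items()}
    rest_to_thr = vals.pop("rest_to_threshold", 49.0)
    vals["v_thresh"] = vals["rmp"] + rest_to_thr
    if vals.get("r_dep", 1.0) < vals.get("r_hyp", 0.0):
        vals["r_dep"] = vals["r_hyp"] * 1.01  # enforce rectification invariant
    return CellGroundTruth(condition=condition, **vals)


class CellRecord(NamedTuple):
    cell_id: str
    ground_truth: CellGroundTruth
    iv: IVRecording
    grating: GratingRecording


def simulate_cell(gt: CellGroundTruth, rng: np.random.Generator,
                  fs: float = 10000.0, n_repeats: int = 6,
                  iv_step_ms: float = 1000.0, phase_locked: bool = True,
                  ) -> tuple[IVRecording, GratingRecording]:
    iv = simulate_iv_recording(gt, duration_ms=iv_step_ms, fs=fs, rng=rng)
    grating = simulate_grating_recording(gt, T=n_repeats, fs=fs, rng=rng,
                                         phase_locked=phase_locked)
    return iv, grating


def simulate_cohort(spec: CohortSpec) -> list[CellRecord]:
    """Simulate a full control + deprived cohort, reproducible from the seed."""
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_control + spec.n_deprived
    children = ss.spawn(n_total)
    out: list[CellRecord] = []
    for idx in range(n_total):
        condition = "control" if idx < spec.n_control else "deprived"
        rng = np.random.default_rng(children[idx])
        gt = draw_ground_truth(condition, rng, spec.field_dists)
        iv, grating = simulate_cell(
            gt, rng, fs=spec.fs, n_repeats=spec.n_repeats,
            iv_step_ms=spec.iv_step_ms, phase_locked=spec.phase_locked,
        )
        out.append(CellRecord(f"{condition}_{idx:03d}", gt, iv, grating))
    return out
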