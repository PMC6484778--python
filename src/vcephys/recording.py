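"""Domain containers for current-clamp recordings.

Canonical units throughout the package: membrane potential in mV, current in
pA, time in ms within a sweep (each sweep's first sample is t = 0), sampling
rate in Hz, resistance in MOhm.  Stimulus event times are carried in seconds,
matching how grating schedules are logged by acquisition software; helpers on
:class:`StimEvents` convert to ms/samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

DIRECTIONS_DEG = tuple(range(0, 360, 30))  #: the 12 drift directions, 30 deg apart


@dataclass(frozen=True)
class StimEvents:
    """Timing/direction metadata for one drifting-grating trial.

    Times are seconds from the first sample of the sweep: the static (hold)
    grating appears at ``static_onset``, starts drifting at ``drift_onset``
    and disappears at ``drift_offset``.
    """

    direction_deg: float
    static_onset: float
    drift_onset: float
    drift_offset: float

    def __post_init__(self) -> None:
        if not (self.static_onset < self.drift_onset < self.drift_offset):
            raise ValueError(
                "stimulus events must be ordered static_onset < drift_onset < drift_offset"
            )
        if not 0 <= self.direction_deg < 360:
            raise ValueError("direction_deg must lie in [0, 360)")


@dataclass(frozen=True)
class Sweep:
    """One membrane-potential trace plus its injection/stimulus metadata.

    Parameters
    ----------
    vm : ndarray
        Membrane potential samples (mV).
    fs : float
        Sampling rate (Hz).
    i_inj : float
        Injected current during the step (pA); 0 for no injection.
    step_window : (float, float), optional
        Start/end of the square current step, ms from the first sample.
    stim : StimEvents, optional
        Grating annotation for visually evoked sweeps.
    """

    vm: np.ndarray
    fs: float
    i_inj: float = 0.0
    step_window: Optional[tuple[float, float]] = None
    stim: Optional[StimEvents] = None

    def __post_init__(self) -> None:
        vm = np.asarray(self.vm)
        if vm.ndim != 1 or vm.size == 0:
            raise ValueError("vm must be a non-empty 1-D array")
        if not np.all(np.isfinite(vm)):
            raise ValueError("vm contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "vm", vm)
        dur = self.duration_ms
        if self.step_window is not None:
            s, e = self.step_window
            if not (0 <= s < e <= dur):
                raise ValueError(f"step_window {self.step_window} outside trace [0, {dur:.3f}] ms")
        if self.stim is not None and self.stim.drift_offset * 1000.0 > dur + 1e-9:
            raise ValueError("stimulus drift_offset beyond end of trace")

    @property
    def n_samples(self) -> int:
        return self.vm.size

    @property
    def duration_ms(self) -> float:
        return self.vm.size / self.fs * 1000.0

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    def time_ms(self) -> np.ndarray:
        """Sample times in ms, t = 0 at the first sample."""
        return np.arange(self.n_samples) / self.fs * 1000.0

    def sample_index(self, t_ms: float) -> int:
        """Index of the first sample at or after ``t_ms`` (half-open windows)."""
        return int(np.ceil(t_ms * self.fs / 1000.0 - 1e-9))

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        """Slice covering the half-open window [start_ms, end_ms)."""
        return slice(self.sample_index(start_ms), self.sample_index(end_ms))

    def with_vm(self, vm: np.ndarray) -> "Sweep":
        return replace(self, vm=vm)


@dataclass
class IVRecording:
    """Ordered set of current-step sweeps (the IV protocol).

    The standard protocol starts at -400 pA, climbs in +50 pA decrements of
    hyperpolarization to the 9th (zero-current) step, then continues with
    +25 pA depolarizing increments up to at least 1.5x rheobase.
    """

    sweeps: list[Sweep]
    nonstandard_protocol: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def currents(self) -> np.ndarray:
        return np.array([s.i_inj for s in self.sweeps], dtype=float)

    def sweep_at(self, current_pa: float) -> Sweep:
        for s in self.sweeps:
            if abs(s.i_inj - current_pa) < 1e-6:
                return s
        raise KeyError(f"no sweep at {current_pa} pA in IV protocol")

    @property
    def has_zero_sweep(self) -> bool:
        return bool(np.any(np.abs(self.currents) < 1e-6))


@dataclass
class GratingRecording:
    """Drifting-grating session: sweeps indexed by (repeat, direction)."""

    trials: dict[tuple[int, float], Sweep]
    meta: dict = field(default_factory=dict)

    @property
    def directions(self) -> list[float]:
        return sorted({th for (_, th) in self.trials})

    @property
    def n_repeats(self) -> int:
        reps = {i for (i, _) in self.trials}
        return len(reps)

    def trials_for_direction(self, theta: float) -> list[Sweep]:
        out = [sw for (i, th), sw in sorted(self.trials.items()) if th == theta]
        if not out:
            raise KeyError(f"no trials at direction {theta} deg")
        return out


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``level`` is 'error' or 'warning'."""

    field: str
    rule: str
    level: str = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.field}: {self.rule}"


def validate_recording(rec) -> list[Violation]:
    """Check type invariants; returns an empty list iff all hold.

    Errors mark data the analysis cannot use; warnings mark departures from
    the standard protocol (e.g. fewer than 3 grating repeats) that are
    analyzable but flagged.
    """
    out: list[Violation] = []
    if isinstance(rec, IVRecording):
        cur = rec.currents
        if len(cur) == 0:
            return [Violation("sweeps", "IV recording has no sweeps")]
        if np.any(np.diff(cur) <= 0):
            out.append(Violation("currents", "currents must be strictly increasing"))
        if not rec.has_zero_sweep:
            out.append(Violation("currents", "missing zero-current sweep"))
        if not rec.nonstandard_protocol:
            hyp = cur[cur < 0]
            dep = cur[cur > 0]
            if len(hyp) and not (
                abs(hyp[0] + 400.0) < 1e-6 and np.allclose(np.diff(hyp), 50.0)
            ):
                out.append(
                    Violation(
                        "currents",
                        "hyperpolarizing steps do not follow -400 pA with +50 pA decrements",
                        "warning",
                    )
                )
            if len(dep) and not (
                abs(dep[0] - 25.0) < 1e-6 and np.allclose(np.diff(dep), 25.0)
            ):
                out.append(
                    Violation(
                        "currents",
                        "depolarizing steps do not follow +25 pA increments",
                        "warning",
                    )
                )
        for j, s in enumerate(rec.sweeps):
            if s.step_window is None:
                out.append(Violation(f"sweeps[{j}].step_window", "step window missing"))
    elif isinstance(rec, GratingRecording):
        dirs = rec.directions
        missing = [d for d in DIRECTIONS_DEG if d not in dirs]
        if missing:
            out.append(
                Violation(
                    "trials",
                    "missing directions: " + ", ".join(f"{d} deg" for d in missing),
                )
            )
        t = rec.n_repeats
        if t < 3:
            out.append(Violation("trials", f"repeats below 3 (T={t})", "warning"))
        elif t > 15:
            out.append(Violation("trials", f"repeats above 15 (T={t})", "warning"))
        for key, sw in rec.trials.items():
            if sw.stim is None:
                out.append(Violation(f"trials[{key}].stim", "stimulus annotation missing"))
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot validate object of type {type(rec).__name__}")
    return out
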