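# Methods

This note documents the models, estimators, numerical conventions and design
choices behind `vcephys`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Units and time conventions

Canonical units are mV (membrane potential), pA (current), ms (time within a
sweep), Hz (sampling and firing rates), MΩ (resistance).  Each sweep's first
sample is t = 0; stimulus events are carried in seconds.  All analysis
windows are half-open `[start, end)` at sample resolution: the first sample
at or after `start` is included, the one at `end` is not.  Window boundaries
therefore shift by less than one sample period between sampling rates, which
is why feature invariance across 10 and 25 kHz is specified to 0.1 mV rather
than exactly.

## Spike detection and threshold location

Candidate spikes are local maxima of dV/dt (central finite differences on
raw samples, no smoothing) exceeding `k = 8` times the SD of dV/dt over the
first 100 ms of the trace.  Two supplements make this robust across the
package's operating range:

* **Absolute floor.** On noise-free synthetic traces the baseline SD is 0
  and the adaptive rule would flag passive charging transients
  (~3 mV/ms).  The detector therefore uses `max(8·SD, 10 mV/ms)`; template
  spike upstrokes exceed 100 mV/ms, so the floor changes nothing for real
  noise levels while keeping noiseless traces analyzable.
* **Peak separation.** dV/dt peaks closer than 2 ms are merged, preventing
  one upstroke from yielding multiple events; 2 ms is far below any
  physiological inter-spike interval in this preparation.

The spike threshold is the sample of maximal d²V/dt² (twice-applied central
difference) in the 4 ms preceding the dV/dt peak; the spike peak is the Vm
maximum within 5 ms after threshold.  If the baseline window itself contains
a detected event, the SD is re-estimated once with that event excluded and a
warning is raised — the behavior in this corner case is a package decision,
logged so it is auditable.

Clipping replaces samples in `[threshold − 1 ms, threshold + 10 ms]`
(overlapping windows merged) with the straight line between the bounding
samples; clipping is idempotent.  Interactive verification of detections is
replaced by a QC report (spike counts per sweep, amplitude histogram).

## Intrinsic properties

`Vm_ss` is the mean of the clipped trace over 250–50 ms before step end; a
trace spanning more than 20 mV inside that window is rejected as unclipped.
RMP is `Vm_ss` at zero current.  Rheobase is the first positive step with a
detected spike; threshold, AHP metrics and the RS classification come from
the first spike of that sweep (AHP reference: `Vm_ss` at rheobase, measured
on the clipped trace — the reference window excludes the spikes themselves
either way).  Input resistances are referenced to the zero-current RMP
rather than a within-sweep pre-step baseline, matching how steady-state
deflections are plotted against injected current.  The depolarizing
measurement at +150 pA is withheld unless rheobase exceeds 150 pA, so it is
always subthreshold.  If a protocol contains repetitions, features are
computed per repetition and averaged.

## Evoked responses

Vm statistics are computed on spike-clipped traces; firing-rate statistics
on the original spike times.  The evoked window (0.5–2.5 s after drift
onset) contains exactly four 2 Hz cycles, so Vm0 is invariant to the
modulation, and the Vm1 fold (four 0.5 s segments averaged) aligns cycles
exactly.  Vm1 assumes the modulation phase is locked to drift onset across
trials; the simulator's default is phase-locked, and a stress mode
randomizes phase per trial (under which the fold cancels by design — this is
a property of the estimator, not a bug).

The responsiveness classification is a one-sample signed-rank test on the
per-trial |F0| distribution, exactly as defined.  Taking absolute values
makes the test one of "any deviation from baseline at all"; a signed-F0
variant is available (`use_signed=True`) as a sensitivity analysis, off by
default.  Neither variant is claimed to be the better definition.

"Responses at the preferred direction" use the spiking-preferred direction;
for cells without usable spiking tuning the Vm0-preferred direction is
substituted and the cell flagged (`vm_preferred_substituted`).

### Known estimator bias: Vm1 max−min

The max − min of a noisy folded average is biased upward by extreme-value
statistics: with per-sample folded noise σ_f = σ/√(4T), the bias is
≈ 2·σ_f·√(2 ln n_eff) where n_eff is the number of effectively independent
folded samples.  At the simulator defaults (σ = 0.5 mV white noise, T = 6–10
repeats, 10 kHz) this is +0.4–0.5 mV, i.e. ~4% of a median-sized Vm1.  The
bias is inherent to the published max−min definition and is *not* corrected
here; the package's recovery diagnostics report it, and the test suite
verifies separately (via the 2 Hz Fourier amplitude of the folded average)
that the underlying averaging is unbiased.  Two knock-on effects are worth
knowing:

* mean-error recovery of `2·a1` by Vm1 fails a ±2·SE unbiasedness bound at
  any nonzero noise level (the bias/SE ratio is independent of σ);
* because the bias acts as an additive floor on every direction's Vm1, it
  inflates the untuned component of Vm1 tuning curves more for cells with
  small modulation, systematically depressing OSI_Vm1 for the deprived
  condition in cohort simulations even though the generative tuning widths
  are identical across conditions.

## Orientation selectivity

θ is doubled in radians inside the vector sum; the index is invariant to
positive scaling of the responses and to rotating all directions by
multiples of the 30° spacing.  Curves whose responses sum to ≤ 0 have no
meaningful normalized vector average and are reported undefined and flagged
(clamping is documented only for ratios above 1 with positive sums, and a
sign-flipped ratio would be meaningless).  Exact ties between the two
candidate preferred directions resolve to the smaller angle — a measure-zero
event on continuous data made deterministic for testing.

## Population statistics

Quartiles use linear interpolation (numpy's default), stated so that
median/IQR values are exactly reproducible.  The rank-sum test uses the
exact null distribution when the combined sample is ≤ 30 without ties, and
the tie-corrected normal approximation otherwise.  Cells are pooled across
animals; a per-animal mixed-effects robustness check is out of scope for the
package's own statistics layer and is expected to be delegated to a standard
mixed-models library on the exported feature table.  No multiple-testing
correction is applied anywhere, by design.

## The synthetic-data generator

### Membrane and spikes

Subthreshold dynamics are a single-compartment exponential relaxation toward
`rmp + I·R(I)` with `R = r_hyp` for hyperpolarizing and `r_dep` for
depolarizing current (rectification), time constant `tau_m` (default 20 ms).
Threshold crossings insert a template waveform: a piecewise-linear upstroke
with a true corner at the kink (so the discrete d²V/dt² is strictly maximal
at the threshold sample at any sampling rate, noiseless or noisy), a concave
cap to the peak, a raised-cosine fall to the AHP trough, and an exponential
recovery.  Pasted templates are truncated at 10 ms after the kink and
blended to zero there, so a spike leaves no residue outside the window the
clipping convention removes — this keeps subthreshold Vm statistics exactly
unbiased on clipped traces.  After a spike the membrane resumes relaxation
from the trough, which yields a natural f–I curve.  A step whose asymptote
exactly equals threshold counts as spiking (crossing within a 10⁻⁹ mV
margin), making the measured rheobase agree with the closed-form
`V∞ = rmp + I·R` oracle.

Recording noise is white Gaussian per sample (`noise_sd`, default 0.5 mV —
the scale of amplifier plus residual high-frequency noise in anesthetized
whole-cell recordings).  Spike *insertion* uses the deterministic
trajectory, so ground-truth spike times and rheobase are exact even in
noise.

### Evoked structure

During drift, deterministic Vm is `rmp + a0(θ) + a1(θ)·sin(2π·2Hz·t + φ)`
with a 50 ms raised-cosine onset ramp (an instantaneous step would produce a
detectable dV/dt transient; the ramp is over well before the evoked window
opens).  Tuning is von Mises in doubled-angle space with concentration
`kappa`, times a `(1 + asym·cosΔ)` direction factor, renormalized to peak 1
at `theta_pref`; `kappa = 0` gives exactly flat curves and OSI 0, and OSI is
nondecreasing in `kappa`.

Spiking is an inhomogeneous Poisson process (thinning, 5 ms refractory)
whose rate follows the deterministic Vm through an exponential escape-rate
transfer `r_max·exp((Vm − v_thresh)/dv_escape)` with `dv_escape = 8 mV` — the
standard noisy-threshold approximation for cells whose mean Vm stays well
below threshold, as here (rest-to-threshold ≈ 49 mV versus evoked
depolarizations ≈ 11 mV).  A linear-rectified transfer
(`gain·max(Vm − v_thresh, 0)`) is available but produces no spikes at
realistic parameter values, precisely because the deterministic Vm never
reaches threshold.  The escape-rate ceilings (`r_max` medians 220 Hz control
/ 116 Hz deprived, lognormal spread) were set so cycle-averaged evoked rates
at the preferred direction land at the published ≈ 2.15 / 0.95 Hz medians,
with spontaneous (static-hold) rates of ≈ 0.5 Hz emerging from the same
transfer.

### Cohort defaults

One cell = one draw per parameter from per-condition distributions
(normal for voltages, lognormal for resistances/amplitudes/rates), location
parameters at the published medians:

| parameter | control | deprived | spread |
|---|---|---|---|
| RMP (mV) | −76.8 | −71.6 | SD 4.5 |
| rest-to-threshold (mV) | 49.1 | 48.9 | SD 4.0 |
| R_in hyperpolarizing (MΩ) | 51.4 | 51.4 | σ_log 0.28 |
| R_in depolarizing (MΩ) | 87.0 | 104.7 | σ_log 0.22 |
| a0 at preferred (mV) | 11.2 | 10.1 | σ_log 0.44 |
| a1 at preferred (mV) | 5.5 | 3.575 | σ_log 0.52 |
| kappa / asymmetry | shared | shared | σ_log 0.6 / U(0.1, 0.4) |

The threshold is generated as `rmp + distance` with the two drawn
independently, because the deprivation result hinges on the *unchanged*
rest-to-threshold distance; the implied deprived threshold shift (+5.0 mV)
is slightly larger than the published +3.6 mV — the published joint
distribution of RMP and threshold is not recoverable from printed medians.
Rheobase is emergent (`distance / r_dep`, quantized to the 25 pA grid); its
absolute scale (~575 pA median) exceeds the published 275 pA because a
passive membrane needs the full 49 mV climb through R_in, whereas real cells
reach threshold earlier via fluctuations and active conductances.  Its
*ratio* between conditions (≈ 0.85) matches the published ≈ 0.82, which is
what the population contrast tests.  Spreads are chosen as plausible
within-condition variability; they are deliberately tighter than the
published IQRs (which fold in animal-to-animal and measurement
heterogeneity) so that a 60+60-cell simulated cohort has power comparable to
the published 150+40-cell dataset.  `theta_pref` is drawn from the 12
sampled directions so preferred-direction recovery is exactly scoreable.

Randomness: one root seed → `numpy.random.SeedSequence` substreams per cell;
cohorts, cells and the pipeline are bit-reproducible from the seed.

### What the simulator does not emulate

Anesthesia-state slow fluctuations (up/down states), conductance-based spike
dynamics, stimulus geometry, eye movements, animal-level clustering, serial
correlations between trials, and band-limited (colored) recording noise.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated generative assumptions, not robustness to every property of
real in vivo data — most notably, real Vm noise is low-passed by the
membrane and amplifier, which would shrink (but not remove) the Vm1
extreme-value bias discussed above.

## Problem sizes in the validation suite

Estimator recovery uses 200 simulated cells at T = 10 repeats; detection
scoring 100 traces at 25 kHz; rheobase exactness 20 noiseless cells; the
type-I calibration 1000 null cells; the cohort pattern 20 seeded 60+60-cell
cohorts in the test suite and 5 in the acceptance script, all at the
simulator default of 10 kHz (the analysis is sampling-rate-agnostic; 25 kHz
reproduces the acquisition fidelity of the original recordings at
proportionally higher cost).  The preferred-direction recovery property is
evaluated with the escape-rate ceiling pinned at its population median and
cells required to fire ≥ 1 Hz at the preferred direction — the spiking-
preferred direction is only meaningful for cells that spike, mirroring the
responsive-only restriction on spiking OSI.

## Known limitations

* Vm1's max−min bias and its knock-on effect on OSI_Vm1 contrasts (above).
* The degenerate |F0| responsiveness test classifies almost any spiking cell
  as responsive; it is implemented as defined, with the signed variant as an
  option.
* The linear-rectified spiking transfer is retained for completeness but is
  silent at realistic parameters.
* Igor PXP / FileMaker ingestion is out of scope; the neutral directory
  container (JSON metadata + float32 or CSV traces) is the supported format,
  and an adapter for any specific archive layout is left to the user.
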