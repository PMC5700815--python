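# Methods

## Model and assumptions

The core model treats synaptic vesicle trafficking at the IHC active zone
as four pools in series (RRP → fusion; recycling → RRP; reserve →
recycling; distant reservoir → reserve), each with a fixed capacity
V_Mi, a rate coefficient k_i and a recruitment threshold ca_i on the
drive.  The drive is the running integral of the rectified Ca²⁺ current
(inward current is negative by convention; a signed integral would
produce a negative drive, contradicting the threshold semantics).  The
drive never decays — there is no Ca²⁺ clearance, buffering or extrusion
term — so thresholds, once crossed, stay crossed.  Transfer into a pool
is throttled by its free capacity through the factor (V_Mi − V_i)/V_Mi.
Vesicle counts are continuous (deterministic mass action), and the five
equations conserve F + ΣV_i exactly.

### Charge unit

Published rate constants for this model are printed in C⁻¹s⁻¹ alongside
thresholds of order 10⁻¹⁴–10⁻¹² C, while the corresponding fitting
constraints place thresholds "between 0 and 10" — readable consistently
only if the model arithmetic uses an internal charge unit of about 1 pC.
`PoolParams.charge_scale` (default 1e-12 C) defines that unit: thresholds
and rate coefficients are stored in the scaled unit (with the scale set
to 1.0 they can be used directly in SI), drives carry SI coulombs, and
`simulate` rescales internally.  With the 1 pC unit the reference
thresholds fall at 0.017–10.2, i.e. inside the documented [0, 10]
fitting box.

### Integration

Fixed-step classical RK4, default dt = 0.05 ms.  The gating is only
piecewise-smooth (threshold crossings, capacity clamps), so a small
fixed step is more predictable than adaptive stepping; an optional
self-check re-integrates at dt/2 and warns when the final fused counts
disagree by more than 0.5%.  Occupancies are clamped to [0, V_Mi] and the
fused count to non-decreasing after each step; at the default step these
clamps only absorb rounding-level overshoot (conservation holds to
~1e-14 relative on the reference train).  The integrator is jitted with
numba when available; the fallback is the same Python function.

## Parameter estimation

The objective is the uniform-weight sum of squared differences between
the observed cumulative ΔC_m curve and the model prediction at the
protocol's sample times (per-point standard deviations are deliberately
not used as weights).  Minimization is Nelder–Mead under box constraints
— scipy's implementation clips every simplex vertex to the box, so the
constraints hold at every iteration — with default bounds k ∈ [0, 10⁴],
V_M1, V_M2 ∈ [0, 10⁵], V_M3 ∈ [5·10³, 10⁵], V_M4 ∈ [10⁴, 10⁵], thresholds
∈ [0, 10] scaled-charge units.

Plain multi-start from random draws is not enough in 12 dimensions: the
simplex reliably stalls in a deceptive basin (a slow-fusion/large-RRP
curve that shadows the true one).  Two additions fix this:

- a **heuristic start** read off the data: the early-plateau level seeds
  the RRP capacity, the first-pulse charge seeds the recycling-pool
  threshold, and the charge at the detected superlinear onset seeds the
  reserve thresholds;
- **restart polishing**: the simplex is re-initialized from the incumbent
  best up to 4 times, which recovers from premature simplex collapse.

Random starts draw capacities and rate coefficients log-uniformly across
their boxes (the reference values span seven decades) and thresholds
uniformly; draws are sequential in the seed, so the first k starts are
shared between runs with different n_starts.  On noise-free synthetic
train curves this recovers the generating k₁, V_M1, V_M2 to well under
10% (best-of-20 starts; the control set is recovered to machine
precision).

The Monte-Carlo sensitivity analysis resamples every observed point from
Normal(mean, sd) — negative excursions are kept, as a plain Gaussian
implies — refits each replicate warm-started from the base fit, and
reports per-parameter means and standard deviations over the (default
60) runs.  Monte-Carlo refits use a reduced simplex budget (maxfev
~800–2000 with one polish restart); the residual optimizer jitter this
leaves is far smaller than the noise-induced parameter scatter being
measured.

### Identifiability

At realistic noise (several % of the curve maximum) k₁ and k₂ are only
weakly identified by a train curve: k₁ informs only the first two or
three points, and late points dominate the unweighted objective.  The
least-squares optimum itself then wanders tens of percent from the
generating values — consistent with the large published uncertainties on
these rate constants — so point recovery of k₁/k₂ from a single noisy
train curve should not be expected; the Monte-Carlo spread is the honest
summary.  The acceptance script reports the measured medians.

## Synthetic-data generators

The generators are pure functions of (parameters, seed) and stand in for
the raw recordings.

- **Protocols**: holding −95 mV, test −10 mV; single 20 ms steps; duration
  series 2–50 ms; paired 20 ms pulses at interpulse intervals
  50–1000 ms; trains of 50 × 5 ms pulses with 10 ms intervals (750 ms
  span).
- **Ca²⁺ current**: Boltzmann activation × linear driving force
  (vrev +45 mV, vhalf −25 mV, slope 7 mV), flat during each step, zero at
  holding (leak-subtracted), Gaussian noise 5 pA.  The default amplitude
  scale (gmax = 1.0, peak ≈ −49 pA at −10 mV, ≈ 0.25 pC per 5 ms pulse)
  was chosen so that the cumulative charge crosses the reserve-pool
  threshold in the late third of the train, which gives the generated
  control curve the three-phase shape (depletion / linear / superlinear)
  that the model is known for.  At the larger per-pulse charges implied
  by an earlier (~23rd-pulse) crossing, the model's middle phase becomes
  strongly humped — pool 2 drains while K₂ keeps growing with the
  non-decaying drive — and no flat linear phase exists at any amplitude;
  this is a property of the published parameter set under a pure
  integral drive, and is documented here as a limitation.
- **Capacitance observations**: the forward model sampled at the end of
  each interpulse interval (trains) or 50 ms after the step, plus i.i.d.
  Gaussian noise (homoscedastic by default; per-point vectors accepted).
- **Uncaging**: [Ca²⁺] steps to ca_peak with an exponential rise whose
  default 10–90% time is 28.8 ms; release follows
  vmax·Hill([Ca²⁺])·(1 − C_m/C_tot); the fluorescence channel is the
  inverse OGB-5N calibration (K_D 23.30 µM).
- **Scenes**: vesicle centers rejection-sampled uniformly inside each
  pool's defining region around a triaxial-ellipsoid ribbon (semiaxes
  110 × 190 × 140 nm, hovering 50 nm above the membrane plane), so
  re-classification recovers the requested counts exactly.  Vesicle
  overlap is not prevented (centers only are classified).
- **STED spots**: channel b uniform; a fraction of channel a spots are
  jittered copies of b spots, the rest uniform background.
- **EPSC trains**: Poisson event times (optionally inhomogeneous via
  thinning), lognormal amplitudes, peak-normalized difference-of-
  exponentials kernels (τ_rise 0.2 ms, τ_decay 1 ms) on Gaussian noise,
  with ground truth returned.

What passing tests on these data do **not** show: robustness to
sine-wave capacitance artifacts, series-resistance errors, Ca²⁺-current
rundown/inactivation, heteroscedastic or correlated noise, non-ellipsoid
ribbons, or spot-detection errors upstream of the point patterns.

## Analysis procedures and numerical choices

- **ΔC_m**: baseline mean over 200 ms before the stimulus; response mean
  over 100 ms starting 50 ms after it (skipping the transient); both
  windows must be clear of every stimulus.  Invariant to constant
  offsets.
- **Slopes**: OLS with a t-based 95% CI on the slope (coverage verified
  at 95% ± 2% over 1000 replicates).  Power fits are log–log OLS.
- **Train segmentation**: depletion phase fixed at pulses 1–3 by
  default; linear slope fitted on pulses 3–23 (both configurable);
  superlinear onset = first pulse whose centered 3-point increment
  exceeds 2× the linear slope for ≥3 consecutive pulses.
- **Replenishment rate**: total ΔC_m / 45 aF / span, with the full train
  span (depolarized + interpulse time) as the default denominator;
  dividing 51 fF by 750 ms gives 1.51 vesicles/ms.
- **Endocytosis**: linear fits report the decline as a positive rate;
  exp-plus-linear fits A·e^(−t/τ) + b·t + c with A ≥ 0, τ ≥ 1 ms.
- **Hill fits**: three-parameter least squares with bounds n ∈ [0.2, 20];
  if the fitted curve reaches < 80% of its own plateau within the data
  range (a partial sigmoid), the affinity falls back to the half-max
  crossing of the max-normalized data and is flagged.
- **Uncaging metrics**: onset = first of ≥3 consecutive samples above
  baseline + 3σ; derivative smoothed by a centered 3 ms moving average.
- **Geometry**: RRP = centers ≤ 40 nm from the membrane and ≤ 80 nm from
  the active-zone center along the membrane; RAP = ≤ 80 nm from the
  ribbon surface excluding all membrane-apposed vesicles (configurable
  to exclude only RRP members — the narrower reading); OP = 80–350 nm
  from the ribbon, not membrane-apposed.  Ellipsoid surface distances
  are exact (bracketed root of the normal-projection equation); shell
  volumes use a 5 nm voxelized Euclidean distance transform, clipped to
  the cytoplasmic side of the membrane, and agree with the analytic
  sphere to ~1%.
- **EPSC detection**: MAD-based noise, threshold and prominence 5σ on a
  0.3 ms-smoothed trace, 1 ms refractory.  Overlap correction fits the
  previous decay down to the inter-peak valley and subtracts its
  extrapolation at the later peak; decay constants are fitted on
  monophasic events only.  Coincident events closer than the refractory
  period are unresolvable by construction.

## Problem sizes

The test suite and the acceptance script keep simulation-based studies
at deliberate sizes: simplex fits run at dt = 0.1 ms; the noisy-recovery
study uses 20 seeds with a reduced per-fit budget (2 random starts plus
the heuristic, maxfev 1500, one polish restart); Monte-Carlo uses the
full 60 runs at maxfev 800; coverage checks use 1000 replicates; EPSC
round trips use 5 × 13 s recordings at 20 events/s.  These sizes are the
package's chosen defaults for its own verification studies.
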