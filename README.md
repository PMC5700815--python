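# ihcexo

Quantitative analysis of exocytosis at the inner-hair-cell (IHC) ribbon
synapse: a Ca²⁺-driven four-pool mass-action model of vesicle trafficking
and fusion, its constrained least-squares estimation with Monte-Carlo
sensitivity analysis, and the standard analyses applied to
membrane-capacitance recordings, Ca²⁺-uncaging experiments, electron-
tomographic 3D reconstructions and afferent EPSC recordings.  All
experimental inputs can be emulated by built-in synthetic-data generators,
so every analysis is testable end to end without raw recordings.

## Who this is for

Auditory/synaptic physiologists and modellers who want a reusable,
tested implementation of the vesicle-pool model and of the
capacitance/uncaging/geometry/EPSC measurement procedures, either to
analyze their own delimited-text data (CSV traces and coordinate tables)
or to run simulation studies.

## The model

Four vesicle pools feed the fusion site in series: the readily releasable
pool (RRP, capacity V_M1), the recycling pool (V_M2), the reserve pool
(V_M3) and a distant reservoir (V_M4).  The drive is the cumulative Ca²⁺
charge q(t) = ∫|I_Ca| dt (with the diffusion volume taken as a unit
volume, charge stands in for [Ca²⁺]ᵢ).  Every transition is gated by a
threshold-linear function of the drive:

    K_i(t) = k_i · max(q(t) − ca_i, 0),   i = 1..4

and the occupancies V_i(t) and cumulative fused count F(t) follow

    dF/dt  = K₁V₁
    dV₁/dt = K₂V₂(1 − V₁/V_M1) − K₁V₁
    dV₂/dt = K₃V₃(1 − V₂/V_M2) − K₂V₂(1 − V₁/V_M1)
    dV₃/dt = K₄V₄(1 − V₃/V_M3) − K₃V₃(1 − V₂/V_M2)
    dV₄/dt =                   − K₄V₄(1 − V₃/V_M3)

with F(0) = 0 and V_i(0) = V_Mi.  Fused vesicles convert to membrane
capacitance at 45 aF per vesicle.  Parameters are estimated by bounded
Nelder–Mead least squares on observed ΔC_m curves (uniform weights,
box constraints enforced at every iteration, seeded multi-start), with
parameter uncertainty from a 60-run Monte-Carlo resampling of the curve.

## Worked example

```python
import ihcexo as ix

# 50 x 5 ms depolarizations, 10 ms apart, from -95 to -10 mV
proto = ix.build_protocol("train")
drive = ix.make_drive(proto)                    # cumulative Ca2+ charge
params = ix.reference_params("control")         # published parameter set
traj = ix.simulate(params, drive, dt=0.05)

print(f"total charge: {drive.q[-1]/1e-12:.1f} pC")
print(f"fused vesicles: {traj.fused[-1]:.0f} ({traj.cm[-1]:.0f} fF)")

curve = ix.synth_cm_observation(params, proto, noise_sd=0.0, seed=0)
phases = ix.train_components(curve)
print(f"linear phase: {phases.linear_slope:.2f} fF/step, "
      f"superlinear onset at pulse {phases.superlinear_onset}")
print(f"replenishment: "
      f"{ix.replenishment_rate(51.0, proto.train_span_ms):.2f} vesicles/ms")
```

Output:

```
total charge: 12.3 pC
fused vesicles: 18247 (821 fF)
linear phase: 4.18 fF/step, superlinear onset at pulse 37
replenishment: 1.51 vesicles/ms
```

The cumulative-release curve shows the three classical components: rapid
RRP depletion over the first pulses, a linear replenishment-limited
phase, and a superlinear component once the cumulative charge crosses the
reserve-pool threshold.  The replenishment line converts a 51 fF train
gain into ~1.5 vesicles/ms at 45 aF/vesicle.

A thin CLI mirrors the library:

```bash
ihcexo synth ica --protocol train --out ica.csv
ihcexo simulate --params control --drive drive.csv --out traj.csv
ihcexo fit --observed obs.csv --drive drive.csv --out fit.json
ihcexo classify-scene --vesicles vesicles.csv --out pools.json
```

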