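# cylcap

Particle contact-rate prediction for cylindrical biological collectors.

Suspension feeders' palps and tube feet, filamentous algae, seagrass
stigmas and vegetation stems all capture suspended particles the same way:
a particle carried past a roughly cylindrical "collector" touches it when
the particle's center passes within one particle radius of the surface
(direct interception). `cylcap` implements that capture framework for
researchers in ecological biomechanics and benthic ecology who need
quantitative contact-rate estimates without running their own
computational fluid dynamics.

## Model

Two dimensionless numbers govern capture by a cylinder of diameter D_c in
a flow U∞: the collector Reynolds number Re = U∞·D_c/ν and the particle
size ratio r_p = D_p/D_c. The contact efficiency η(Re, r_p) is the
fraction of particles crossing the collector's upstream window that make
contact, and the contact rate is

```
CR = η · F_p,    F_p = C_p · U∞ · h_c · D_c
```

Because η locally behaves as a power law η ≈ k₂ Re^α r_p^β,

```
CR ∝ U∞^γ · D_p^β · D_c^δ,    γ ≡ 1 + α,    δ ≡ 1 + α − β
```

and the *local* exponents (log-log slopes on an efficiency surface) tell
you how capture responds to flow speed, diet particle size and collector
size anywhere in the parameter space — including where they change sign.

The package provides:

- closed-form efficiency models (finite-size creeping flow, boundary-layer
  theory, the empirical rigid-cylinder power-law fit, potential flow);
- a stitched surrogate surface spanning 0.01 ≤ Re ≤ 1000, 0.005 ≤ r_p ≤ 1.5
  with per-cell provenance, plus a loader for user-supplied η tables;
- local exponent fields (α, β, γ, δ) with wake-regime boundaries
  (Re = 47, 180, 260) treated as differencing barriers;
- a trajectory-integration oracle (critical-streamline bisection in
  analytic flow fields) that independently verifies the closed forms;
- dimensional contact-rate prediction, exposed-height calibration and the
  constant-biomass collector-division analysis;
- emulations of five published experimental comparisons (brittle star,
  two spionid polychaete studies, red-algae-type structures, rigid
  cylinders) driven by synthetic generators — no external data needed.

## Worked example

```python
from cylcap import CaptureScenario, biomass_division, build_surrogate_surface, predict_contact

surface = build_surrogate_surface()
scenario = CaptureScenario.from_eco(          # ecological units: cm/s, um
    velocity_cm_s=6.0, collector_diameter_um=100.0, particle_diameter_um=25.0,
    collector_height_m=0.01, particle_concentration_per_m3=1e6,
)
pred = predict_contact(scenario, surface)
print(f"F_p = {pred.approaching_flux:.3f}/s, eta = {pred.efficiency:.4f}, CR = {pred.contact_rate:.4f}/s")
for n in (2, 4, 16):
    print(n, round(biomass_division(scenario, n, surface).total_ratio, 2))
```

prints

```
F_p = 0.060/s, eta = 0.1401, CR = 0.0084/s
2 1.89
4 3.04
16 11.4
```

Of the 0.06 particles per second crossing this collector's upstream
window, 14% make contact, giving 0.0084 contacts/s. Dividing the same
collector biomass into n thinner cylinders of equal height multiplies the
total contact rate by up to ~11 at n = 16 — the frontal-area gain of many
thin collectors, one candidate driver of selection toward fine filtering
arrays. The `examples/` directory has one short script per capability
(closed forms, surface, oracle, exponent maps, predictions, experiment
emulations), and the `cylcap` command exposes the same pipeline from the
shell (`cylcap surface`, `cylcap exponents`, `cylcap emulate`,
`cylcap predict ...`, `cylcap fixtures`).

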