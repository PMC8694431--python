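# Methods

## Problem and model

`cylcap` predicts rates of contact between suspended particles and
cylindrical biological collectors — suspension-feeder palps and tube feet,
algal branches, vegetation stems — by direct interception: particle centers
follow fluid pathlines, and contact occurs when a center comes within one
particle radius of the collector surface. Inertial impaction and diffusional
deposition are out of scope (both are negligible for near-neutrally-buoyant
particles larger than a few microns and smaller than ~5% of the collector
diameter at the densities typical of seston).

Two dimensionless groups control the process: the collector Reynolds number
Re = U∞·D_c/ν and the particle size ratio r_p = D_p/D_c. The contact
efficiency η(Re, r_p) is the fraction of particles crossing the collector's
upstream window (width D_c, height h_c) that touch it; the contact rate is

    CR = η · F_p,   F_p = C_p · U∞ · h_c · D_c .

Locally, η behaves as a power law η ≈ k₂ Re^α r_p^β, giving

    CR ∝ U∞^γ · D_p^β · D_c^δ,   γ ≡ 1 + α,   δ ≡ 1 + α − β .

These identities are enforced exactly in the exponent fields.

## Closed-form efficiency models

* **Creeping flow** (0 < Re ≤ 5): η = G(r_p) / (2·(c − ln Re)) with
  c = 2.002 and the finite-size flux factor
  G(r_p) = 2(1+r_p)ln(1+r_p) − (1+r_p) + 1/(1+r_p). G → 2r_p² as r_p → 0,
  recovering the classical small-particle form η = r_p²/(c − ln Re). The
  constant c is configurable (nearby literature rounds it to 2.0); the
  validity ceiling Re = 5 keeps a margin below the denominator's zero at
  Re = e^c ≈ 7.4. The finite-size form is the default because ecological
  particles are routinely a large fraction of the collector diameter; the
  r_p² limit is retained as a named variant.
* **Boundary layer** (Re ≥ 500, r_p ≤ 0.05): η = k₁·Re^0.5·r_p². Theory
  fixes the exponents but not k₁.
* **Empirical rigid-cylinder fit** (38 < Re < 486, r_p < 0.03):
  η = 0.224·Re^0.718·r_p^2.08, from flume measurements of bead capture on
  greased cylinders. Results carry an in-validity flag.
* **Potential flow**: η = (1+r_p) − 1/(1+r_p); not a realistic capture
  model at these Reynolds numbers, but its critical-streamline flux is
  exact, making it an oracle for the trajectory integrator.

## Surrogate surface

No single form covers the ecological parameter space (0.01 ≤ Re ≤ 1000,
0 < r_p ≤ 1.5), so predictions are served from a stitched surface:
creeping form for Re ≤ 5, empirical fit for 38 ≤ Re ≤ 486, boundary-layer
form for Re ≥ 500, and per-r_p-column linear blends in (ln η, ln Re) across
the gaps. All constituents are local power laws in Re, so log-log-linear
blending is the natural interpolant and the stitched function is continuous
in Re by construction. k₁ is calibrated once per build so the
boundary-layer form equals the empirical fit at (Re = 500, r_p = 0.03) —
the fit's particle-size validity edge; since the two forms have different
r_p exponents (2 vs 2.08), a single constant cannot match every column, and
the residual per-column mismatch is absorbed by the 486–500 blend. The
default grid is 51 log-spaced Re points (10 per decade) × 40 log-spaced r_p
points (0.005–1.5); every cell carries a provenance tag (creeping /
blended / empirical / boundary-layer / user-table). A user-supplied
(Re, r_p, η) table — e.g. digitized simulation output — can override
computed cells; table points are snapped to the nearest grid node in log
space.

Known limitations of the stitch: the empirical fit is applied across the
full r_p column although it was fitted for r_p < 0.03, and extrapolated η
can exceed 1 at large r_p and Re; near the creeping ceiling (Re ≳ 3) the
logarithmic denominator makes the local α exceed 1, so γ and δ leave the
1 ≤ γ ≤ 2 band that resolved simulations show. Exponents quoted for
specific regions (the acceptance checks) use only regions where a closed
form is authoritative.

## Trajectory oracle

An independent check on the closed forms integrates tracer pathlines in
the two analytic fields (potential; creeping/Oseen for Re ≤ 5),
nondimensionalized by collector radius and free-stream speed. Trajectories
start 50 radii upstream and are integrated with an adaptive Runge–Kutta
scheme (rtol 1e-8); contact (center distance ≤ 1 + r_p) is detected by
event root-finding on the continuous solution, including a closest-approach
event (zero of the radial velocity) that catches grazing passes whose dip
below the contact circle fits inside a single step. Endpoint-only checking
is available as a documented lower-accuracy mode. Because steady symmetric
fields make the contacting set an interval in the seed offset, the critical
offset is found by bisection (default relative tolerance 1e-6) rather than
dense particle seeding. Efficiency is reported flux-normalized — the
streamfunction value at the critical seed point — which equals the fraction
of approaching particles contacting; in the creeping field the upstream
velocity never becomes uniform (logarithmic far field), so the raw offset
is not the flux fraction and both numbers are kept on the result. The
oracle is restricted to the steady regime; unsteady wakes are not
simulated, and results carry a note saying so.

## Local exponent fields

α and β are log-log slopes of the tabulated surface. Interior cells use
centered differences in log space; grid edges and cells flanking a wake
regime boundary (Re = 47, 180, 260 — where η is discontinuous because the
flow itself changes character) use one-sided differences, and no stencil
ever crosses a boundary. Boundary-adjacent cells are flagged in a mask;
masked cells export as not-a-value, never as extrapolated numbers. The
pairwise (two-point) forms are exposed separately as `local_alpha` /
`local_beta`. Both variants are exact on power-law surfaces, which is what
makes synthetic-surface exponent recovery a machine-precision test. A
regime segment with fewer than three grid points is fully masked and a
warning is issued (the default grid has only two nodes inside 180 < Re ≤ 260).

## Dimensional prediction

`CaptureScenario` holds SI values; ecological units (cm/s, μm) are
converted once at the interface, so predictions are bit-identical between
conventions. Surface lookups interpolate bilinearly in
(ln Re, ln r_p, ln η) — exact on power-law patches — and refuse to
extrapolate: out-of-coverage queries raise an error naming the exceeded
bound. Biomass division assumes constant total cross-sectional area at
fixed height (n cylinders of diameter D_c/√n); on a power-law patch the
total-rate gain is n^(1−δ/2), which the implementation reproduces
numerically. Height calibration inverts CR = η·C_p·U∞·h_c·D_c in closed
form for the one experiment series whose exposed collector length was
unreported.

## Experiment emulations and synthetic data

The five published comparisons are emulated on configuration fixtures
transcribing the experiments' summary table (velocities, collector and
particle diameters, Re and r_p ranges, plot markers); values the original
studies did not report carry an `estimated` flag. A consistency check
verifies each printed Re/r_p endpoint against the interval implied by the
dimensional columns (ν = 1e-6 m²/s), expanded by one unit in the endpoint's
last printed digit — the printed ranges reflect the experiments' actual
velocity/diameter pairings, not the outer product, so a tighter two-sided
check is not derivable from the table alone.

The brittle-star emulation needs a time-varying suspension. The generator
draws a binned lognormal (10 μm bins, 40–320 μm; mode at 150 μm, log-sigma
0.5; optional seeded multiplicative jitter) and depletes it by well-mixed
Stokes settling: each bin decays as exp(−w_s(D)·t/H) with
w_s = Δρ g D²/(18 μ). The defaults Δρ = 150 kg/m³ and H = 0.3 m are a
calibration fixture chosen once so the suspended peak migrates from the
150–160 μm bin to the 110–120 μm bin over a 180 s run, matching the
reported drift from ~150 to ~110 μm; they are not measurements. Captured
counts accumulate per bin and time step (default dt = 1 s over 180 s;
halving dt changes totals only through the suspension time-sampling, which
the conservation test bounds). What the emulation demonstrates is the
size-selection bias — the captured distribution peaking above the
suspension — not absolute counts, since the flume's true depth, particle
density and exposed collector length are unknown.

The polychaete contact-rate ratio uses the finite-size creeping form, whose
logarithmic Re factor cancels in the ratio: CR_large/CR_small =
G(r_p,large)/G(r_p,small), independent of velocity, concentration and
height. Representative palp diameters default to 60, 100 and 200 μm
(configurable); the mean spat diameter for the red-algae normalized-rate
case defaults to 212 μm (the alternative tabulated value of 200 μm is a
config choice), with velocity 5 cm/s. The red-algae case reports only
normalized rates because the ambient spat concentration was never
published. A pronation guard flags velocities above 6 cm/s (exclusive at
the threshold), where flexible collectors bend and rigid-collector
predictions overestimate contact.

## Numerical choices and degenerate inputs

r_p = 0 returns η = 0 in every model (a zero-size particle cannot
intercept). η ≤ 0 cells make local exponents undefined and are masked.
Zero observed rate calibrates to h_c = 0 (degenerate, returned as 0 rather
than raised). Bisection brackets grow geometrically from 2(1+r_p) and fail
loudly after 8 doublings. Serialization keeps 12 significant digits in CSV
(`%.12g`) and full precision in JSON; round-trips are tested lossless at
those levels.

## Problem sizes

Default analyses use the 51×40 surface grid, nine oracle cases (three size
ratios × three fields), a 180-step brittle-star run and 21-point exponent
grids for the fixed-exponent checks. These sizes keep the full suite and
the acceptance script in the seconds-to-a-minute range while leaving every
estimate deterministic.

## What passing tests do and do not show

Tests verify the closed forms, the stitching, the exponent algebra, the
oracle equivalence and the emulation mechanics on synthetic fixtures. They
do not validate the surrogate against resolved flow simulations in the
vortex-shedding regimes (no such surface is bundled), nor against raw
experimental counts (not redistributed); structural properties — monotone
η, size-selection bias, negative δ in the rigid-cylinder region — are the
tested claims there.
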