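# Methods

## Physical model

The package models aspiration-mediated patterning as a competition between
pinned gas–liquid interfaces. Aspiration through one port lowers the pressure
of the liquid body, which is continuous beneath the whole rail footprint
because the low rails stand off the floor. Each interface is immobile until
the local contact angle falls to the receding value θ_R,c, at which point the
contact line recedes; the pressure difference at that moment is the
interface's critical capillary pressure. Three interface families exist:

* **Open port** (diameter D): a hemispherical cap of maximum curvature 4/D,
  so Δp_O = 4γ/D.
* **Low-rail side meniscus** (gap h): Δp_L = γ(2cosθ_R,c/h + 1/η), where η is
  the in-plane radius of curvature. On plasma-treated surfaces θ_R,c ≈ 0 so
  cosθ_R,c defaults to 1, and since η scales with the rail length (h ≪ l) the
  1/η term defaults off. Both defaults are overridable
  (`cos_theta_override`, `include_eta_term`/`eta`); the η term is additive,
  as in the source formulation.
* **High-rail lane meniscus** (gap H, width w_H): a channel-spanning
  interface with curvature contributions from both the gap and the width.

### The Δp_H convention flag

The two published statements of the high-rail pressure are mutually
inconsistent: the formula carries a factor 2 — Δp_H = 2γ(1/w_H + 1/H) — while
the worked numeric value (311.9 Pa at γ = 71.97 mN/m, H = 300 μm,
w_H = 1 mm) equals γ(1/w_H + 1/H). The design boundary H = h/(1 − h) (lengths
in mm at w_H = 1 mm), and every reported geometry outcome, are consistent
only with the factor-2 form. We therefore default to `FACTOR2` and keep
`SINGLE_INTERFACE` solely to reproduce the printed value; no attempt is made
to guess which was intended. Both forms are exposed on every pressure-taking
operation through `PressureModelOptions.hr_convention`, and
`FACTOR2 = 2 × SINGLE_INTERFACE` holds identically.

### Water surface tension

The tabulated surface tension of water at 25 °C is 72.9 mN/m, but the worked
pressure triple (1439 / 479.8 / 311.9 Pa) backs out to γ = 71.97 mN/m. The
fluid library ships both (`water_table1`, `water_numeric`); quantitative
reference checks use 71.97 mN/m and the ~1.3% discrepancy is inherited, not
resolved, here.

## Classification and design boundaries

With Δp_L largest, patterning succeeds: `SUCCESS_CONTINUOUS`
(Δp_L > Δp_O > Δp_H, the lane empties in one sweep once the port bursts) or
`SUCCESS_STEPWISE` (Δp_L > Δp_H > Δp_O, further suction is needed after the
port burst). Otherwise the low rail gives way first
(`FAIL_LR_BEFORE_PORT`, Δp_O ≥ Δp_L) or after the port burst
(`FAIL_LR_AFTER_PORT`, Δp_O < Δp_L ≤ Δp_H). Exact ties are measure-zero but
resolve deterministically by those ≥/≤ conventions and emit a
`BoundaryWarning` — reproducibility is preferred over pretending the case
cannot occur. γ cancels in every comparison, so the class of a geometry is
identical for all fluids.

The boundaries follow in closed form: Δp_L = Δp_O gives D* = 2h
(fluid-independent), and Δp_L = Δp_H under `FACTOR2` gives
H* = h·w_H/(w_H − h), which requires h < w_H (no positive solution
otherwise). `phase_diagram` sweeps default grids of h ∈ [50, 300] μm step
5, D ∈ [100, 1000] μm step 10, H ∈ [100, 500] μm step 5 — spanning the
experimentally probed designs — and flags per column the cell nearest the
closed-form curve; the exact polyline comes from `boundary_polyline`.

## Quasi-static aspiration simulation

The simulator has **no time axis**: the applied suction rises monotonically
from 0 to its maximum, and events fire in ascending threshold order. This is
a deliberate abstraction — the underlying model is purely static capillary
thresholds, and meniscus kinetics (viscous drops, contact-line velocity)
are outside its scope. Consequences and conventions:

* A lane's clearing threshold is `max(Δp_O(entry port), Δp_H(lane))`; the
  entry port is the lane's open port (for the aspiration lane, its
  non-aspirating port; for a two-open-port lane, the larger port bursts
  first and governs). A lane whose only port is the aspiration port has no
  air-entry path and is a validation error.
* The low-rail region is one interface with threshold Δp_L evaluated at the
  **minimum** low-rail gap in the device: the most fragile meniscus governs,
  which errs on the side of predicting failure.
* Equal thresholds of distinct regions are ordered lexicographically by id
  with a `TIE` warning — deterministic replay over physical realism for
  measure-zero cases. At equal pressure a port burst is reported before the
  lane clearing it enables.
* A non-aspiration lane with two equal open ports emits `FILM_TRAP` and
  never clears: rupturing the trapped film needs extra pressure (a foam
  film carries two interfaces) that the model does not quantify. A config
  knob `film_break_extra_pressure` (default ∞) exists purely for
  sensitivity exploration.
* `success` = every lane cleared and no `LR_INVASION`.

Observations at modestly super-threshold suctions (~1950 Pa against
Δp_L = 1439 Pa) suggest patterning can survive brief over-pressure; this is
deliberately **not** modelled — the window uses the strict quasi-static
threshold, and an `lr_tolerance_factor`-style relaxation was rejected to keep
the reported window a pure model prediction.

## Uniformity statistic

`U = [1 − (Max − Min)/(2·Avg)] × 100 %` over replicate retained areas,
exactly as printed: permutation- and scale-invariant, 100% iff all areas are
equal, and unclamped — spreads exceeding twice the mean yield negative U with
a warning, since the source does not state clamping. Note that adding a
replicate strictly inside [Min, Max] leaves the spread unchanged but moves
the mean, so U does change unless the new replicate sits exactly at the
mean. Area measurement on label masks is exact pixel counting ×
pixel_size²; published uniformity values (92.5% / 89.0%) come from
photographs of physical devices and are not reproducible from synthetic
masks, so they are demonstrated in form, not in value.

## Synthetic data: what it emulates and what it does not

The generators produce: valid/invalid single-lane devices around the design
boundaries; multi-lane arrays with ordered opposing-port diameters
(three-lane S/N/U replica with h = 75 μm, and a 98-lane array replica);
film-trap configurations; seeded multiplicative-Gaussian replicate areas
(`area = mean × (1 + σz)`, negative draws rejected, ≤100 retries — chosen
multiplicative because it preserves positivity and the scale-invariance of
U); and rasterised retained-footprint masks. Replica port diameters not on
record are chosen once: 450/350/250 μm for the three-lane device and
460→250 μm linearly spaced for the 98-lane array — strictly decreasing, all
above 2h, and all inside the port-dominated regime (4γ/D > Δp_H) so the
clearing order is set by the ports, with the aspiration lane's opposing hole
smallest. Only the *order* of formation is asserted for the replicas, never
timing or exact layout.

Not emulated: photographic appearance (dye color, optics), dye diffusion,
meniscus kinetics, fabrication tolerances, and operator variability beyond
the single σ knob. Passing tests therefore validate the capillary model and
its implementation, not the behavior of any physical print of these designs.

## Numerical choices

* Internal units are SI; config files and factories use μm and mN/m with
  exact power-of-ten conversion at the boundary (round-trip drift ≤ a couple
  of ulps, from decimal↔binary representation only).
* Boundary operations are algebraically exact: the pressure residual at the
  returned D* and H* is below 10⁻⁹ relative, limited by floating point.
* Mask rasterisation uses polygon scan conversion; at the default 10 μm/px
  the area of the reference footprint converges within 1% under mesh
  refinement.
* The simulator is fully deterministic; the only RNG in the package is the
  seeded replicate-area sampler (`numpy.random.default_rng`).
* Problem sizes used in the shipped checks — 10⁴ random geometries for the
  classifier oracle, 10³ random ≤20-lane devices for the event-order oracle,
  n = 1000 replicates for noise recovery — are the package's chosen
  verification scale and complete in seconds.

## Known limitations

* The general two-radius Young–Laplace expression is never evaluated; only
  the reduced per-interface forms are implemented, so exotic rail
  cross-sections are out of scope.
* Lane path shape (straight, S, N, U, circles) is rendering metadata; the
  model sees only h, H, w_H, D and therefore cannot capture path-dependent
  effects such as corner pinning along curved rails.
* The film-trap rule is binary; real films rupture at some finite extra
  pressure that the model leaves unquantified.
* Quasi-static event ordering has no notion of simultaneity: lanes with
  identical thresholds clear "in order" only by the lexicographic
  convention.
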