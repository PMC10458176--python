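# Methods

`lyopnm` simulates primary freeze drying — the sublimation stage of
lyophilization — at the pore scale. The frozen product is represented as a
regular three-dimensional bond network: the entire void space is assigned
to cylindrical pores that meet at volumeless computational nodes, and each
node carries a cubic control volume (CV) with edge length equal to the
pore length. Mass balances (vapor pressure) and enthalpy balances
(temperature) are solved on the nodes; pores carry the geometry and the
transport resistances.

## Model

### Lattice and control volumes

Nodes sit on a regular grid with spacing `L_cv` (default 10 µm). Vertical
pores connect z-adjacent nodes; lateral pores connect x/y-adjacent nodes
with one periodic wrap pore per row and column, so the side boundaries are
periodic. The default 5×5×15 grid has 375 nodes and 1100 pores
(350 vertical + 375 + 375 lateral). The top node layer faces the drying
chamber; the bottom layer sits on the heating shelf and is impermeable to
mass.

Pore diameters are normally distributed. The monomodal network draws every
diameter from N(5, 0.2) µm. The bimodal network emulates a sample whose
periphery froze faster (smaller ice crystals): pores whose two end nodes
both lie in the central 3×3 block of lateral node columns are *large*
(N(5, 0.2) µm), all others are *small* (N(1, 0.2) µm). On the default grid
this puts 306 large and 794 small pores (count ratio 2.59). Draws at or
below 0.1 µm are resampled; at the default spread this is a ~1e-90
probability event per draw, so the distribution moments are effectively
exact.

The CV porosity collects half of every incident pore volume,
`eps_cv = (Σ V_ij / 2) / L_cv³`, which conserves total pore volume
exactly. CV saturation is the ice volume over the void volume of the CV;
partially saturated pores hold their ice uniformly (the position of the
ice interface inside a pore is not tracked).

### Effective properties (Krischer mixing)

Density and heat capacity mix linearly in the ice and solid fractions.
Thermal conductivity uses the Krischer rule: the weighted harmonic
combination `lam = [a/lam_ser + (1-a)/lam_par]^-1` of the series and
parallel bounds of the ice/solid composite, with `a = 0.5`. The vacated
pore fraction `(1 - S)·eps` contributes neither conductance nor
resistance; this makes the dry cake conduct worse than the frozen material
(≈0.36 vs ≈1.17 W/m/K at eps = 0.58) but keeps it finite, and below full
saturation it can place the "series" bound above the "parallel" one — the
effective value always lies between the two. At full saturation the
network-average porosities of the two reference lattices (≈0.575 and
≈0.177) give λ_eff ≈ 1.17 W/m/K (monomodal) and ≈0.69 W/m/K (bimodal).

### Ice–vapor equilibrium

The saturation pressure over ice follows the Goff–Gratch correlation with
triple point T* = 273.16 K, P* = 610.71 Pa; it is used for the front
boundary condition and inverted by bracketed bisection (tolerance 1e-9 K)
to convert chamber pressure to chamber temperature. At the default
conditions: P_eq(−18 °C) = 124.7 Pa, P_eq(−28 °C) = 46.6 Pa, and 10 Pa
corresponds to −42 °C.

### Vapor transport

Vapor flows only through completely empty pores, under quasi-steady
conditions. The pore transport coefficient spans the Knudsen–viscous
transition regime,

    K = d² P̄ / (32 η) · (1 + 8.88 Kn + 4.96 Kn²),    Kn = Λ / d,
    Λ = (η / P̄) √(π R T̄ / (2 M)),

with arithmetic-mean pore temperature and pressure; the mass conductance
is `g = A M K / (R T̄ L)`. At the process pressures (10–125 Pa) the mean
free path is ~100 µm, so 5 µm pores sit deep in the Knudsen regime and the
literal SI evaluation gives K values orders of magnitude above published
dry-cake coefficients quoted in different unit conventions; the literal
equations are implemented and the coefficients are reported as computed.

The pressure field solves node mass balances on the *vapor-active*
subgraph: top-layer nodes plus every node reachable from the top through
empty pores. Front nodes (active nodes still touching an ice-containing
pore) are Dirichlet-pinned at the local equilibrium pressure P_eq(T_i);
top-layer nodes couple to the chamber pressure through the constant
surface coefficient g_inf = 1e-12 kg/(s·Pa) per node. Because conductances
depend on pressure, they are evaluated with the previous step's pressure
field (sequential coupling; one linear solve per step). Interior balances
close to solver precision and the total front production equals the total
top outflow identically.

At t = 0 the network is fully saturated and no empty pore exists;
sublimation is seeded by treating all top-layer nodes as front nodes
against the chamber. Their equilibrium pressure at the warm initial
temperature (−28 °C vs the chamber's −42 °C) produces the characteristic
high initial rate that collapses by S ≈ 0.99 once the surface pores dry.

### Sublimation and heat transfer

Each front node's *positive* net vapor production is apportioned to its
incident ice-containing pores in proportion to their cross sections; a
pore may collect from both ends. Negative nodal balances (vapor arriving
at a cold front node) are disregarded — condensation is not modelled.
Each subliming pore charges half of its latent heat `Δh_sub · Ṁ` to each
of its two end CVs.

The CV enthalpy balance (conduction with harmonic-mean interfacial
conductivity, upwinded vapor advection through empty pores, explicit
sublimation sinks) advances by one implicit Euler step per coupling step,
solved in banded form. Bottom CVs conduct to the shelf across half a cell,
`A_cv λ_cv (T_bot − T_i)/(L_cv/2)`. The top surface exchanges heat only
through the leaving vapor: an upwinded outflow leaves at the CV's own
temperature and therefore exerts no relative cooling, which renders the
dry region nearly adiabatic at the top — consistent with the model's
near-uniform dry-layer temperatures. The enthalpy flow carried to the
chamber, `Ṁ_i∞ (Δh_sub + c_p,v T_i)`, is recorded per step as a
diagnostic rather than charged to the top CV: the latent part was already
paid by the front sink, and double-charging it would impose kelvin-scale
spurious gradients in the dry layer.

### Time stepping and coupling

Each step executes, in order: property update → pressure solve →
sublimation apportioning → time-step selection → implicit heat step → ice
bookkeeping. The step is `dt = min(safety · dt_h, dt_m)` with

    dt_h = min over CVs of V_cv (ρ c_p)_cv L_cv / Σ_j (λ_if A_cv),
    dt_m = min over subliming pores of m_ice / Ṁ_sub,

so the fastest pore empties exactly at a step boundary and the
vapor-conducting topology never lags the ice inventory. `dt_h` evaluates
to ~3e-5 s for the reference lattices, which makes a full drying run a few
hundred thousand steps; the banded solves keep this to a few minutes of
wall time. The safety factor defaults to 1.0 — implicit Euler is
unconditionally stable, but the sequential (non-iterated) coupling is the
accuracy-limiting element, so the controller is kept. A run terminates
when the overall saturation reaches zero; a step in which no pore sublimes
while ice remains raises a stall error.

### Audits

Two closures are accumulated over every run and written to `audit.json`:

* **Mass**: initial ice mass vs the time-integrated top outflow. These
  differ only by disregarded negative front balances, and close to
  ~1e-12 in the reference runs.
* **Energy**: the integrated terms the discrete scheme actually exchanges
  — shelf influx, net advective heating, sublimation sinks, storage change
  at per-step-frozen properties. This closes to solver precision by
  construction; it verifies the consistency of the assembled systems, not
  an independent physical estimate. Sensible enthalpy removed with the ice
  mass is outside the heat equation (ice removal is isothermal
  bookkeeping) and is not part of the balance.

### Front metrics

The sublimation front is the set of ice-containing pores in contact with
the vapor-active region. Every pore belongs to one horizontal slice:
lateral pores to their node layer, vertical pores to the layer of their
*upper* node (their midpoint lies exactly on the slab boundary and is
rounded toward the open top; this convention makes a flat receding front
occupy exactly one slice). MAP/LAP are the extreme front-pore slice
heights (most/least advanced point), MFP the ice-volume-weighted mean, and
the width counts occupied layers inclusively: `(LAP − MAP) + L_cv`.

These exact extremes are recorded at every step. For the *summary*
statistic `max_front_width` the per-step series is binned into saturation
windows of 0.05 and the within-window **median** is maximised. Rationale:
when a pore layer finishes, its last, nearly drained pores (holding a few
percent of a layer's ice) coexist for a short interval with the freshly
exposed layer below, and the instantaneous extremes read one extra layer.
Front structure is characterised per saturation stage — the same
convention as the slice-profile snapshots — and the median over a window
reports the prevailing width at that stage while such single-step
emptying transients, which a slice-saturation reading would not resolve,
do not register. Sustained widening (the pinned-periphery regime of the
bimodal network) spans many windows and is fully captured. This convention
was fixed at design time.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| nx × ny × nz | 5 × 5 × 15 | – | node grid (x-fastest numbering) |
| L_cv | 10 | µm | pore length = CV edge |
| d (mono / bi-large, bi-small) | 5 ± 0.2 / 1 ± 0.2 | µm | pore diameter distributions |
| center_extent | 3 | – | lateral span of the large-pore core |
| ρ_ice, ρ_s | 919, 1565 | kg/m³ | ice / maltodextrin density |
| λ_ice, λ_s | 2.42, 0.5 | W/m/K | thermal conductivities |
| c_p,ice, c_p,s, c_p,v | 1930, 1250, 1617 | J/kg/K | heat capacities |
| Δh_sub | 2838 | kJ/kg | sublimation enthalpy |
| η(T) | 18.4558e-7·T^1.5/(T+650) | Pa·s | vapor viscosity |
| a | 0.5 | – | Krischer weighting |
| T_bot / T_init / T_∞ | −18 / −28 / −42 | °C | shelf / initial / chamber |
| P_∞ = P_init | 10 | Pa | chamber / initial pressure |
| g_inf | 1e-12 | kg/(s·Pa) | per-node surface vapor coefficient |
| safety | 1.0 | – | multiplier on dt_h |
| snapshot_ds | 0.05 | – | saturation spacing of state snapshots |

Material constants are constant in temperature (mean values over the
process window); only the vapor viscosity carries a temperature law. All
constants are overridable through the YAML configuration.

## What the generator emulates — and what it does not

The synthetic lattices reproduce the *statistics* of a freeze-dried
maltodextrin microstructure (pore-size distribution, porosity, spatial
segregation of large and small pores) on a regular grid. Real frozen
matrices have irregular topology, correlated pore sizes, non-cylindrical
throats and anisotropy from directional freezing; none of these are
represented, and conclusions about real products should treat the
simulations as structure–transport studies, not as product-specific
predictions. In particular the flat, single-layer monomodal front is
partly an artefact of the regular geometry and of not tracking the ice
interface inside pores. Shrinkage, collapse, bound-water desorption
(secondary drying), radiative heating, inert-gas diffusion and capillary
liquid transport are out of scope.

## Numerical choices

* Linear systems are assembled directly in LAPACK banded storage (the
  x-fastest node numbering bounds couplings to nx·ny indices off the
  diagonal) and solved with `scipy.linalg.solve_banded`.
* The pressure solve validates itself by checking interior node balances
  against the round-off floor `eps · g · P`; the heat step validates a
  per-step energy identity to 1e-7 of the system scale.
* Ice volumes within 1e-12 of empty are snapped to zero so drained pores
  leave the inventory instead of lingering as numerical residue.
* Conductances use the previous step's pressures (quasi-steady lag); no
  inner iteration is performed, matching the sequential coupling.
* Ties in front pinning (a node touching several ice pores) need no
  special handling: the node is pinned once and its production is shared
  by cross-section.
* Degenerate lattices: a 1-wide axis has no lateral pores (a wrap edge
  would be a self-loop); a 2-wide axis keeps a single lateral pore per
  row (the wrap duplicate is dropped).

## Regime sensitivity of front widening

At chamber pressures of order 10–100 Pa the vapor mean free path
(~100 µm) far exceeds the pore diameters, so the transition-regime
coefficient is Knudsen-dominated and nearly independent of diameter; the
pore conductance contrast between 1 µm and 5 µm pores is then just the
area ratio, 25×. Under these conditions the bimodal network's front
widens to about two pore layers in the reference runs: the peripheral
small pores are slower but never decisively pinned, because the pressure
drop along the fast central channels exceeds the equilibrium-pressure
differences that would otherwise stall the periphery. In a
viscous-dominated setting (higher pressures, or larger pores) the
contrast scales with d⁴ (625× here) and peripheral pinning — and hence
front widening — would be far stronger. Reported front widths should be
read with this regime dependence in mind.

## Known limitations

* Disregarding negative front balances means local condensation is
  silently dropped; the mass audit quantifies the effect (negligible in
  the reference runs).
* The sequential coupling makes the solution first-order accurate in
  time; dt_h is small enough that this is not the dominant error, but no
  step-doubling control is performed.
* The absolute drying times depend directly on g_inf and on the literal
  transition-regime coefficients; only ratios and front structure are
  validated against independent references.
* `solve_banded` cost grows with (nx·ny)²·N, so very wide lattices would
  warrant a sparse factorisation instead.
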