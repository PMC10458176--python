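# lyopnm — a non-isothermal pore-network model of primary freeze drying

`lyopnm` simulates the primary-drying (sublimation) stage of
lyophilization at the pore scale. It is aimed at process modellers and
formulation scientists who want to study how the *microstructure* of a
frozen product — pore sizes and their spatial arrangement — shapes the
sublimation front, the local temperature and pressure fields, and the
drying kinetics, which vial-scale continuum models average away.

## Model

The frozen product is a regular 3D bond lattice: cylindrical pores of
length `L` joined at volumeless nodes, each node carrying a cubic control
volume (CV) with saturation-dependent effective properties. Ice fills the
pores; drying proceeds from the open top while a shelf at `T_bot` heats
the bottom and the lateral boundaries are periodic.

Per time step the engine solves, sequentially:

* **Quasi-steady vapor transport** on the vapor-connected subnetwork.
  Empty pores conduct with the transition-regime (Knudsen + viscous)
  coefficient

  `K_ij = d_ij² P̄ᵢⱼ / (32 η) · (1 + 8.88 Kn + 4.96 Kn²)`, `Kn = Λ/d`,

  giving node mass balances `Σⱼ g_ij (P_i − P_j) = 0` with
  `g_ij = A_ij M̃ K_ij / (R̃ T̄ᵢⱼ L)`. Sublimation-front nodes are pinned
  at the Goff–Gratch equilibrium pressure `P_eq(T_i)` over ice; the top
  couples to the chamber (`P_∞` = 10 Pa) through a constant surface
  coefficient `g_∞`.
* **Sublimation**: each front node's positive vapor production is shared
  among its ice-containing pores by cross-section; each subliming pore
  charges `½ Δh_sub Ṁ` of latent heat to each end CV.
* **Transient heat transfer**: an implicit-Euler CV enthalpy balance with
  Krischer effective conductivities (series/parallel mixing, `a = 0.5`),
  upwinded vapor advection, shelf contact below and a vapor-borne top
  efflux.
* **Ice bookkeeping** with the adaptive step
  `Δt = min(Δt_heat, Δt_mass)`, chosen so the fastest pore empties
  exactly at a step boundary.

Two reference microstructures are built in: a *monomodal* network
(all pores ~ N(5, 0.2) µm — a homogeneous product) and a *bimodal* one
(5 µm pores in the central 3×3 node columns, 1 µm pores along the
periphery — a product frozen faster at its sides).

## Worked example

```python
from lyopnm import make_fixture, run_primary_drying

net, cfg = make_fixture("mono_small")     # fast 3x3x5 monomodal lattice
rec = run_primary_drying(net)
print(f"dried in {rec.drying_time:.3f} s, "
      f"mass closure {rec.audit['mass_closure']:.1e}")
```

Running `python examples/03_small_drying_run.py` prints

```
drying time: 0.592 s in 43865 steps
mass closure: 3.82e-15
energy closure: 1.78e-14

   S      t [s]   rate [kg/s]  MFP [um]  T_front [degC]
  0.90    0.0172  1.298e-10     40.0      -34.16
  0.70    0.0749  5.234e-11     30.0      -23.04
  0.50    0.1762  3.626e-11     20.0      -20.51
  0.30    0.3145  2.746e-11     10.0      -19.16
  0.10    0.4893  2.233e-11      0.0      -18.39
```

The overall ice saturation `S` falls from 1 to 0 while the mean front
position `MFP` recedes from the open top (40 µm) to the shelf (0 µm); the
front temperature climbs from its sublimation-cooled minimum toward the
shelf's −18 °C; and the integrated top outflow returns the initial ice
mass to machine precision (`mass closure`).

`python examples/05_reference_scale_run.py` repeats this for the two
full-size reference networks and prints the headline comparison — the
monomodal front stays one 10 µm pore layer wide, the bimodal front
widens, and the monomodal network takes ~1.3× longer to dry than the
bimodal one, which holds ~3.3× less ice.

There is also a small CLI: `lyopnm generate|run|regimes|metrics`
(`lyopnm run --mode bimodal --seed 1 --out out/` writes
`drying_curve.csv`, per-slice profiles, JSON snapshots and the
mass/energy audit).

## Layout

| path | contents |
|---|---|
| `src/lyopnm/network.py` | lattice generator, CV geometry |
| `src/lyopnm/properties.py` | material constants, Goff–Gratch, Krischer |
| `src/lyopnm/vapor.py` | transition-regime conductances, pressure solve |
| `src/lyopnm/heat.py` | implicit-Euler enthalpy balance |
| `src/lyopnm/engine.py` | coupling loop, time stepping, drying record |
| `src/lyopnm/metrics.py` | slice profiles, front MFP/MAP/LAP/width |
| `src/lyopnm/regimes.py` | closed-form MTL/HTL/transition/Darcy rates |
| `src/lyopnm/config.py`, `io.py`, `cli.py`, `fixtures.py` | configuration, serialization, CLI |
| `docs/methods.md` | model description, assumptions, numerical choices |
| `examples/` | one narrative script per capability |

See `docs/methods.md` for the full model description, parameter table,
measurement conventions and known limitations.
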