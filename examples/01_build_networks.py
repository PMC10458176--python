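"""Build the two reference pore networks and inspect their geometry.

The monomodal lattice emulates a homogeneous frozen maltodextrin matrix
(every pore ~ Normal(5, 0.2) um); the bimodal lattice has large 5 um pores
in the central 3x3 block of node columns and small 1 um pores along the
periphery, mimicking faster freezing (smaller ice crystals) at the sides.
"""


from lyopnm import LatticeSpec, assign_diameters, build_lattice, compute_cv_geometry

for mode in ("monomodal", "bimodal"):
    spec = LatticeSpec(psd_mode=mode, seed=2131)
    net = assign_diameters(build_lattice(spec), spec)
    cvg = compute_cv_geometry(net)
    print(f"--- {mode} lattice ({spec.nx}x{spec.ny}x{spec.nz}, L = {spec.L_cv_um} um)")
    print(f"nodes: {net.n_nodes}, pores: {net.n_pores}")
    if net.large is not None and mode == "bimodal":
        n_l, n_s = int(net.large.sum()), int((~net.large).sum())
        print(f"large pores: {n_l}, small pores: {n_s} (ratio {n_s / n_l:.2f})")
    print(f"total ice volume: {net.V.sum() / 1e-18:.4g} um^3")
    print(f"overall porosity: {cvg.overall_porosity(net.n_nodes):.3f}")
    print(f"CV porosity range: {cvg.eps.min():.3f} .. {cvg.eps.max():.3f}")
    print()

# The porosity is the fraction of the 50 x 50 x 150 um domain occupied by
# pores; the bimodal network holds ~3.3x less ice than the monomodal one,
# which is why it dries faster despite its higher transport resistance.
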