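"""Closed-form drying-regime envelopes (MTL / HTL / transition / Darcy).

Tabulates the area-specific rates for the monomodal effective parameters;
overlaying these on a simulated rate curve reproduces the classical
regime comparison.
"""


from lyopnm import RegimeParams, darcy_rate, regime_rates

params = RegimeParams(K_eff=5.63e-6, lam_eff=1.1731)

print("   S     m_MTL        m_HTL        m_trans   [kg/s/m^2]")
for S in (0.99, 0.9, 0.7, 0.5, 0.3, 0.1):
    rr = regime_rates(S, params)
    print(f"  {S:.2f}  {rr.mtl:.4e}  {rr.htl:.4e}  {rr.trans:.4e}")

print()
print("Darcy rate vs front depth (T_front = -25 degC):")
for z_um in (0.0, 50.0, 100.0, 140.0):
    m = darcy_rate(z_um * 1e-6, 248.15, RegimeParams(K_eff=4.7e-12, lam_eff=1.0))
    print(f"  z_front = {z_um:5.1f} um: {m:.4e} kg/s/m^2")

# The transition rate is the harmonic combination of the mass- and
# heat-transfer-limited branches and never exceeds either; the Darcy rate
# diverges as the cake thickness L_PN - z_front vanishes.
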