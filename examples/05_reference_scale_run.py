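"""Full reference-scale comparison: monomodal vs bimodal drying (~15 min).

Runs both 5x5x15 networks to completion and prints the headline
comparison: front structure, drying-time ratio and initial heat flows.
"""

from lyopnm import make_fixture, run_primary_drying
from lyopnm.io import record_summary

records = {}
for name in ("mono_ref", "bi_ref"):
    net, cfg = make_fixture(name)
    print(f"running {name} ({net.n_pores} pores)...", flush=True)
    records[name] = run_primary_drying(net)
    for key, val in record_summary(records[name]).items():
        print(f"  {key}: {val}")

mono, bi = records["mono_ref"], records["bi_ref"]
print()
print(f"drying-time ratio mono/bi: {mono.drying_time / bi.drying_time:.2f}")
print(
    "initial bottom heat-flow ratio mono/bi: "
    f"{mono['Q_bot'][0] / bi['Q_bot'][0]:.3f}"
)

# The monomodal front stays one pore layer (10 um) wide; the bimodal front
# widens as the large central pores outrun the smaller peripheral pores.
# The bimodal network dries faster in absolute time because it holds
# ~3.3x less ice.
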