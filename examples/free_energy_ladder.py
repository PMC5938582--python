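"""Build the complex I pumping cycle and print its free-energy ladder.

The 17-state cycle couples the two-electron NADH -> ubiquinone redox
drop (-320 -> +90 mV, about -19 kcal/mol) to the translocation of four
protons.  At zero proton motive force the ladder descends to the end
state IX at the full redox drop; at a physiological 200 mV the four
pumped charges claw back ~18.4 kcal/mol and IX sits just below zero —
the machine runs close to equilibrium.
"""

import pcetpump as pp

model = pp.build_model(pp.load_model("complex_i_ubiquinone"))

p0 = pp.apply_pmf(model, 0.0)
p200 = pp.apply_pmf(model, 200.0)

print(f"{'state':8s} {'dG(0 mV)':>10s} {'dG(200 mV)':>11s}   barrier")
for (s, g0, b), (_, g200, _) in zip(p0, p200):
    bar = f"{b:5.1f}" if b is not None else "  ?  "
    print(f"{s:8s} {g0:10.2f} {g200:11.2f}   {bar}")

print()
print(f"total translocated charge per cycle : {model.total_translocated_charge:.1f} H+")
print(f"stall pmf                           : {pp.stall_pmf(model):.0f} mV")
print("energies in kcal/mol; '?' marks a barrier no data constrains")
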