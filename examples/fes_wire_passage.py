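"""Electron tunneling down the FMN -> N2 iron-sulfur wire.

Per-step rates come from the empirical distance ruler (lambda = 0.7 eV,
packing density 0.76); most centers are near-equipotential at -320 mV
and the terminal N2 sink lies higher, so the last hop is downhill.  The
mean first-passage time of one electron over the whole wire lands in
the ~100 microsecond domain, dominated by the 14 A N5 -> N6a bottleneck.
"""

import pcetpump as pp

path = pp.packaged_model_path("complex_i_ubiquinone").parent / "fes_wire_complex_i.tsv"
chain = pp.read_chain(path)

rates = pp.chain_step_rates(chain)
print(rates[["donor", "acceptor", "r_A", "dG_ev", "log10_k_fwd"]].to_string(index=False))

tau = pp.chain_passage_time(chain)
print(f"\nmean first-passage time FMN -> N2: {tau * 1e6:.0f} us")
print("log10 k in s^-1; the 14 A step carries ~10^4.7 s^-1 and sets the pace")
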