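"""A passive single-site proton channel, with and without a pmf.

The simplest membrane proton-transfer model: N-side bulk (pH 7) ->
buried site with pKa 8 halfway across the membrane -> P-side bulk
(pH 7), uptake and release on ~1 us timescales.  Without a pmf the
bound state sits 1.4 kcal/mol below bulk (pKa > pH); a 200 mV gradient
lifts the bound state by 2.3 and the far side by 4.6 kcal/mol — which
is why a *pump* must modulate the site's pKa to move protons uphill.
"""

import pcetpump as pp

for pmf in (0.0, 200.0):
    prof = pp.single_site_pump_profile(8.0, pmf_mv=pmf)
    row = "  ".join(f"{s}: {g:+.2f}" for s, g, _ in prof)
    print(f"pmf {pmf:5.0f} mV   {row}   (kcal/mol)")

barrier = pp.single_site_pump_profile(8.0).barriers_out[0]
print(f"\nuptake/release barrier from the 1 us step time: {barrier:.1f} kcal/mol")
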