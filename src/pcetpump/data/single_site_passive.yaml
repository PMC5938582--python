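# Passive single-site membrane proton transfer: N-side (pH 7) -> buried
# site with pKa 8 halfway across the membrane -> P-side (pH 7), with
# uptake/release on a 1 us timescale.
schema_version: 1
name: single_site_passive
kind: single_site
constants_mode: exact
parameters:
  pKa: 8.0
  pH_N: 7.0
  pH_P: 7.0
  step_time_s: 1.0e-06
  buried_fraction: 0.5
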