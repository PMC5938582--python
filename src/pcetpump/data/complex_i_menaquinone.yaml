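# Menaquinone variant of the packaged complex I cycle: the acceptor
# midpoint potential drops to -80 mV, so the cycle transduces only
# ~ -11 kcal/mol instead of ~ -19.
schema_version: 1
name: complex_i_menaquinone
kind: complex_i
constants_mode: exact
parameters:
  donor_em_mv: -320.0
  acceptor_em_mv: -80.0
  n_electrons: 2
  ph_n: 7.0
  ph_p: 7.0
  uptake_pka: 10.0
  release_pka: 9.0
  q_motion_fraction: 0.6
  relay_step_dg: -1.0
  q_reduction_barrier: 13.0
  q_motion_barrier: 4.0
  ion_pair_barrier: 4.0
  relay_barrier: 10.0
  water_barrier: 10.0
  buried_fraction: 0.5
  unknown_barrier_ceiling: 14.0
  exchange_barrier: 14.0
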