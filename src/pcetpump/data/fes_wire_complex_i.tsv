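# FMN -> N2 iron-sulfur wire of complex I (synthetic representative
# geometry): midpoint potentials are the near-equipotential -320 mV for
# all centers except the N2 sink (-160 mV); edge-to-edge distances are
# chosen inside the structurally observed 9-14 A range with the N5->N6a
# bottleneck at 14 A (exact per-pair distances are not tabulated here).
# lambda = 0.7 eV throughout; packing density rho = 0.76 is supplied by
# the chain reader. N7 is ~22 A off-pathway and carries no wire current.
label	Em_mV	r_to_next_A	lambda_eV	on_path	note
FMN	-320	9.5	0.7	true	electron entry (NADH/FMN site)
N3	-320	11.0	0.7	true
N1b	-320	10.8	0.7	true
N4	-320	9.2	0.7	true
N5	-320	14.0	0.7	true	bottleneck to N6a
N6a	-320	9.6	0.7	true
N6b	-320	10.4	0.7	true
N2	-160		0.7	true	terminal sink above the Q site
N7	-320	22.0	0.7	false	off-pathway from N3; not on the wire
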