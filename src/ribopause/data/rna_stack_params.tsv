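# Turner-style RNA/RNA nearest-neighbor stack free energies, DeltaG37 in kcal/mol.
# Each row is one stack of two adjacent base pairs written
#     5'-T1 T2-3'   ->  key "T1T2/B1B2"
#     3'-B1 B2-5'
# where T_i pairs with B_i (Watson-Crick or GU wobble). Only one orientation per
# motif is listed; the symmetric orientation (B2B1/T2T1) is derived on load.
# Watson-Crick/Watson-Crick entries are the published Xia et al. 1998 values.
# Entries marked 'approx' are GU-wobble stacks set to representative Turner-style
# magnitudes, constrained so that no wobble stack outcompetes its Watson-Crick
# counterpart (perfect complementarity is always optimal); downstream
# weak/strong thresholds are calibrated to this table.
top_bottom	delta_g	note
AA/UU	-0.93	wc
AU/UA	-1.10	wc
UA/AU	-1.33	wc
CU/GA	-2.08	wc
CA/GU	-2.11	wc
GU/CA	-2.24	wc
GA/CU	-2.35	wc
CG/GC	-2.36	wc
GG/CC	-3.26	wc
GC/CG	-3.42	wc
AG/UU	-0.55	wobble
AU/UG	-1.36	wobble
UG/AU	-1.00	approx
UU/AG	-1.27	approx
CG/GU	-1.41	wobble
CU/GG	-1.77	approx
GG/CU	-1.53	wobble
GU/CG	-2.51	wobble
GG/UU	0.47	approx
GU/UG	0.30	approx
UG/GU	-0.60	approx
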