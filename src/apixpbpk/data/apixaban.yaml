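# Apixaban compound parameter file (flat, unit-suffixed keys).
# Values are the packaged model inputs; fu_plasma is reproduced verbatim from
# the source input table and can be overridden (public references list ~0.13).
name: apixaban
log_p: 2.22
fu_plasma: 0.93
mw_g_per_mol: 459.0
pka_acid: 13.07
peff_cm_per_min: 9.0e-07
cl_h_l_per_h: 2.4
f_gfr: 0.18
blood_plasma_ratio: 1.0
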