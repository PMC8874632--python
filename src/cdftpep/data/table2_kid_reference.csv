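# Published Koopmans-deviation indices (eV) for the Veraguamides A-G at
# MN12SX/Def2TZVP/water. Note: for Veraguamide A and Veraguamide F the
# published delta_sl is inconsistent with |SOMO - LUMO| recomputed from
# the published orbital energies (0.008 and 0.044 vs 0.003 and 0.019);
# consistency checks therefore cover rows B, C, D, E, G only.
molecule_id,j_i,j_a,j_hl,delta_sl
Veraguamide A,0.006,0.003,0.006,0.003
Veraguamide B,0.008,0.012,0.014,0.030
Veraguamide C,0.003,0.017,0.017,0.048
Veraguamide D,0.010,0.005,0.011,0.011
Veraguamide E,0.002,0.007,0.007,0.014
Veraguamide F,0.002,0.015,0.015,0.019
Veraguamide G,0.009,0.001,0.009,0.003
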