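# Published global reactivity descriptors (eV; softness in 1/eV) for the
# Veraguamides A-G at MN12SX/Def2TZVP/water.
molecule_id,chi,eta,omega,softness,nu,omega_minus,omega_plus,net_electrophilicity
Veraguamide A,3.760,5.751,1.229,0.174,2.157,4.697,0.937,5.634
Veraguamide B,3.790,5.695,1.261,0.176,2.156,4.772,0.983,5.755
Veraguamide C,3.903,5.819,1.309,0.172,1.981,4.932,1.030,5.962
Veraguamide D,3.704,5.913,1.160,0.169,2.132,4.543,0.838,5.381
Veraguamide E,3.795,6.156,1.170,0.162,1.920,4.621,0.827,5.448
Veraguamide F,3.867,5.702,1.311,0.175,2.075,4.912,1.045,5.957
Veraguamide G,3.734,5.926,1.177,0.169,2.096,4.590,0.856,5.447
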