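# Bioactivity scores of the Veraguamides A-G from external
# similarity-based target prediction (ingestion-only input).
molecule_id,GPCR Ligand,Ion Channel Modulator,Nuclear Receptor Ligand,Kinase Inhibitor,Protease Inhibitor,Enzyme Inhibitor
Veraguamide A,-0.42,-1.45,-1.21,-1.18,0.05,-0.83
Veraguamide B,-0.33,-1.31,-1.07,-1.02,0.13,-0.73
Veraguamide C,-0.29,-1.21,-1.06,-0.96,0.20,-0.62
Veraguamide D,-0.42,-1.39,-1.22,-1.18,0.12,-0.76
Veraguamide E,-0.55,-1.57,-1.38,-1.35,0.02,-0.91
Veraguamide F,-0.64,-1.78,-1.55,-1.43,-0.09,-1.09
Veraguamide G,-0.35,-1.32,-1.12,-1.04,0.13,-0.72
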