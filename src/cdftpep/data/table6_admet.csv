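# ADMET boolean matrix of the Veraguamides A-G from external predictors
# (ingestion-only input). Tokens: + (positive prediction) / - (negative).
property,Veraguamide A,Veraguamide B,Veraguamide C,Veraguamide D,Veraguamide E,Veraguamide F,Veraguamide G
HI Absorption,+,+,+,+,+,+,+
BBB Permeability,+,+,+,+,+,+,+
Caco-2,-,-,-,-,-,-,-
P-gp Substrate,+,+,+,+,+,+,+
P-gp Inhibitor,+,+,+,+,+,+,+
CYP2C9 Substrate,-,-,-,-,-,+,-
CYP2D6 Substrate,-,-,-,-,-,-,-
CYP3A4 Substrate,+,+,+,+,+,+,+
CYP1A2 Inhibitor,-,-,-,-,-,-,-
CYP2C19 Inhibitor,-,-,-,-,-,-,-
CYP2C9 Inhibitor,-,-,-,-,-,-,-
CYP2D6 Inhibitor,-,-,-,-,-,-,-
CYP3A4 Inhibitor,-,-,-,-,-,-,-
OCT2 Substrate,-,-,-,-,-,-,-
AMES Toxicity,-,-,-,-,-,-,-
hERG Inhibitor,-,-,-,-,-,-,-
Hepatotoxicity,+,+,+,+,+,+,+
Skin Sensitization,-,-,-,-,-,-,-
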