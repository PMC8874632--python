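solvent_name,inv_dielectric,functional,mean_gkd,n_molecules
NMF,0.0055,LC-BLYP,4.17,7
NMF,0.0055,LC-PBE,4.16,7
NMF,0.0055,MN12SX,0.02,7
NMF,0.0055,CAM-B3LYP,2.15,7
NMF,0.0055,LC-wHPBE,3.88,7
Formamide,0.0092,LC-BLYP,4.18,7
Formamide,0.0092,LC-PBE,4.17,7
Formamide,0.0092,MN12SX,0.02,7
Formamide,0.0092,CAM-B3LYP,2.16,7
Formamide,0.0092,LC-wHPBE,3.89,7
H2O,0.0128,LC-BLYP,4.16,7
H2O,0.0128,LC-PBE,4.16,7
H2O,0.0128,MN12SX,0.01,7
H2O,0.0128,CAM-B3LYP,2.15,7
H2O,0.0128,LC-wHPBE,3.87,7
Methanol,0.0307,LC-BLYP,4.09,7
Methanol,0.0307,LC-PBE,4.08,7
Methanol,0.0307,MN12SX,0.05,7
Methanol,0.0307,CAM-B3LYP,2.08,7
Methanol,0.0307,LC-wHPBE,3.80,7
Ethanol,0.0402,LC-BLYP,4.00,7
Ethanol,0.0402,LC-PBE,3.99,7
Ethanol,0.0402,MN12SX,0.11,7
Ethanol,0.0402,CAM-B3LYP,2.00,7
Ethanol,0.0402,LC-wHPBE,3.81,7
Acetone,0.0488,LC-BLYP,3.73,7
Acetone,0.0488,LC-PBE,3.72,7
Acetone,0.0488,MN12SX,0.27,7
Acetone,0.0488,CAM-B3LYP,1.77,7
Acetone,0.0488,LC-wHPBE,3.45,7
DCE,0.0988,LC-BLYP,3.62,7
DCE,0.0988,LC-PBE,3.61,7
DCE,0.0988,MN12SX,0.37,7
DCE,0.0988,CAM-B3LYP,1.65,7
DCE,0.0988,LC-wHPBE,3.33,7
THF,0.1347,LC-BLYP,3.45,7
THF,0.1347,LC-PBE,3.44,7
THF,0.1347,MN12SX,0.48,7
THF,0.1347,CAM-B3LYP,1.50,7
THF,0.1347,LC-wHPBE,3.16,7
DBE,0.3282,LC-BLYP,2.95,7
DBE,0.3282,LC-PBE,2.94,7
DBE,0.3282,MN12SX,0.85,7
DBE,0.3282,CAM-B3LYP,1.03,7
DBE,0.3282,LC-wHPBE,2.67,7
Cyclohexane,0.4959,LC-BLYP,2.56,7
Cyclohexane,0.4959,LC-PBE,2.55,7
Cyclohexane,0.4959,MN12SX,1.14,7
Cyclohexane,0.4959,CAM-B3LYP,0.66,7
Cyclohexane,0.4959,LC-wHPBE,2.29,7
n-Hexane,0.5314,LC-BLYP,2.48,7
n-Hexane,0.5314,LC-PBE,2.47,7
n-Hexane,0.5314,MN12SX,2.03,7
n-Hexane,0.5314,CAM-B3LYP,0.58,7
n-Hexane,0.5314,LC-wHPBE,2.21,7
Gas,1.0000,LC-BLYP,1.36,7
Gas,1.0000,LC-PBE,1.35,7
Gas,1.0000,MN12SX,2.08,7
Gas,1.0000,CAM-B3LYP,0.48,7
Gas,1.0000,LC-wHPBE,1.09,7
NMF,0.0055,wB97XD,2.91,7
NMF,0.0055,M11,3.54,7
NMF,0.0055,RSX-PBE,4.06,7
NMF,0.0055,RSX-PBE0,4.24,7
NMF,0.0055,RSX-PBE0-1/3,4.32,7
Formamide,0.0092,wB97XD,2.92,7
Formamide,0.0092,M11,3.55,7
Formamide,0.0092,RSX-PBE,4.08,7
Formamide,0.0092,RSX-PBE0,4.25,7
Formamide,0.0092,RSX-PBE0-1/3,4.33,7
H2O,0.0128,wB97XD,2.90,7
H2O,0.0128,M11,3.53,7
H2O,0.0128,RSX-PBE,4.06,7
H2O,0.0128,RSX-PBE0,4.23,7
H2O,0.0128,RSX-PBE0-1/3,4.32,7
Methanol,0.0307,wB97XD,2.84,7
Methanol,0.0307,M11,3.46,7
Methanol,0.0307,RSX-PBE,3.99,7
Methanol,0.0307,RSX-PBE0,4.16,7
Methanol,0.0307,RSX-PBE0-1/3,4.24,7
Ethanol,0.0402,wB97XD,2.76,7
Ethanol,0.0402,M11,3.38,7
Ethanol,0.0402,RSX-PBE,3.38,7
Ethanol,0.0402,RSX-PBE0,4.07,7
Ethanol,0.0402,RSX-PBE0-1/3,4.16,7
Acetone,0.0488,wB97XD,2.53,7
Acetone,0.0488,M11,3.12,7
Acetone,0.0488,RSX-PBE,3.01,7
Acetone,0.0488,RSX-PBE0,3.80,7
Acetone,0.0488,RSX-PBE0-1/3,3.88,7
DCE,0.0988,wB97XD,2.42,7
DCE,0.0988,M11,3.01,7
DCE,0.0988,RSX-PBE,2.89,7
DCE,0.0988,RSX-PBE0,3.68,7
DCE,0.0988,RSX-PBE0-1/3,3.77,7
THF,0.1347,wB97XD,2.26,7
THF,0.1347,M11,2.84,7
THF,0.1347,RSX-PBE,2.72,7
THF,0.1347,RSX-PBE0,3.51,7
THF,0.1347,RSX-PBE0-1/3,3.59,7
DBE,0.3282,wB97XD,1.80,7
DBE,0.3282,M11,2.36,7
DBE,0.3282,RSX-PBE,2.60,7
DBE,0.3282,RSX-PBE0,3.02,7
DBE,0.3282,RSX-PBE0-1/3,3.10,7
Cyclohexane,0.4959,wB97XD,1.43,7
Cyclohexane,0.4959,M11,1.98,7
Cyclohexane,0.4959,RSX-PBE,2.47,7
Cyclohexane,0.4959,RSX-PBE0,2.63,7
Cyclohexane,0.4959,RSX-PBE0-1/3,2.71,7
n-Hexane,0.5314,wB97XD,1.35,7
n-Hexane,0.5314,M11,1.90,7
n-Hexane,0.5314,RSX-PBE,2.39,7
n-Hexane,0.5314,RSX-PBE0,2.55,7
n-Hexane,0.5314,RSX-PBE0-1/3,2.63,7
Gas,1.0000,wB97XD,0.28,7
Gas,1.0000,M11,0.79,7
Gas,1.0000,RSX-PBE,1.26,7
Gas,1.0000,RSX-PBE0,1.42,7
Gas,1.0000,RSX-PBE0-1/3,1.50,7
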