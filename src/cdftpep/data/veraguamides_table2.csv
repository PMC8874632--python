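# Veraguamides A-G energetics at MN12SX/Def2TZVP with SMD water.
# One row per species: neutral (charge 0), vertical radical cation (+1,
# doublet) and vertical radical anion (-1, doublet). Orbital energies are
# the published frontier eigenvalues; ground-state total energies were not
# published and are stored as zero placeholders, so Koopmans-deviation
# indices must NOT be recomputed from the total-energy columns of this
# file (use table2_kid_reference.csv for the published indices).
molecule_id,functional,solvent_name,solvent_dielectric,charge,multiplicity,total_energy,energy_unit,homo,lumo,somo
Veraguamide A,MN12SX,water,78.355,0,1,0.0,eV,-6.635,-0.884,
Veraguamide A,MN12SX,water,78.355,1,2,0.0,eV,,,
Veraguamide A,MN12SX,water,78.355,-1,2,0.0,eV,,,-0.892
Veraguamide B,MN12SX,water,78.355,0,1,0.0,eV,-6.637,-0.942,
Veraguamide B,MN12SX,water,78.355,1,2,0.0,eV,,,
Veraguamide B,MN12SX,water,78.355,-1,2,0.0,eV,,,-0.912
Veraguamide C,MN12SX,water,78.355,0,1,0.0,eV,-6.812,-0.993,
Veraguamide C,MN12SX,water,78.355,1,2,0.0,eV,,,
Veraguamide C,MN12SX,water,78.355,-1,2,0.0,eV,,,-0.946
Veraguamide D,MN12SX,water,78.355,0,1,0.0,eV,-6.661,-0.748,
Veraguamide D,MN12SX,water,78.355,1,2,0.0,eV,,,
Veraguamide D,MN12SX,water,78.355,-1,2,0.0,eV,,,-0.759
Veraguamide E,MN12SX,water,78.355,0,1,0.0,eV,-6.873,-0.717,
Veraguamide E,MN12SX,water,78.355,1,2,0.0,eV,,,
Veraguamide E,MN12SX,water,78.355,-1,2,0.0,eV,,,-0.702
Veraguamide F,MN12SX,water,78.355,0,1,0.0,eV,-6.717,-1.016,
Veraguamide F,MN12SX,water,78.355,1,2,0.0,eV,,,
Veraguamide F,MN12SX,water,78.355,-1,2,0.0,eV,,,-0.972
Veraguamide G,MN12SX,water,78.355,0,1,0.0,eV,-6.697,-0.771,
Veraguamide G,MN12SX,water,78.355,1,2,0.0,eV,,,
Veraguamide G,MN12SX,water,78.355,-1,2,0.0,eV,,,-0.768
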