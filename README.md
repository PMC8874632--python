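# cdftpep

Conceptual-DFT computational peptidology: a post-processing toolkit that
turns per-species quantum-chemistry energetics into chemical-reactivity
descriptors, validates the density functional behind them, and assembles
pharmacology reports. It is aimed at computational chemists screening
peptide natural products (the bundled case study is the Veraguamides A–G,
cyclic hexadepsipeptides from marine cyanobacteria) who already have
electronic-structure results and want the descriptor, validation and
reporting layers without touching a quantum-chemistry code again.

## What it computes

**Global reactivity descriptors** from the neutral species' frontier
orbital energies ϵH, ϵL (eV):

- electronegativity χ = −(ϵH + ϵL)/2, hardness η = ϵL − ϵH, softness
  S = 1/η, electrophilicity ω = χ²/(2η)
- electrodonating / electroaccepting powers ω⁻ = (3ϵH+ϵL)²/16η,
  ω⁺ = (ϵH+3ϵL)²/16η, net electrophilicity Δω± = ω⁻ + ω⁺
- nucleophilicity N = ϵH − ϵH(TCE), referenced to tetracyanoethylene
- band classification on the empirical scales (electrophiles:
  strong > 1.5 eV > moderate ≥ 0.8 eV > marginal; nucleophiles:
  strong > 3.0 eV > moderate > 2.0 eV ≥ marginal)

**Koopmans-compliance (KID) validation.** Exact DFT ties ϵH to −I and ϵL
to −A of the vertical N±1 species. Per molecule the deviations
J(I) = |ϵH + Egs(N−1) − Egs(N)|, J(A) = |ϵL + Egs(N) − Egs(N+1)|,
J(HL) = √(J(I)²+J(A)²) and ΔSL = |ϵSOMO(anion) − ϵL| are combined into the
global KID descriptor GKD = √(J(I)²+J(A)²+J(HL)²+ΔSL²), zero for an
exactly compliant functional. Averaging GKD per (functional, solvent) cell
ranks functionals for a given medium.

**Local reactivity** on density grids (Gaussian cube files): nucleophilic
and electrophilic Fukui functions NFF = ρN+1 − ρN, EFF = ρN − ρN−1, and the
dual descriptor DD = NFF − EFF (DD > 0 marks nucleophilic-attack sites),
plus condensed per-atom variants from partial atomic charges.

**Pharmacology layer**: the hardness QSAR pKa = 16.3088 − 0.8268η,
bioactivity-score banding (active / moderately active / inactive at 0 and
−5), and ADMET boolean-matrix validation and consensus summaries.

A seeded synthetic-data module generates Koopmans-deviation energetics
with known noise scale and analytic Gaussian density triads, so every
stage is testable without any electronic-structure calculation.

## Worked example

```bash
cdftpep compute-global --energetics src/cdftpep/data/veraguamides_table2.csv
```

prints (first rows):

```
molecule_id,chi,eta,omega,softness,nu,omega_minus,omega_plus,net_electrophilicity
Veraguamide A,3.760,5.751,1.229,0.174,2.158,4.697,0.937,5.634
Veraguamide B,3.790,5.695,1.261,0.176,2.156,4.772,0.983,5.755
Veraguamide C,3.903,5.819,1.309,0.172,1.981,4.932,1.030,5.962
```

Reading row A: χ = 3.760 eV and η = 5.751 eV place the molecule among the
harder (less reactive) peptides of its size class; ω = 1.229 eV is in the
moderate-electrophile band, and N = 2.158 eV makes it a moderate
nucleophile. Veraguamide C's N = 1.981 eV drops it to the marginal
nucleophile band — with Veraguamide E it is one of the only two family
members there. The same numbers are available programmatically:

```python
from cdftpep.datasets import load_veraguamide_energetics
from cdftpep import global_descriptor_set

triads = load_veraguamide_energetics()
g = global_descriptor_set(triads[0])
print(g.molecule_id, round(g.omega, 3))   # Veraguamide A 1.229
```

Other subcommands: `validate-kid`, `benchmark-functionals`,
`local-descriptors` (three cube files → NFF/EFF/DD cubes),
`pharma-report`, `run-all`, `make-synthetic`.

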