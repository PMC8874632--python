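# Methods

## Scope and model

cdftpep is a post-processing layer. It assumes that, for each molecule,
somebody has already computed — at a single model chemistry (density
functional, basis set, solvation model) — the ground-state total energies
of the neutral (N electrons), the vertical radical cation (N−1, doublet)
and the vertical radical anion (N+1, doublet), plus the neutral's HOMO and
LUMO eigenvalues and the anion's SOMO. Everything downstream is closed-form
arithmetic on those numbers, or voxel arithmetic on the corresponding
electron densities. Nothing here runs an electronic-structure code, and no
descriptor depends on molecular geometry or wavefunction files.

All energies are converted to eV at ingest (1 hartree = 27.211386 eV,
1 kcal/mol = 0.0433641 eV, fixed constants so outputs are bit-stable) and
eV is the only internal unit; every descriptor of interest is
conventionally quoted in eV, so conversion happens exactly once.

## Global descriptors: conventions chosen

The frozen-orbital (Koopmans-like) forms are used throughout; the
finite-difference variants built from I = E(N−1)−E(N) and A = E(N)−E(N+1)
are deliberately not offered, because for a Koopmans-compliant functional
the two coincide and the orbital forms are what published descriptor
tables print.

Conventions where the literature is genuinely inconsistent:

- **Sign of χ.** The chemical potential μ = (ϵH+ϵL)/2 is negative for
  stable molecules; published tables print the positive electronegativity.
  We report χ = −μ and expose μ = −χ separately.
- **Hardness.** η = ϵL − ϵH, the full gap, with no ½ factor. This is the
  definition consistent with published gap columns equalling published η
  columns. Softness is S = 1/η, not 1/(2η).
- **Electrophilicity.** ω = χ²/(2η) (the Parr index). Some sources print
  the formula with a 4η denominator while their tabulated values follow
  χ²/(2η); both forms are implemented, the 2η one is the default and the
  4η variant requires an explicit `four_eta=True` so it can never be
  selected silently.
- **Nucleophilicity origin.** N = ϵH − ϵH(TCE). The default TCE reference
  is −8.793 eV, a constant *back-computed* from published MN12SX/Def2TZVP
  water-phase tables (the seven ϵH − N residuals agree to ±0.001 eV). It
  is model-chemistry-dependent and must be overridden when working at a
  different functional, basis or solvent (`ReactivityConfig` /
  `--tce-reference`).
- **Band boundaries.** The published scale prose leaves the boundary
  points ambiguous. We assign ω exactly 0.8 or 1.5 eV to the moderate
  band, N exactly 2.0 eV to marginal and exactly 3.0 eV to moderate —
  ties resolve toward the middle band.
- **Report rounding.** 3 decimals (descriptors, KID), 2 decimals (pKa,
  benchmark means), rounding half away from zero, as printed tables do.
  Python's built-in banker's rounding is not used for report output.

## KID validation

J(I), J(A) and ΔSL are stored as absolute deviations: the defining
expressions are signed, but only magnitudes are meaningful as compliance
measures, and published tables print non-negative values. ΔSL compares the
anion's SOMO against the neutral's LUMO; a small ΔSL indicates a
negligible derivative discontinuity, i.e. the LUMO eigenvalue genuinely
tracks the electron affinity.

GKD = √(J(I)²+J(A)²+J(HL)²+ΔSL²) is implemented exactly as defined even
though J(HL)² = J(I)²+J(A)² makes it algebraically redundant
(GKD² = 2·J(HL)²+ΔSL²). The non-redundant √(J(I)²+J(A)²+ΔSL²) is exposed
under the distinct name `gkd_nonredundant` and is never substituted.

Benchmark aggregation is the unweighted arithmetic mean of per-molecule
GKD per (functional, solvent) cell; ranking is ascending mean GKD with
alphabetical tie-breaking for determinism.

Known data caveats in the bundled reference tables: for Veraguamides A
and F the published ΔSL disagrees with |SOMO−LUMO| recomputed from the
published orbital columns (0.003 vs 0.008 and 0.019 vs 0.044); the
implementation always computes from orbital energies and the consistency
tests exclude those two rows. The published benchmark matrix is shipped as
a fixture for the aggregation/ranking interface — recomputing its ten
functionals from scratch would require running the underlying DFT and is
out of scope. The bundled energetics fixture stores total energies as zero
placeholders (the source prints KID indices, not total energies); the
pipeline detects the resulting non-positive finite-difference ionization
energy, suppresses J(I)/J(A)/GKD for such rows and logs a data-quality
flag, so placeholder totals can never masquerade as real deviations.

## Local descriptors

Fukui functions are density differences on grids (NFF = ρN+1−ρN,
EFF = ρN−ρN−1) and the dual descriptor is DD = NFF − EFF, the two-parabola
finite-difference realisation of ∂f(r)/∂N. Integrals use rectangle-rule
quadrature (voxel sum × |det(axes)|), the standard for cube-file
post-processing; no higher-order scheme is attempted because cube data is
already a box-average discretisation. Grid arithmetic demands exact
geometric agreement (1e−6 Bohr on origin and axes, identical shapes);
mismatched grids raise rather than resample, since silent interpolation
would corrupt the integrals the descriptors are judged by.

Cube I/O follows the Gaussian convention: lengths in Bohr, z-fastest
ordering, positive axis counts. The orbital-cube dialect (negative atom
count) and the Angstrom flag are rejected. Data values are written at six
significant figures; header geometry is written at full double precision
so metadata round-trips exactly.

Condensed Fukui functions use the charge-difference convention
f⁺ = q(N)−q(N+1), f⁻ = q(N−1)−q(N) on externally supplied partial charges
(Hirshfeld-type charges are the recommended input); the signs make f⁺ and
f⁻ positive at accepting/donating sites and each sums to ≈ 1 e. Charge
triads whose totals do not step by 1 e (±0.05 e) are rejected as
inconsistently partitioned.

## Pharmacology layer

pKa = 16.3088 − 0.8268·η is an externally calibrated one-descriptor QSAR
(calibrated on amino acids and small peptides); this package only
evaluates it. Note the bundled published pKa table for the Veraguamides is
*not* reproducible from this formula with the bundled hardness values
(formula gives ≈11.2–11.6 with the opposite hardness ordering); the
fixture documents this and nothing asserts agreement.

Bioactivity banding uses cutoffs 0 and −5 with both boundaries assigned to
the middle (moderately-active) band. ADMET handling is ingestion-only:
predictions from external tools are validated against a fixed 18-property
vocabulary and summarised per property as uniformly positive, uniformly
negative or mixed — the three categories partition the vocabulary.

## Synthetic data: what it emulates, what it does not

The energetics emulator draws I ~ U(5, 8) eV and A ~ U(0, 2) eV (typical
of closed-shell organics in solution), fixes Egs(N) = 0, Egs(N−1) = I,
Egs(N+1) = −A (only differences enter any formula), and sets
ϵH = −I + δ₁, ϵL = −A + δ₂, ϵSOMO = ϵL + δ₃ with independent
δ ~ Normal(0, σ). Consequences used as test oracles: σ = 0 gives exactly
compliant triads (all indices 0); for σ > 0, J(I) and J(A) are half-normal
with mean σ√(2/π); mean GKD is monotone in σ. The density generator builds
each species as a weighted sum of isotropic normalized Gaussians scaled to
its electron count, so all integrals are analytic; the grid must cover ±5σ
of every center (≥ 99.9999% of each Gaussian's mass) or generation fails.

What the emulator deliberately does not model: correlated deviations
between ϵH and ϵL (real functionals err systematically, not
independently), any solvent dependence of σ (solvents are labels in the
synthetic suite), cusped or anisotropic real densities, and basis-set
effects. Passing the synthetic suites therefore demonstrates that the
arithmetic, aggregation and ranking machinery is correct — not that any
particular functional is accurate for real peptides; that judgement comes
from the KID indices on real energetics.

Randomness: one `numpy` generator per spec, seeded from the spec; the
benchmark suite derives per-cell seeds from a `SeedSequence`, so identical
specs and seeds are bitwise reproducible and no global state is touched.

## Problem sizes and numerics

Default test problem sizes: 1000 molecules for the exact-compliance
property, 200 molecules per σ level for the noise-recovery checks (3
standard-error tolerance), 64³ grids for the Fukui normalization checks
(48³ in unit tests), tolerances 0.01 e on Fukui integrals and 0.02 e on
the dual-descriptor integral. Reference-table reproduction is checked at
0.005 eV elementwise — the inputs are printed at 3 decimals, so half-ulp
propagation through the descriptor formulas bounds the achievable
agreement; KID internal-consistency checks use 0.0015 eV for the same
reason.

## Limitations

- The frozen-orbital descriptor forms inherit whatever Koopmans
  non-compliance the underlying functional has; the KID layer quantifies
  but cannot repair it.
- The TCE nucleophilicity reference is a derived constant; absolute N
  values across different model chemistries are not comparable unless the
  reference is recomputed.
- Condensed Fukui functions are only as good as the supplied charge
  partitioning; no partitioning is performed in-package.
- The pKa QSAR is a linear calibration for peptide-like molecules near
  physiological conditions; extrapolating it far outside η ≈ 4–7 eV is
  meaningless (its formal root at η ≈ 19.7 eV has no chemical content).
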