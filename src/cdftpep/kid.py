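"""Koopmans-compliance (KID) validation of density functionals.

In exact generalized Kohn–Sham DFT the ionization-energy theorem ties the
frontier eigenvalues of the neutral to total-energy differences of the
vertical N±1 species: ϵH = −I = Egs(N) − Egs(N−1) and, for the LUMO via the
anion, ϵL = −A = Egs(N+1) − Egs(N).  An approximate functional deviates;
the deviations are summarised per molecule by four non-negative indices
(all eV):

    J(I)  = |ϵH + Egs(N−1) − Egs(N)|
    J(A)  = |ϵL + Egs(N) − Egs(N+1)|
    J(HL) = sqrt(J(I)² + J(A)²)
    ΔSL   = |ϵSOMO(anion) − ϵL(neutral)|   (derivative-discontinuity probe)

and aggregated into the global KID descriptor

    GKD = sqrt(J(I)² + J(A)² + J(HL)² + ΔSL²),

which is zero for a functional exactly satisfying the theorem.  Note that
GKD deliberately keeps the J(HL) term even though J(HL)² = J(I)² + J(A)²
(so GKD² = 2·J(HL)² + ΔSL²); the non-redundant alternative is exposed as
:func:`gkd_nonredundant` and never silently substituted.

Averaging GKD over a family of molecules per (functional, solvent) cell
gives a benchmark matrix from which functionals are ranked — smallest mean
GKD first — for a given solvent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .energetics import MoleculeEnergetics, SolventSpec
from .errors import MissingDataError, MissingSpeciesError

__all__ = [
    "KIDDescriptorSet",
    "BenchmarkCell",
    "j_ionization",
    "j_affinity",
    "j_hl",
    "delta_sl",
    "gkd",
    "gkd_nonredundant",
    "kid_descriptor_set",
    "aggregate_benchmark",
    "rank_functionals",
]


@dataclass
class KIDDescriptorSet:
    """Per-molecule Koopmans-deviation indices (eV, all ≥ 0)."""

    molecule_id: str
    j_i: float
    j_a: float
    j_hl: float
    delta_sl: float
    gkd: float


@dataclass
class BenchmarkCell:
    """Mean GKD of a molecule family for one (functional, solvent) cell."""

    functional: str
    solvent: SolventSpec
    mean_gkd: float
    n_molecules: int


def j_ionization(triad: MoleculeEnergetics) -> float:
    """J(I) = |ϵH + Egs(N−1) − Egs(N)|."""
    if triad.cation is None:
        raise MissingSpeciesError(
            f"{triad.molecule_id}: cation species required for J(I)")
    if triad.neutral is None or triad.neutral.homo is None:
        raise MissingDataError(
            f"{triad.molecule_id}: neutral HOMO required for J(I)")
    return abs(triad.neutral.homo + triad.cation.total_energy
               - triad.neutral.total_energy)


def j_affinity(triad: MoleculeEnergetics) -> float:
    """J(A) = |ϵL + Egs(N) − Egs(N+1)|."""
    if triad.anion is None:
        raise MissingSpeciesError(
            f"{triad.molecule_id}: anion species required for J(A)")
    if triad.neutral is None or triad.neutral.lumo is None:
        raise MissingDataError(
            f"{triad.molecule_id}: neutral LUMO required for J(A)")
    return abs(triad.neutral.lumo + triad.neutral.total_energy
               - triad.anion.total_energy)


def j_hl(j_i: float, j_a: float) -> float:
    """J(HL) = sqrt(J(I)² + J(A)²)."""
    return math.hypot(j_i, j_a)


def delta_sl(triad: MoleculeEnergetics) -> float:
    """ΔSL = |ϵSOMO(anion) − ϵL(neutral)|.

    The SOMO is the anion's highest occupied orbital; ΔSL near zero means
    the LUMO eigenvalue tracks the electron affinity, i.e. the functional's
    derivative discontinuity is negligible.
    """
    if triad.anion is None or triad.anion.somo is None:
        raise MissingDataError(
            f"{triad.molecule_id}: anion SOMO required for ΔSL")
    if triad.neutral is None or triad.neutral.lumo is None:
        raise MissingDataError(
            f"{triad.molecule_id}: neutral LUMO required for ΔSL")
    return abs(triad.anion.somo - triad.neutral.lumo)


def gkd(j_i: float, j_a: float, j_hl_value: float,
        delta_sl_value: float) -> float:
    """GKD = sqrt(J(I)² + J(A)² + J(HL)² + ΔSL²)."""
    return math.sqrt(j_i ** 2 + j_a ** 2 + j_hl_value ** 2
                     + delta_sl_value ** 2)


def gkd_nonredundant(j_i: float, j_a: float, delta_sl_value: float) -> float:
    """sqrt(J(I)² + J(A)² + ΔSL²) — the variant without the J(HL) term."""
    return math.sqrt(j_i ** 2 + j_a ** 2 + delta_sl_value ** 2)


def kid_descriptor_set(triad: MoleculeEnergetics) -> KIDDescriptorSet:
    """Compute all KID indices for a complete triad."""
    ji = j_ionization(triad)
    ja = j_affinity(triad)
    jhl = j_hl(ji, ja)
    dsl = delta_sl(triad)
    return KIDDescriptorSet(triad.molecule_id, ji, ja, jhl, dsl,
                            gkd(ji, ja, jhl, dsl))


def aggregate_benchmark(
    records: Iterable[tuple[str, SolventSpec, KIDDescriptorSet]],
) -> list[BenchmarkCell]:
    """Average per-molecule GKD into (functional, solvent) benchmark cells.

    The mean is unweighted and arithmetic.  Output is sorted by functional
    name, then by descending solvent dielectric (most polar first).
    """
    cells: dict[tuple[str, SolventSpec], list[float]] = {}
    for functional, solvent, kid in records:
        cells.setdefault((functional, solvent), []).append(kid.gkd)
    out = [
        BenchmarkCell(functional, solvent,
                      sum(vals) / len(vals), len(vals))
        for (functional, solvent), vals in cells.items()
    ]
    out.sort(key=lambda c: (c.functional, -c.solvent.dielectric))
    return out


def rank_functionals(cells: Sequence[BenchmarkCell],
                     solvent_name: str) -> list[str]:
    """Rank functionals by ascending mean GKD for one solvent.

    Ties break alphabetically for determinism.  Raises ``KeyError`` if the
    solvent does not occur in the cells.
    """
    matching = [c for c in cells if c.solvent.name == solvent_name]
    if not matching:
        known = sorted({c.solvent.name for c in cells})
        raise KeyError(f"solvent {solvent_name!r} not present; "
                       f"known solvents: {known}")
    matching.sort(key=lambda c: (c.mean_gkd, c.functional))
    return [c.functional for c in matching]
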