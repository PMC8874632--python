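"""Grid-based and condensed local reactivity descriptors.

Fukui functions resolve *where* in a molecule reactivity concentrates, via
finite differences of the electron density over electron number:

    NFF(r) = ρ_{N+1}(r) − ρ_N(r)   (sites prone to nucleophilic attack)
    EFF(r) = ρ_N(r) − ρ_{N−1}(r)   (sites prone to electrophilic attack)
    DD(r)  = NFF(r) − EFF(r)       (dual descriptor; > 0 nucleophilic,
                                    < 0 electrophilic)

Each Fukui function integrates to one electron; DD integrates to zero.
Grid arithmetic requires the three cubes to share origin, axes and shape
exactly (1e−6 Bohr tolerance); no resampling is attempted between
mismatched grids.  Integrals use rectangle-rule quadrature (voxel sum ×
voxel volume), the standard for cube-file post-processing.

Condensed (per-atom) variants use the charge-difference convention on
partial atomic charges q_k of the three species:

    f⁺_k = q_k(N) − q_k(N+1),  f⁻_k = q_k(N−1) − q_k(N),
    dd_k = f⁺_k − f⁻_k,

signed so f⁺, f⁻ are positive at electron-accepting/-donating sites and
each sums to ≈ 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cube import DensityGrid
from .errors import GridMismatchError, SchemaError

__all__ = [
    "GridTriad",
    "CondensedChargesTriad",
    "GridCompatReport",
    "check_grid_compat",
    "integrate_grid",
    "nucleophilic_fukui",
    "electrophilic_fukui",
    "dual_descriptor",
    "condensed_fukui",
]

#: Geometric agreement tolerance for grid arithmetic, in Bohr.
GRID_TOL_BOHR = 1e-6


@dataclass
class GridTriad:
    """Densities of the N−1, N and N+1 electron species on one grid."""

    rho_nminus: DensityGrid
    rho_n: DensityGrid
    rho_nplus: DensityGrid

    def validate(self) -> None:
        for name, other in (("rho_nminus", self.rho_nminus),
                            ("rho_nplus", self.rho_nplus)):
            report = check_grid_compat(self.rho_n, other)
            if not report.ok:
                raise GridMismatchError(
                    f"{name} incompatible with rho_n: "
                    + "; ".join(report.problems))


@dataclass
class CondensedChargesTriad:
    """Per-atom partial charges (e) of the three species.

    Successive species should differ by about one elementary charge in
    total (the added/removed electron); a drift beyond 0.05 e indicates
    inconsistent charge partitioning and is rejected.
    """

    atom_labels: Sequence[str]
    q_nminus: Sequence[float]
    q_n: Sequence[float]
    q_nplus: Sequence[float]

    def validate(self, charge_tol: float = 0.05) -> None:
        n = len(self.atom_labels)
        for name in ("q_nminus", "q_n", "q_nplus"):
            if len(getattr(self, name)) != n:
                raise SchemaError(
                    f"{name} has {len(getattr(self, name))} entries for "
                    f"{n} atoms")
        for a, b, lbl in ((self.q_nminus, self.q_n, "N−1 → N"),
                          (self.q_n, self.q_nplus, "N → N+1")):
            drift = (sum(a) - sum(b)) - 1.0
            if abs(drift) > charge_tol:
                raise SchemaError(
                    f"charge sums across {lbl} differ from 1 e by "
                    f"{drift:+.3f} e (tolerance {charge_tol})")


@dataclass
class GridCompatReport:
    ok: bool
    problems: list[str] = field(default_factory=list)


def check_grid_compat(a: DensityGrid, b: DensityGrid) -> GridCompatReport:
    """Diagnose whether two grids can enter voxelwise arithmetic."""
    problems: list[str] = []
    if a.shape != b.shape:
        dims = [i for i in range(3) if a.shape[i] != b.shape[i]]
        problems.append(f"shape mismatch in dimension(s) {dims}: "
                        f"{a.shape} vs {b.shape}")
    dorigin = float(np.max(np.abs(a.origin - b.origin)))
    if dorigin > GRID_TOL_BOHR:
        problems.append(f"origin deviation up to {dorigin:.3e} Bohr "
                        f"(tolerance {GRID_TOL_BOHR:.0e})")
    daxes = float(np.max(np.abs(a.axes - b.axes)))
    if daxes > GRID_TOL_BOHR:
        problems.append(f"axes deviation up to {daxes:.3e} Bohr "
                        f"(tolerance {GRID_TOL_BOHR:.0e})")
    return GridCompatReport(ok=not problems, problems=problems)


def integrate_grid(grid: DensityGrid) -> float:
    """Rectangle-rule integral of the grid (sum × voxel volume)."""
    return grid.integral()


def _difference(minuend: DensityGrid, subtrahend: DensityGrid) -> DensityGrid:
    report = check_grid_compat(minuend, subtrahend)
    if not report.ok:
        raise GridMismatchError("; ".join(report.problems))
    return DensityGrid(origin=minuend.origin.copy(),
                       axes=minuend.axes.copy(),
                       values=minuend.values - subtrahend.values,
                       atoms=list(minuend.atoms))


def nucleophilic_fukui(triad: GridTriad) -> DensityGrid:
    """NFF = ρ_{N+1} − ρ_N; integrates to ≈ 1 electron."""
    triad.validate()
    return _difference(triad.rho_nplus, triad.rho_n)


def electrophilic_fukui(triad: GridTriad) -> DensityGrid:
    """EFF = ρ_N − ρ_{N−1}; integrates to ≈ 1 electron."""
    triad.validate()
    return _difference(triad.rho_n, triad.rho_nminus)


def dual_descriptor(nff: DensityGrid, eff: DensityGrid) -> DensityGrid:
    """DD = NFF − EFF; integrates to ≈ 0.

    Positive voxels mark sites favoured for nucleophilic attack, negative
    voxels sites favoured for electrophilic attack.
    """
    return _difference(nff, eff)


def condensed_fukui(charges: CondensedChargesTriad) -> pd.DataFrame:
    """Per-atom Fukui functions and dual descriptor from partial charges.

    Returns a DataFrame indexed by atom label with columns ``f_plus``,
    ``f_minus`` and ``dual``.
    """
    charges.validate()
    qm = np.asarray(charges.q_nminus, dtype=float)
    q0 = np.asarray(charges.q_n, dtype=float)
    qp = np.asarray(charges.q_nplus, dtype=float)
    f_plus = q0 - qp
    f_minus = qm - q0
    return pd.DataFrame(
        {"f_plus": f_plus, "f_minus": f_minus, "dual": f_plus - f_minus},
        index=pd.Index(list(charges.atom_labels), name="atom"),
    )
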