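"""Global chemical-reactivity descriptors from frontier orbital energies.

Within conceptual DFT, chemical reactivity is summarised by derivatives of
the energy with respect to electron number.  In the frozen-orbital
approximation these reduce to closed forms in the neutral species' HOMO and
LUMO energies ϵH, ϵL (all in eV):

    electronegativity      χ  = −(ϵH + ϵL)/2      (= −μ, reported positive)
    global hardness        η  = ϵL − ϵH           (the full H–L gap)
    global softness        S  = 1/η
    electrophilicity       ω  = χ²/(2η)
    electrodonating power  ω⁻ = (3ϵH + ϵL)²/(16η)
    electroaccepting power ω⁺ = (ϵH + 3ϵL)²/(16η)
    net electrophilicity   Δω± = ω⁻ + ω⁺

The nucleophilicity index N is the HOMO energy relative to that of
tetracyanoethylene (TCE), the conventional origin of the nucleophilicity
scale: N = ϵH(molecule) − ϵH(TCE).  Molecules are binned on the empirical
electrophilicity scale (strong > 1.5 eV > moderate ≥ 0.8 eV > marginal) and
nucleophilicity scale (strong > 3.0 eV > moderate > 2.0 eV ≥ marginal).

Two identities follow algebraically and are enforced by the test suite:
ω⁻ − ω⁺ = χ and S·η = 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .energetics import MoleculeEnergetics
from .errors import MissingDataError, UndefinedValueError

__all__ = [
    "ReactivityConfig",
    "GlobalDescriptorSet",
    "electronegativity",
    "chemical_potential",
    "hardness",
    "softness",
    "electrophilicity",
    "charge_transfer_powers",
    "nucleophilicity",
    "classify_electrophile",
    "classify_nucleophile",
    "global_descriptor_set",
]

#: HOMO energy of tetracyanoethylene used as the nucleophilicity origin.
#: Back-computed from published descriptor tables at MN12SX/Def2TZVP in
#: water; model-chemistry-dependent, so override per functional/solvent.
DEFAULT_TCE_HOMO_EV = -8.793


@dataclass(frozen=True)
class ReactivityConfig:
    """Scale cutoffs and the TCE nucleophilicity reference (all eV)."""

    tce_homo_reference: float = DEFAULT_TCE_HOMO_EV
    electrophile_strong_cutoff: float = 1.5
    electrophile_marginal_cutoff: float = 0.8
    nucleophile_strong_cutoff: float = 3.0
    nucleophile_marginal_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if self.electrophile_strong_cutoff <= self.electrophile_marginal_cutoff:
            raise ValueError("electrophile strong cutoff must exceed marginal")
        if self.nucleophile_strong_cutoff <= self.nucleophile_marginal_cutoff:
            raise ValueError("nucleophile strong cutoff must exceed marginal")


@dataclass
class GlobalDescriptorSet:
    """The eight global descriptors of one molecule (eV; softness eV⁻¹)."""

    molecule_id: str
    chi: float
    eta: float
    softness: float
    omega: float
    nu: float
    omega_minus: float
    omega_plus: float
    net_electrophilicity: float


def _require_finite(*values: float) -> None:
    if not all(math.isfinite(v) for v in values):
        raise MissingDataError("orbital energies must be finite numbers")


def electronegativity(homo: float, lumo: float) -> float:
    """χ = −(ϵH + ϵL)/2, the magnitude (positive-sign) convention."""
    _require_finite(homo, lumo)
    return -(homo + lumo) / 2.0


def chemical_potential(homo: float, lumo: float) -> float:
    """μ = (ϵH + ϵL)/2 = −χ."""
    return -electronegativity(homo, lumo)


def hardness(homo: float, lumo: float) -> float:
    """η = ϵL − ϵH (the full HOMO–LUMO gap, no ½ factor).

    A non-positive gap is physically suspect for a closed-shell ground
    state; the value is still returned but a warning is emitted.
    """
    _require_finite(homo, lumo)
    if lumo <= homo:
        warnings.warn(f"non-positive HOMO-LUMO gap ({lumo} ≤ {homo}); "
                      "hardness is not meaningful", stacklevel=2)
    return lumo - homo


def softness(eta: float) -> float:
    """S = 1/η (eV⁻¹)."""
    if eta == 0:
        raise UndefinedValueError("softness undefined for zero hardness")
    return 1.0 / eta


def electrophilicity(homo: float, lumo: float, *,
                     four_eta: bool = False) -> float:
    """Electrophilicity index ω.

    Default is the Parr form ω = χ²/(2η) = (ϵH+ϵL)²/(8(ϵL−ϵH)).  With
    ``four_eta=True`` the (ϵH+ϵL)²/(4η) variant is returned instead (exactly
    double); it is retained for auditing against sources that print that
    denominator.
    """
    _require_finite(homo, lumo)
    gap = lumo - homo
    if gap == 0:
        raise UndefinedValueError("electrophilicity undefined for zero gap")
    denom = 4.0 if four_eta else 8.0
    return (homo + lumo) ** 2 / (denom * gap)


def charge_transfer_powers(homo: float,
                           lumo: float) -> tuple[float, float, float]:
    """(ω⁻, ω⁺, Δω±): electrodonating, electroaccepting, net.

    ω⁻ = (3ϵH+ϵL)²/(16η), ω⁺ = (ϵH+3ϵL)²/(16η), Δω± = ω⁻ + ω⁺.
    The identity ω⁻ − ω⁺ = χ holds exactly.
    """
    _require_finite(homo, lumo)
    eta = lumo - homo
    if eta == 0:
        raise UndefinedValueError("charge-transfer powers undefined for "
                                  "zero gap")
    omega_minus = (3.0 * homo + lumo) ** 2 / (16.0 * eta)
    omega_plus = (homo + 3.0 * lumo) ** 2 / (16.0 * eta)
    return omega_minus, omega_plus, omega_minus + omega_plus


def nucleophilicity(homo: float,
                    config: ReactivityConfig | None = None) -> float:
    """N = ϵH(molecule) − ϵH(TCE reference)."""
    config = config or ReactivityConfig()
    _require_finite(homo, config.tce_homo_reference)
    return homo - config.tce_homo_reference


def classify_electrophile(omega: float,
                          config: ReactivityConfig | None = None) -> str:
    """Bin ω on the electrophilicity scale.

    Values exactly at a cutoff fall in the moderate band (ties resolve
    toward the middle band).
    """
    config = config or ReactivityConfig()
    if omega > config.electrophile_strong_cutoff:
        return "strong"
    if omega >= config.electrophile_marginal_cutoff:
        return "moderate"
    return "marginal"


def classify_nucleophile(nu: float,
                         config: ReactivityConfig | None = None) -> str:
    """Bin N on the nucleophilicity scale.

    N exactly at the marginal cutoff is marginal; exactly at the strong
    cutoff is moderate (ties resolve toward the middle band).
    """
    config = config or ReactivityConfig()
    if nu > config.nucleophile_strong_cutoff:
        return "strong"
    if nu > config.nucleophile_marginal_cutoff:
        return "moderate"
    return "marginal"


def global_descriptor_set(
    mol: MoleculeEnergetics,
    config: ReactivityConfig | None = None,
) -> GlobalDescriptorSet:
    """Assemble the full descriptor set from a molecule's neutral species."""
    config = config or ReactivityConfig()
    if mol.neutral is None or mol.neutral.homo is None \
            or mol.neutral.lumo is None:
        raise MissingDataError(
            f"{mol.molecule_id}: neutral-species HOMO and LUMO are required "
            "for global descriptors")
    h, l = mol.neutral.homo, mol.neutral.lumo
    eta = hardness(h, l)
    w_minus, w_plus, net = charge_transfer_powers(h, l)
    return GlobalDescriptorSet(
        molecule_id=mol.molecule_id,
        chi=electronegativity(h, l),
        eta=eta,
        softness=softness(eta),
        omega=electrophilicity(h, l),
        nu=nucleophilicity(h, config),
        omega_minus=w_minus,
        omega_plus=w_plus,
        net_electrophilicity=net,
    )
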