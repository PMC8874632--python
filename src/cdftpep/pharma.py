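"""Pharmacology layer: hardness-based pKa QSAR, bioactivity bands, ADMET.

The pKa model is a one-descriptor QSAR calibrated on amino acids and small
peptides,

    pKa = 16.3088 − 0.8268·η,

with η the global hardness in eV.  Bioactivity scores (from external
similarity-based predictors) are binned as active (> 0), moderately active
(−5 ≤ s ≤ 0, boundaries inclusive) or inactive (< −5).  ADMET handling is
ingestion-only: boolean predictions computed by external tools are
validated against a fixed 18-property vocabulary, attached to per-molecule
profiles and summarised across molecules as uniformly positive, uniformly
negative, or mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import VocabularyError

__all__ = [
    "PKA_INTERCEPT",
    "PKA_SLOPE",
    "ADMET_PROPERTIES",
    "BIOACTIVITY_TARGETS",
    "PharmaProfile",
    "predict_pka",
    "classify_bioactivity",
    "bioactivity_bands",
    "assemble_admet_report",
]

PKA_INTERCEPT = 16.3088
PKA_SLOPE = -0.8268

#: The fixed ADMET reporting vocabulary, in report order.
ADMET_PROPERTIES = (
    "HI Absorption",
    "BBB Permeability",
    "Caco-2",
    "P-gp Substrate",
    "P-gp Inhibitor",
    "CYP2C9 Substrate",
    "CYP2D6 Substrate",
    "CYP3A4 Substrate",
    "CYP1A2 Inhibitor",
    "CYP2C19 Inhibitor",
    "CYP2C9 Inhibitor",
    "CYP2D6 Inhibitor",
    "CYP3A4 Inhibitor",
    "OCT2 Substrate",
    "AMES Toxicity",
    "hERG Inhibitor",
    "Hepatotoxicity",
    "Skin Sensitization",
)

BIOACTIVITY_TARGETS = (
    "GPCR Ligand",
    "Ion Channel Modulator",
    "Nuclear Receptor Ligand",
    "Kinase Inhibitor",
    "Protease Inhibitor",
    "Enzyme Inhibitor",
)


@dataclass
class PharmaProfile:
    """Per-molecule pharmacology summary."""

    molecule_id: str
    pka_predicted: float | None = None
    bioactivity_scores: dict[str, float] = field(default_factory=dict)
    bioactivity_bands: dict[str, str] = field(default_factory=dict)
    admet_flags: dict[str, bool] = field(default_factory=dict)


def predict_pka(eta: float) -> float:
    """pKa = 16.3088 − 0.8268·η (η in eV).

    Strictly decreasing in hardness; the intercept is the soft-molecule
    (η → 0) limit of the calibration.
    """
    return PKA_INTERCEPT + PKA_SLOPE * eta


def classify_bioactivity(score: float) -> str:
    """Band a bioactivity score: active / moderately_active / inactive.

    The boundaries 0 and −5 are assigned to the middle band (inclusive
    convention).
    """
    if score > 0.0:
        return "active"
    if score >= -5.0:
        return "moderately_active"
    return "inactive"


def bioactivity_bands(scores: dict[str, float]) -> dict[str, str]:
    """Band every target score; target names are validated."""
    unknown = set(scores) - set(BIOACTIVITY_TARGETS)
    if unknown:
        raise VocabularyError(f"unknown bioactivity target(s): "
                              f"{sorted(unknown)}; expected "
                              f"{list(BIOACTIVITY_TARGETS)}")
    return {t: classify_bioactivity(s) for t, s in scores.items()}


def assemble_admet_report(
    flags: pd.DataFrame,
) -> tuple[dict[str, dict[str, bool]], dict[str, str]]:
    """Validate and summarise an ADMET boolean matrix.

    Parameters
    ----------
    flags : DataFrame indexed by property name (rows) with one boolean
        column per molecule.

    Returns
    -------
    per_molecule : mapping molecule → {property: bool}
    summary : mapping property → 'uniform_positive' | 'uniform_negative'
        | 'mixed'; the three categories partition the properties.
    """
    unknown = set(flags.index) - set(ADMET_PROPERTIES)
    if unknown:
        raise VocabularyError(f"unknown ADMET propert(ies): "
                              f"{sorted(unknown)}")
    bool_flags = flags.astype(bool)
    per_molecule = {
        str(mol): bool_flags[mol].to_dict() for mol in bool_flags.columns
    }
    summary: dict[str, str] = {}
    for prop, row in bool_flags.iterrows():
        if row.all():
            summary[str(prop)] = "uniform_positive"
        elif not row.any():
            summary[str(prop)] = "uniform_negative"
        else:
            summary[str(prop)] = "mixed"
    return per_molecule, summary
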