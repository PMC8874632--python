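"""Bundled reference datasets for the Veraguamides A–G case study.

All loaders return freshly parsed objects; nothing is cached or mutated.
The energetics fixture flows through the same public reader as user data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .energetics import MoleculeEnergetics, SolventSpec, read_energetics_table
from .kid import BenchmarkCell

__all__ = [
    "load_veraguamide_energetics",
    "load_kid_reference",
    "load_global_descriptor_reference",
    "load_benchmark_table",
    "load_pka_reference",
    "load_bioactivity_scores",
    "load_admet_table",
]


def _data_path(name: str):
    return resources.files("cdftpep.data").joinpath(name)


def load_veraguamide_energetics() -> list[MoleculeEnergetics]:
    """Species triads of the seven Veraguamides (MN12SX, SMD water)."""
    with resources.as_file(_data_path("veraguamides_table2.csv")) as p:
        return read_energetics_table(p)


def load_kid_reference() -> pd.DataFrame:
    """Published KID indices, indexed by molecule.

    The file documents an inconsistency for Veraguamides A and F between
    the published ΔSL and |SOMO−LUMO| from the published orbital energies.
    """
    with resources.as_file(_data_path("table2_kid_reference.csv")) as p:
        return pd.read_csv(p, comment="#", index_col="molecule_id")


def load_global_descriptor_reference() -> pd.DataFrame:
    """Published global descriptor table, indexed by molecule."""
    with resources.as_file(_data_path("table3_reference.csv")) as p:
        return pd.read_csv(p, comment="#", index_col="molecule_id")


def load_benchmark_table() -> list[BenchmarkCell]:
    """Mean-GKD benchmark cells: 10 functionals × 12 solvents, 7 molecules.

    Solvent dielectrics are reconstructed from the tabulated 1/ϵ values.
    """
    with resources.as_file(_data_path("table1_benchmark.csv")) as p:
        df = pd.read_csv(p, comment="#")
    return [
        BenchmarkCell(
            functional=row.functional,
            solvent=SolventSpec(row.solvent_name, 1.0 / row.inv_dielectric),
            mean_gkd=row.mean_gkd,
            n_molecules=int(row.n_molecules),
        )
        for row in df.itertuples()
    ]


def load_pka_reference() -> pd.DataFrame:
    """Published pKa predictions (reference only; see the fixture note)."""
    with resources.as_file(_data_path("table4_pka_reference.csv")) as p:
        return pd.read_csv(p, comment="#", index_col="molecule_id")


def load_bioactivity_scores() -> pd.DataFrame:
    """External bioactivity scores, molecules × six target classes."""
    with resources.as_file(_data_path("table5_bioactivity_scores.csv")) as p:
        return pd.read_csv(p, comment="#", index_col="molecule_id")


def load_admet_table() -> pd.DataFrame:
    """External ADMET predictions as booleans, properties × molecules."""
    with resources.as_file(_data_path("table6_admet.csv")) as p:
        df = pd.read_csv(p, comment="#", index_col="property")
    return df.apply(lambda col: col.str.strip() == "+")
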