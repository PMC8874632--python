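"""End-to-end orchestration: energetics → descriptors → KID → pharma.

The pipeline reads one energetics table, computes every applicable
descriptor table, and emits delimited text outputs with fixed ordering
(lexicographic by molecule id) and fixed rounding (3 decimals for
descriptor/KID tables, 2 for pKa and benchmark means, half away from
zero), so reruns on unchanged inputs are byte-identical.  A failure in one
molecule is logged with its stage name and the run continues over the
remaining molecules.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .energetics import MoleculeEnergetics, read_energetics_table
from .errors import CdftpepError
from .global_reactivity import (ReactivityConfig, classify_electrophile,
                                classify_nucleophile, global_descriptor_set)
from .kid import delta_sl, gkd, j_affinity, j_hl, j_ionization
from .pharma import assemble_admet_report, bioactivity_bands, predict_pka

__all__ = ["RunConfig", "RunResult", "run_pipeline", "round_half_away"]


def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed tables).

    Python's built-in ``round`` is banker's rounding; printed chemistry
    tables round 0.0005 up in magnitude.
    """
    if not math.isfinite(value):
        return value
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(value))
    return float(d.copy_abs().quantize(q, rounding=ROUND_HALF_UP)
                 * (1 if d >= 0 else -1))


@dataclass
class RunConfig:
    """Inputs, options and output location of one pipeline run."""

    energetics: str | Path
    output_dir: str | Path | None = None
    bioactivity_scores: str | Path | None = None
    admet: str | Path | None = None
    reactivity: ReactivityConfig = field(default_factory=ReactivityConfig)

    def config_hash(self) -> str:
        payload = json.dumps({
            "energetics": str(self.energetics),
            "bioactivity_scores": (None if self.bioactivity_scores is None
                                   else str(self.bioactivity_scores)),
            "admet": None if self.admet is None else str(self.admet),
            "reactivity": vars(self.reactivity),
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    """Tables, per-molecule failures and the run log of one pipeline run."""

    global_descriptors: pd.DataFrame
    kid_indices: pd.DataFrame
    classifications: pd.DataFrame
    pka: pd.DataFrame
    bioactivity: pd.DataFrame | None
    admet_summary: pd.DataFrame | None
    failures: list[tuple[str, str, str]]  # (molecule, stage, message)
    log: list[str]


_GLOBAL_COLUMNS = ["chi", "eta", "omega", "softness", "nu",
                   "omega_minus", "omega_plus", "net_electrophilicity"]
_KID_COLUMNS = ["homo", "lumo", "somo", "gap", "j_i", "j_a", "j_hl",
                "delta_sl", "gkd"]


def _kid_row(triad: MoleculeEnergetics, log: list[str]) -> dict:
    n = triad.neutral
    row: dict[str, float] = {
        "homo": n.homo if n else math.nan,
        "lumo": n.lumo if n else math.nan,
        "somo": (triad.anion.somo if triad.anion
                 and triad.anion.somo is not None else math.nan),
        "gap": (n.lumo - n.homo if n and n.homo is not None
                and n.lumo is not None else math.nan),
    }
    try:
        row["delta_sl"] = delta_sl(triad)
    except CdftpepError:
        row["delta_sl"] = math.nan
    # J indices need real total energies; a non-positive finite-difference
    # ionization energy marks placeholder or corrupt totals.
    ji = ja = math.nan
    if not triad.is_partial:
        i_fd = triad.cation.total_energy - triad.neutral.total_energy
        if i_fd > 0:
            ji = j_ionization(triad)
            ja = j_affinity(triad)
        else:
            log.append(f"data-quality: {triad.molecule_id}: non-positive "
                       "finite-difference ionization energy; "
                       "J(I)/J(A)/GKD suppressed")
    row["j_i"], row["j_a"] = ji, ja
    row["j_hl"] = j_hl(ji, ja) if math.isfinite(ji) else math.nan
    row["gkd"] = (gkd(ji, ja, row["j_hl"], row["delta_sl"])
                  if math.isfinite(ji) and math.isfinite(row["delta_sl"])
                  else math.nan)
    return row


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every applicable stage; write delimited outputs if configured."""
    log: list[str] = [f"cdftpep {__version__} config={config.config_hash()}"]
    failures: list[tuple[str, str, str]] = []

    triads = read_energetics_table(config.energetics)
    log.append(f"read {len(triads)} molecule triad(s) from "
               f"{Path(config.energetics).name}")
    if not triads:
        log.append("warning: energetics input is empty")

    global_rows, kid_rows, class_rows, pka_rows = {}, {}, {}, {}
    for triad in sorted(triads, key=lambda t: t.molecule_id):
        mid = triad.molecule_id
        if "partial" in triad.flags:
            log.append(f"data-quality: {mid}: partial triad "
                       "(missing charged species)")
        try:
            gset = global_descriptor_set(triad, config.reactivity)
        except CdftpepError as exc:
            failures.append((mid, "global_descriptors", str(exc)))
            log.append(f"error: {mid} [global_descriptors]: {exc}")
            continue
        global_rows[mid] = {c: getattr(gset, c) for c in _GLOBAL_COLUMNS}
        class_rows[mid] = {
            "electrophile_band": classify_electrophile(gset.omega,
                                                       config.reactivity),
            "nucleophile_band": classify_nucleophile(gset.nu,
                                                     config.reactivity),
        }
        pka_rows[mid] = {"pka_predicted": predict_pka(gset.eta)}
        kid_rows[mid] = _kid_row(triad, log)

    global_df = pd.DataFrame.from_dict(global_rows, orient="index",
                                       columns=_GLOBAL_COLUMNS)
    kid_df = pd.DataFrame.from_dict(kid_rows, orient="index",
                                    columns=_KID_COLUMNS)
    class_df = pd.DataFrame.from_dict(
        class_rows, orient="index",
        columns=["electrophile_band", "nucleophile_band"])
    pka_df = pd.DataFrame.from_dict(pka_rows, orient="index",
                                    columns=["pka_predicted"])
    for df in (global_df, kid_df, class_df, pka_df):
        df.index.name = "molecule_id"

    bio_df = None
    if config.bioactivity_scores is not None:
        scores = pd.read_csv(config.bioactivity_scores, comment="#",
                             index_col="molecule_id")
        bio_df = pd.DataFrame({
            mol: {t: f"{s:.2f} ({b})" for (t, s), b in
                  zip(row.items(), bioactivity_bands(row.to_dict()).values())}
            for mol, row in scores.iterrows()
        }).T
        bio_df.index.name = "molecule_id"

    admet_df = None
    if config.admet is not None:
        raw = pd.read_csv(config.admet, comment="#", index_col="property")
        flags = raw.apply(lambda col: col.astype(str).str.strip() == "+")
        _, summary = assemble_admet_report(flags)
        admet_df = pd.DataFrame.from_dict(summary, orient="index",
                                          columns=["consensus"])
        admet_df.index.name = "property"

    result = RunResult(global_df, kid_df, class_df, pka_df, bio_df,
                       admet_df, failures, log)
    if config.output_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: RunResult, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# cdftpep {__version__} config={config.config_hash()}\n"

    def dump(df: pd.DataFrame, name: str, ndigits: int | None) -> None:
        shown = df.copy()
        if ndigits is not None:
            num = shown.select_dtypes("number").columns
            shown[num] = shown[num].map(
                lambda v: round_half_away(v, ndigits))
        path = outdir / name
        path.write_text(
            header + shown.to_csv(float_format=f"%.{ndigits}f"
                                  if ndigits is not None else None))

    dump(result.global_descriptors, "global_descriptors.csv", 3)
    dump(result.kid_indices, "kid_indices.csv", 3)
    dump(result.classifications, "classifications.csv", None)
    dump(result.pka, "pka_predictions.csv", 2)
    if result.bioactivity is not None:
        dump(result.bioactivity, "bioactivity_bands.csv", None)
    if result.admet_summary is not None:
        dump(result.admet_summary, "admet_summary.csv", None)
    (outdir / "run_log.txt").write_text("\n".join(result.log) + "\n")
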