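"""CSV and config I/O with unit-explicit columns, plus run reporting.

Boundary unit convention: volumes in mL, concentrations in M, time in
hours, absorbance dimensionless — stated in the column headers so that the
mixed uL/mL/uM/mM usage common in lab notebooks cannot leak in silently.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .binding import NO_BINDING
from .column import ColumnConfig, Program, ProgramStep, SpeciesSpec
from .errors import ParseError
from .photokinetics import K_THERMAL_PER_H, PhotoPhase, standard_phases
from .spectra import IsomerFractions, IsomerSpectra

__all__ = [
    "DIALECTS",
    "read_table",
    "write_table",
    "read_spectra",
    "write_spectra",
    "RunConfig",
    "load_config",
    "build_simulation",
    "run_report",
    "report_text",
]

logger = logging.getLogger("azochrom")

#: required numeric columns per table dialect
DIALECTS = {
    "titration": ["v_cd_mL", "absorbance"],
    "relaxation": ["time_h", "absorbance"],
    "dilution": ["conc_M", "absorbance"],
    "spectra": ["wavelength_nm", "eps_trans", "eps_cis"],
    "chromatogram": ["fraction_start_mL", "fraction_end_mL", "amount_nmol"],
}


def read_table(path, dialect: str) -> pd.DataFrame:
    """Read and validate a CSV table of a known dialect.

    Raises :class:`ParseError` naming the offending row/column for missing
    columns, non-numeric cells or an empty file; tolerates (and warns
    about) extra columns.
    """
    if dialect not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect!r}; know {sorted(DIALECTS)}")
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    required = DIALECTS[dialect]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring extra column(s) {extra}", stacklevel=2)
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in "
                f"column {col!r}, row {bad[0] + 2} (1-based incl. header)"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0])
            raise ParseError(f"{path}: empty cell in column {col!r}, row {row + 2}")
        df[col] = coerced
    return df[required + extra]


def write_table(df: pd.DataFrame, path, dialect: str | None = None) -> None:
    if dialect is not None:
        missing = [c for c in DIALECTS[dialect] if c not in df.columns]
        if missing:
            raise ParseError(f"refusing to write {dialect} table without {missing}")
    df.to_csv(path, index=False)


def read_spectra(path) -> IsomerSpectra:
    df = read_table(path, "spectra")
    return IsomerSpectra(
        df["wavelength_nm"].to_numpy(),
        df["eps_trans"].to_numpy(),
        df["eps_cis"].to_numpy(),
    )


def write_spectra(spectra: IsomerSpectra, path) -> None:
    write_table(spectra.to_frame(), path, "spectra")


# -- structured run configuration -----------------------------------------


class PhaseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    x_cis_pss: float = Field(ge=0.0, le=1.0)
    k_photo_per_h: float = Field(ge=0.0)
    k_thermal_per_h: float = Field(default=K_THERMAL_PER_H, ge=0.0)

    def to_phase(self) -> PhotoPhase:
        return PhotoPhase(
            self.label,
            IsomerFractions.from_cis(self.x_cis_pss),
            self.k_photo_per_h,
            self.k_thermal_per_h,
        )


class SpeciesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    load_amount_nmol: float = Field(ge=0.0)
    x_cis_load: float = Field(default=0.0, ge=0.0, le=1.0)
    K_D_trans_M: float | None = None  # null -> no binding
    K_D_cis_M: float | None = None
    photoactive: bool = True
    competitor_block: float = Field(default=0.0, ge=0.0, le=1.0)

    def to_spec(self) -> SpeciesSpec:
        return SpeciesSpec(
            name=self.name,
            load_amount=self.load_amount_nmol,
            load_fractions=IsomerFractions.from_cis(self.x_cis_load),
            K_D_trans=self.K_D_trans_M if self.K_D_trans_M is not None else NO_BINDING,
            K_D_cis=self.K_D_cis_M if self.K_D_cis_M is not None else NO_BINDING,
            photoactive=self.photoactive,
            competitor_block=self.competitor_block,
        )


class ColumnBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_plates: int = 30
    bed_volume_mL: float = 1.0
    ligand_conc_M: float = 10e-3
    transmission: float = 0.5
    flow_rate_mL_min: float = 1.0

    def to_config(self) -> ColumnConfig:
        return ColumnConfig(
            n_plates=self.n_plates,
            bed_volume=self.bed_volume_mL,
            ligand_conc=self.ligand_conc_M,
            transmission=self.transmission,
            flow_rate=self.flow_rate_mL_min,
        )


class StepConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    volume_mL: float = Field(gt=0.0)
    phase: str


class ProgramConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    load_volume_mL: float = Field(default=0.1, ge=0.0)
    steps: list[StepConfig]


class RunConfig(BaseModel):
    """Structured description of a column simulation run."""

    model_config = ConfigDict(extra="forbid")
    column: ColumnBlock = ColumnBlock()
    phases: list[PhaseConfig] = []
    species: list[SpeciesConfig]
    program: ProgramConfig
    seed: int | None = None


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"config file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ParseError(f"{path}: invalid configuration:\n{exc}") from None


def build_simulation(cfg: RunConfig):
    """Materialize (ColumnConfig, species list, Program) from a RunConfig.

    Phase names in program steps resolve first against the ``phases:``
    block, then against the built-in dark/daylight/uv355/blue430 set.
    """
    phases = standard_phases()
    phases.update({p.label: p.to_phase() for p in cfg.phases})
    column = cfg.column.to_config()
    species = [s.to_spec() for s in cfg.species]
    steps = []
    for s in cfg.program.steps:
        if s.phase not in phases:
            raise ParseError(
                f"program step references unknown phase {s.phase!r}; "
                f"known: {sorted(phases)}"
            )
        steps.append(ProgramStep(s.volume_mL, phases[s.phase]))
    program = Program(steps=tuple(steps), load_volume=cfg.program.load_volume_mL)
    logger.info(
        "resolved simulation: n_plates=%d bed=%.3g mL sites=%.3g M "
        "transmission=%.2f flow=%.3g mL/min",
        column.n_plates, column.bed_volume, column.ligand_conc,
        column.transmission, column.flow_rate,
    )
    return column, species, program


# -- reporting -------------------------------------------------------------


def run_report(results: dict, seed: int | None = None, config: dict | None = None) -> dict:
    """Machine-readable summary of a completed fit or simulation.

    Dissociation constants (any key ending ``K_D_M``) are duplicated in uM
    for readability.  The exact seed and configuration are embedded so the
    run can be reproduced from the report alone.
    """
    out = dict(results)
    for key in list(out):
        if key.endswith("K_D_M") and isinstance(out[key], (int, float)):
            out[key.replace("_M", "_uM")] = out[key] * 1e6
    return {"results": out, "seed": seed, "config": config or {}}


def report_text(report: dict) -> str:
    lines = ["azochrom run report", "==================="]
    lines.append(f"seed: {report.get('seed')}")
    for key, val in report["results"].items():
        if isinstance(val, float):
            lines.append(f"{key}: {val:.6g}")
        else:
            lines.append(f"{key}: {val}")
    if report.get("config"):
        lines.append("config: " + json.dumps(report["config"], sort_keys=True))
    return "\n".join(lines) + "\n"
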