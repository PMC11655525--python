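"""Theoretical-plate (Craig) simulator of light-controlled affinity columns.

The packed bed is discretized into ``n_plates`` serial equilibrium stages.
Each flow step advances one plate-volume of mobile phase: the free (mobile)
material of plate *i* moves to plate *i+1*, the last plate's mobile contents
leave as effluent, and fresh buffer (or sample, while loading) enters plate
1; every plate then re-equilibrates its free/bound partition against the
immobilized ligand sites via the 1:1 mass-action quadratic.  Retention thus
emerges from per-plate partitioning: a species with per-plate free fraction
``f`` migrates ``f`` plates per step, i.e. needs about ``1/f`` bed volumes
to traverse the column.

Illumination couples in through the isomer composition: the trans state of
the azobenzene tag binds the matrix (K_D ~ 1e-4 M for alpha-CD) while the
cis state shows no measurable affinity, so driving the population to a
cis-rich photostationary state mobilizes the band.  Light intensity inside
the bed is reduced by a single transmission factor (>= 50 % for a typical
1 mL agarose column); the spatial attenuation profile is not resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import NO_BINDING
from .errors import ParameterError
from .photokinetics import PhotoPhase
from .spectra import IsomerFractions

__all__ = [
    "ColumnConfig",
    "SpeciesSpec",
    "ProgramStep",
    "Program",
    "Chromatogram",
    "Column",
    "equilibrate_plate",
    "run_program",
]


@dataclass(frozen=True)
class ColumnConfig:
    """Geometry and chemistry of the discretized affinity bed.

    ``ligand_conc`` is the concentration of accessible immobilized ligand
    sites referred to the plate volume (a calibration parameter; the true
    site density of an epoxy-coupled matrix is not directly measurable).
    ``transmission`` scales all photochemical rates inside the bed.
    ``flow_rate`` (mL/min) converts flow steps into real time so that
    photo/thermal rates in 1/h act on the correct timescale.
    """

    n_plates: int = 30
    bed_volume: float = 1.0  # mL
    ligand_conc: float = 10e-3  # M of sites per plate volume
    transmission: float = 0.5
    flow_rate: float = 1.0  # mL/min

    def __post_init__(self):
        if self.n_plates < 2:
            raise ParameterError("need at least 2 theoretical plates")
        if self.bed_volume <= 0 or self.flow_rate <= 0:
            raise ParameterError("bed volume and flow rate must be positive")
        if not 0 < self.transmission <= 1:
            raise ParameterError("transmission must be in (0, 1]")
        if self.ligand_conc < 0:
            raise ParameterError("ligand concentration must be non-negative")

    @property
    def plate_volume(self) -> float:
        """Mobile-phase volume advanced per flow step, mL."""
        return self.bed_volume / self.n_plates

    @property
    def sites_per_plate(self) -> float:
        """Immobilized ligand sites per plate, nmol."""
        return self.ligand_conc * self.plate_volume * 1e6

    @property
    def dt_per_step(self) -> float:
        """Real time elapsed per flow step, hours."""
        return self.plate_volume / self.flow_rate / 60.0


@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular species applied to the column.

    ``K_D_trans`` / ``K_D_cis`` are the matrix dissociation constants of the
    two isomer states (``NO_BINDING`` for no measurable affinity).  A
    non-photoactive species (untagged contaminant, host protein) keeps its
    isomer fractions frozen; its binding, if any, uses ``K_D_trans``.
    ``competitor_block`` is the fraction of molecules whose binding pocket
    is pre-occupied by a competitor (e.g. maltose-saturated MBP) and which
    therefore behave as non-binding.
    """

    name: str
    load_amount: float  # nmol
    load_fractions: IsomerFractions = field(
        default_factory=IsomerFractions.pure_trans
    )
    K_D_trans: float = NO_BINDING
    K_D_cis: float = NO_BINDING
    photoactive: bool = True
    competitor_block: float = 0.0

    def __post_init__(self):
        if self.load_amount < 0:
            raise ParameterError("load amount must be non-negative")
        if not (self.K_D_trans > 0 and self.K_D_cis > 0):
            raise ParameterError("K_D values must be > 0 (or NO_BINDING)")
        if not 0.0 <= self.competitor_block <= 1.0:
            raise ParameterError("competitor_block must be a fraction in [0, 1]")


@dataclass(frozen=True)
class ProgramStep:
    volume: float  # mL
    phase: PhotoPhase

    def __post_init__(self):
        if self.volume <= 0:
            raise ParameterError("step volume must be positive")


@dataclass(frozen=True)
class Program:
    """Ordered illumination/flow steps plus the sample-application volume.

    The sample (all species' ``load_amount``) enters the column dissolved in
    the first ``load_volume`` mL of the first step's flow, under that step's
    illumination — so a dark load and a blue-light load differ in how much
    of a cis-containing sample is captured.
    """

    steps: tuple[ProgramStep, ...]
    load_volume: float = 0.1  # mL

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))
        if not self.steps:
            raise ParameterError("program must contain at least one step")
        if self.load_volume < 0:
            raise ParameterError("load volume must be non-negative")

    @property
    def total_volume(self) -> float:
        return sum(s.volume for s in self.steps)


def equilibrate_plate(
    free: float, bound: float, plate_volume: float, ligand_sites: float, K_D: float
) -> tuple[float, float]:
    """Re-partition one species pool in one plate (amounts in nmol).

    Mass-conserving solution of the single-site binding quadratic at the
    plate scale; the site pool is taken at its nominal value (trace-load
    regime).  ``K_D = NO_BINDING`` puts everything in the mobile phase.
    """
    if free < 0 or bound < 0 or plate_volume <= 0 or ligand_sites < 0:
        raise ParameterError("inputs must be non-negative, volume positive")
    total = free + bound
    if total == 0.0:
        return 0.0, 0.0
    if math.isinf(K_D) or ligand_sites == 0.0:
        return total, 0.0
    v_L = plate_volume * 1e-3  # mL -> L
    g = total * 1e-9 / v_L  # M
    s = ligand_sites * 1e-9 / v_L  # M
    ssum = g + s + K_D
    b = 0.5 * (ssum - math.sqrt(max(ssum * ssum - 4.0 * g * s, 0.0)))
    b = min(max(b, 0.0), min(g, s))
    bound_new = b * v_L * 1e9
    return total - bound_new, bound_new


def _bound_vec(total: np.ndarray, sites_conc: float, K_D: float, v_L: float):
    """Vectorized plate equilibration: bound nmol for each plate."""
    if math.isinf(K_D) or sites_conc == 0.0:
        return np.zeros_like(total)
    g = total * 1e-9 / v_L
    ssum = g + sites_conc + K_D
    b = 0.5 * (ssum - np.sqrt(np.maximum(ssum**2 - 4.0 * g * sites_conc, 0.0)))
    b = np.clip(b, 0.0, np.minimum(g, sites_conc))
    return b * v_L * 1e9


class _SpeciesState:
    """Per-plate amounts (nmol) of one species, split by isomer and pool."""

    __slots__ = ("spec", "free", "bound", "blocked")

    def __init__(self, spec: SpeciesSpec, n_plates: int):
        self.spec = spec
        self.free = np.zeros((n_plates, 2))  # columns: trans, cis
        self.bound = np.zeros((n_plates, 2))
        self.blocked = np.zeros(n_plates)  # competitor-blocked, mobile only

    def total(self) -> float:
        return float(self.free.sum() + self.bound.sum() + self.blocked.sum())


class Column:
    """Mutable column state advanced by illumination and flow operations."""

    def __init__(self, config: ColumnConfig, species: list[SpeciesSpec]):
        self.config = config
        self.states = {sp.name: _SpeciesState(sp, config.n_plates) for sp in species}
        names = [sp.name for sp in species]
        if len(set(names)) != len(names):
            raise ParameterError("species names must be unique")

    # -- core operations ---------------------------------------------------

    def equilibrate(self) -> None:
        cfg = self.config
        v_L = cfg.plate_volume * 1e-3
        s_conc = cfg.ligand_conc
        for st in self.states.values():
            for iso, K in ((0, st.spec.K_D_trans), (1, st.spec.K_D_cis)):
                tot = st.free[:, iso] + st.bound[:, iso]
                b = _bound_vec(tot, s_conc, K, v_L)
                st.bound[:, iso] = b
                st.free[:, iso] = tot - b

    def inject(self, name: str, amount: float, fractions: IsomerFractions) -> None:
        """Add ``amount`` nmol of a species to plate 1 (mobile phase)."""
        st = self.states[name]
        block = st.spec.competitor_block
        bindable = amount * (1.0 - block)
        st.free[0, 0] += bindable * fractions.x_trans
        st.free[0, 1] += bindable * fractions.x_cis
        st.blocked[0] += amount * block

    def apply_illumination(self, phase: PhotoPhase, dt: float) -> None:
        """Evolve isomer compositions in every plate for ``dt`` hours.

        Photochemical rates are scaled by the bed transmission; thermal
        relaxation is unattenuated.  After the composition update each
        plate re-equilibrates (local-equilibrium assumption), so material
        arriving in a newly non-binding state becomes mobile at once.
        """
        k_p = phase.k_photo * self.config.transmission
        k_t = phase.k_thermal
        k_tot = k_p + k_t
        if k_tot > 0.0 and dt > 0.0:
            x_eq = k_p * phase.pss.x_cis / k_tot
            decay = math.exp(-k_tot * dt)
            for st in self.states.values():
                if not st.spec.photoactive:
                    continue
                tot = st.free + st.bound  # (n_plates, 2)
                plate_tot = tot.sum(axis=1)
                occupied = plate_tot > 0.0
                if not occupied.any():
                    continue
                x_cis = np.zeros_like(plate_tot)
                x_cis[occupied] = tot[occupied, 1] / plate_tot[occupied]
                x_new = x_eq + (x_cis - x_eq) * decay
                # redistribute plate totals across isomer pools, all mobile,
                # then re-equilibrate below
                st.free[:, 0] = plate_tot * (1.0 - x_new)
                st.free[:, 1] = plate_tot * x_new
                st.bound[:] = 0.0
        self.equilibrate()

    def advance_flow(
        self, inject: dict[str, tuple[float, IsomerFractions]] | None = None
    ) -> dict[str, float]:
        """One Craig transfer; returns effluent per species, nmol.

        Mobile contents of plate *i* move to plate *i+1*; the last plate's
        mobile contents leave the column; plate 1 receives fresh buffer or,
        while loading, a sample aliquot given by ``inject``.
        """
        effluent: dict[str, float] = {}
        for name, st in self.states.items():
            out = float(st.free[-1].sum() + st.blocked[-1])
            st.free[1:] = st.free[:-1]
            st.free[0] = 0.0
            st.blocked[1:] = st.blocked[:-1]
            st.blocked[0] = 0.0
            effluent[name] = out
        if inject:
            for name, (amount, fractions) in inject.items():
                self.inject(name, amount, fractions)
        self.equilibrate()
        return effluent

    # -- observables -------------------------------------------------------

    def retained(self, name: str) -> float:
        """Total amount of a species currently on the column, nmol."""
        return self.states[name].total()

    def band_center(self, name: str) -> float:
        """Mass-weighted mean plate index (0-based); NaN if column empty."""
        st = self.states[name]
        per_plate = st.free.sum(axis=1) + st.bound.sum(axis=1) + st.blocked
        m = per_plate.sum()
        if m <= 0.0:
            return float("nan")
        return float(np.arange(self.config.n_plates) @ per_plate / m)


@dataclass
class Chromatogram:
    """Effluent record of a simulated run plus per-step column observables.

    ``effluent[name]`` holds the amount (nmol) leaving the column in each
    flow step; ``fraction_edges`` are the cumulative-volume boundaries of
    those steps (mL), so step *i* spans ``fraction_edges[i]`` to
    ``fraction_edges[i+1]``.
    """

    fraction_edges: np.ndarray
    effluent: dict[str, np.ndarray]
    retained: dict[str, np.ndarray]
    band_center: dict[str, np.ndarray]
    phase_labels: list[str]
    phase_start_volumes: dict[str, float]
    loads: dict[str, float]

    @property
    def n_steps(self) -> int:
        return len(self.phase_labels)

    def recovery(self, name: str) -> float:
        """Fraction of the loaded amount that left the column."""
        if self.loads[name] == 0.0:
            return 0.0
        return float(self.effluent[name].sum() / self.loads[name])

    def retained_at(self, name: str, volume: float) -> float:
        """Column content of a species when the run had delivered ``volume`` mL."""
        idx = int(np.searchsorted(self.fraction_edges[1:], volume + 1e-12))
        if idx == 0:
            return self.loads[name]
        return float(self.retained[name][min(idx, self.n_steps) - 1])

    def elution_volume(
        self, name: str, from_volume: float = 0.0, fraction: float = 0.95
    ) -> float:
        """Volume past ``from_volume`` to reach a cumulative recovery fraction.

        The reference amount is the column content at ``from_volume`` (e.g.
        at light-on), matching how elution sharpness is quoted in bed
        volumes from the start of the elution phase.  Returns ``inf`` if
        the fraction is never reached.
        """
        ref = self.retained_at(name, from_volume)
        if ref <= 0.0:
            return 0.0
        mask = self.fraction_edges[1:] > from_volume + 1e-12
        cum = np.cumsum(self.effluent[name][mask])
        hit = np.nonzero(cum >= fraction * ref - 1e-12)[0]
        if hit.size == 0:
            return float("inf")
        return float(self.fraction_edges[1:][mask][hit[0]] - from_volume)

    def window_amount(self, name: str, start: float, end: float) -> float:
        """Effluent of one species within a volume window, nmol."""
        centers = 0.5 * (self.fraction_edges[:-1] + self.fraction_edges[1:])
        mask = (centers >= start) & (centers < end)
        return float(self.effluent[name][mask].sum())

    def purity(self, name: str, start: float, end: float) -> float:
        """Mass purity of one species in a designated elution window."""
        total = sum(self.window_amount(n, start, end) for n in self.effluent)
        if total <= 0.0:
            return float("nan")
        return self.window_amount(name, start, end) / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_steps):
            for name, eff in self.effluent.items():
                rows.append(
                    {
                        "fraction_start_mL": self.fraction_edges[i],
                        "fraction_end_mL": self.fraction_edges[i + 1],
                        "species": name,
                        "amount_nmol": eff[i],
                        "phase": self.phase_labels[i],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out: dict = {"species": {}}
        for name in self.effluent:
            out["species"][name] = {
                "load_nmol": self.loads[name],
                "recovered_nmol": float(self.effluent[name].sum()),
                "recovery": self.recovery(name),
            }
        out["phase_start_volumes_mL"] = dict(self.phase_start_volumes)
        out["total_volume_mL"] = float(self.fraction_edges[-1])
        return out


def run_program(
    config: ColumnConfig, species: list[SpeciesSpec], program: Program
) -> Chromatogram:
    """Run a full load/wash/elute program and collect the chromatogram.

    Deterministic: loops ``apply_illumination`` + ``advance_flow`` per
    plate-volume of delivered buffer.  The sample is distributed uniformly
    over the flow steps that make up ``program.load_volume``.
    """
    col = Column(config, species)
    step_v = config.plate_volume
    dt = config.dt_per_step

    n_load = max(int(round(program.load_volume / step_v)), 1) if program.load_volume > 0 else 0

    edges = [0.0]
    labels: list[str] = []
    effluent: dict[str, list[float]] = {sp.name: [] for sp in species}
    retained: dict[str, list[float]] = {sp.name: [] for sp in species}
    centers: dict[str, list[float]] = {sp.name: [] for sp in species}
    phase_starts: dict[str, float] = {}
    loads = {sp.name: sp.load_amount for sp in species}

    step_count = 0
    vol = 0.0
    for prog_step in program.steps:
        phase_starts.setdefault(prog_step.phase.label, vol)
        n_steps = max(int(round(prog_step.volume / step_v)), 1)
        for _ in range(n_steps):
            col.apply_illumination(prog_step.phase, dt)
            inject = None
            if step_count < n_load:
                inject = {
                    sp.name: (sp.load_amount / n_load, sp.load_fractions)
                    for sp in species
                }
            out = col.advance_flow(inject=inject)
            vol += step_v
            edges.append(vol)
            labels.append(prog_step.phase.label)
            for name in out:
                effluent[name].append(out[name])
                retained[name].append(col.retained(name))
                centers[name].append(col.band_center(name))
            step_count += 1

    return Chromatogram(
        fraction_edges=np.array(edges),
        effluent={k: np.array(v) for k, v in effluent.items()},
        retained={k: np.array(v) for k, v in retained.items()},
        band_center={k: np.array(v) for k, v in centers.items()},
        phase_labels=labels,
        phase_start_volumes=phase_starts,
        loads=loads,
    )
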