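"""Seeded generators for every input the fitting and simulation stages read.

These emulate the experimental setup behind the models: cuvette titrations
of 50 uM Pap (2 mL) with a 50 mM cyclodextrin stock added in 1-20 uL
aliquots to 200 uL total (1:100 final molar ratio, 10 % dilution), thermal
relaxation traces sampled every 12 h over 100 h, Beer-Lambert dilution
series, and lysate-like species mixtures including the untagged by-product
of incomplete amber suppression.

Instrument noise is modelled as homoscedastic Gaussian absorbance noise
(default sigma 0.002 AU — an assumption about a well-behaved photometer,
not a measured property).  All generators are bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import (
    NO_BINDING,
    BindingParams,
    TitrationSeries,
    competitive_occupancy,
    titration_absorbance,
)
from .column import SpeciesSpec
from .errors import ParameterError
from .photokinetics import RelaxationParams, relaxation_curve
from .spectra import IsomerFractions

__all__ = [
    "NoiseModel",
    "default_titration_schedule",
    "make_titration",
    "make_dilution_series",
    "make_relaxation",
    "make_lysate",
    "KD_ALPHA_TRANS",
    "KD_BETA_TRANS",
    "KD_BETA_CIS",
    "KD_MBP_MALTOSE",
]

# reference dissociation constants (M) used as synthetic ground truths
KD_ALPHA_TRANS = 91e-6  # trans-Pap / alpha-CD
KD_BETA_TRANS = 325e-6  # trans-Pap / beta-CD
KD_BETA_CIS = 4.98e-3  # cis-Pap / beta-CD
KD_MBP_MALTOSE = 3.5e-6  # maltose-binding protein / maltose (proxy for matrix)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian absorbance noise with a reproducible seed."""

    sigma_absorbance: float = 0.002  # AU
    seed: int | None = None

    def __post_init__(self):
        if self.sigma_absorbance < 0:
            raise ParameterError("noise sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb(self, values: np.ndarray) -> np.ndarray:
        if self.sigma_absorbance == 0.0:
            return np.asarray(values, dtype=float).copy()
        return values + self.rng().normal(0.0, self.sigma_absorbance, np.shape(values))


def default_titration_schedule() -> np.ndarray:
    """Cumulative titrant volumes (mL): 1-20 uL aliquots totalling 200 uL."""
    additions_uL = [1, 1, 2, 2, 3, 4, 5, 7, 10, 10, 15, 20, 20, 20, 20, 20, 20, 20]
    return np.concatenate([[0.0], np.cumsum(additions_uL) / 1000.0])


def make_titration(
    params: BindingParams,
    V0: float = 2.0,
    C0_pap: float = 50e-6,
    C0_cd: float = 50e-3,
    schedule: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    wavelength: float = 326.0,
    path: float = 1.0,
) -> TitrationSeries:
    """Simulate one spectroscopic titration experiment.

    Default setup: 2 mL of 50 uM guest titrated with a 50 mM host stock to
    0.2 mL total addition — i.e. a 1:100 final guest:host molar ratio and a
    10 % dilution of the initial guest solution.
    """
    v = default_titration_schedule() if schedule is None else np.asarray(schedule, float)
    A = titration_absorbance(params, V0, C0_pap, C0_cd, v, path)
    A_noisy = noise.perturb(A)
    return TitrationSeries(
        V0=V0,
        C0_pap=C0_pap,
        C0_cd=C0_cd,
        points=tuple(zip(v.tolist(), A_noisy.tolist())),
        wavelength=wavelength,
    )


def make_dilution_series(
    epsilon: float = 21500.0,
    concentrations: np.ndarray | None = None,
    path: float = 1.0,
    noise: NoiseModel = NoiseModel(),
) -> np.ndarray:
    """Beer-Lambert dilution series as an ``(n, 2)`` array of (conc_M, A).

    Default grid: 10 concentrations from 5 to 50 uM.
    """
    c = (
        np.linspace(5e-6, 50e-6, 10)
        if concentrations is None
        else np.asarray(concentrations, float)
    )
    A = noise.perturb(epsilon * path * c)
    return np.column_stack([c, A])


def make_relaxation(
    params: RelaxationParams,
    t_max: float = 100.0,
    dt: float = 12.0,
    noise: NoiseModel = NoiseModel(),
) -> np.ndarray:
    """Thermal relaxation trace as an ``(n, 2)`` array of (time_h, A).

    Default sampling — every 12 h up to 100 h — gives 9 points, matching a
    spectrophotometer programmed for long measurement intervals to avoid
    actinic exposure at the diagnostic wavelength.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    t = np.arange(0.0, t_max + 1e-9, dt)
    A = noise.perturb(relaxation_curve(params, t))
    return np.column_stack([t, A])


def make_lysate(
    tag_efficiency: float = 0.5,
    poi_amount: float = 10.0,
    poi_name: str = "POI",
    load_fractions: IsomerFractions | None = None,
    K_D_trans: float = KD_ALPHA_TRANS,
    contaminant_amount: float = 100.0,
    include_mbp: bool = True,
    mbp_amount: float = 5.0,
    maltose_conc: float = 0.0,
) -> list[SpeciesSpec]:
    """Lysate-like species mixture for the column simulator.

    The protein of interest splits into an Azo-tagged, photoactive species
    (fraction ``tag_efficiency``, the amber-suppression yield — about 50 %
    in an RF-1-attenuated host versus 10-20 % in a wild-type background)
    and an otherwise identical species lacking the photoswitchable residue,
    which neither binds the matrix nor responds to light.  Bulk host
    proteins are non-binding; maltose-binding protein is given the matrix
    affinity of its maltose complex (K_D = 3.5 uM) as a documented proxy,
    and supplementing ``maltose_conc`` (M) pre-blocks the corresponding
    fraction of its pockets.
    """
    if not 0.0 <= tag_efficiency <= 1.0:
        raise ParameterError("tag_efficiency must be a fraction in [0, 1]")
    fractions = load_fractions or IsomerFractions.pure_trans()
    species: list[SpeciesSpec] = []
    if tag_efficiency > 0:
        species.append(
            SpeciesSpec(
                name=poi_name,
                load_amount=poi_amount * tag_efficiency,
                load_fractions=fractions,
                K_D_trans=K_D_trans,
                K_D_cis=NO_BINDING,
                photoactive=True,
            )
        )
    if tag_efficiency < 1:
        species.append(
            SpeciesSpec(
                name=f"{poi_name}-untagged",
                load_amount=poi_amount * (1.0 - tag_efficiency),
                load_fractions=fractions,
                K_D_trans=NO_BINDING,
                K_D_cis=NO_BINDING,
                photoactive=False,
            )
        )
    if contaminant_amount > 0:
        species.append(
            SpeciesSpec(
                name="host-proteins",
                load_amount=contaminant_amount,
                K_D_trans=NO_BINDING,
                K_D_cis=NO_BINDING,
                photoactive=False,
            )
        )
    if include_mbp:
        block = (
            competitive_occupancy(KD_MBP_MALTOSE, maltose_conc)
            if maltose_conc > 0
            else 0.0
        )
        species.append(
            SpeciesSpec(
                name="MBP",
                load_amount=mbp_amount,
                K_D_trans=KD_MBP_MALTOSE,
                K_D_cis=KD_MBP_MALTOSE,
                photoactive=False,
                competitor_block=block,
            )
        )
    return species
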