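"""Photostationary-state composition and cis/trans isomerization kinetics.

An azobenzene population under continuous illumination relaxes toward a
photostationary state (PSS) whose cis:trans ratio is set by the product of
extinction coefficient and isomerization quantum yield of each isomer at the
irradiation wavelength:

    x_cis / x_trans = (eps_trans * Phi_tc) / (eps_cis * Phi_ct)

In the dark the only process is the slow thermal cis -> trans relaxation
(first order, half-life about 196 h for Pap in aqueous buffer at 25 C).
Both processes are first order, so the composition approaches its attractor
exponentially with total rate ``k_photo + k_thermal``, where the attractor
blends the optical PSS and the all-trans thermal ground state weighted by
the two rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitConvergenceError, ParameterError, UnidentifiableError
from .spectra import IsomerFractions

__all__ = [
    "T_HALF_THERMAL_H",
    "K_THERMAL_PER_H",
    "RelaxationParams",
    "PhotoPhase",
    "standard_phases",
    "pss_cis_fraction",
    "phi_ratio_for_pss",
    "evolve_fractions",
    "relaxation_curve",
    "RelaxationFit",
    "fit_relaxation",
]

#: thermal cis->trans half-life of Pap in aqueous buffer at 25 C, hours
T_HALF_THERMAL_H = 196.0
#: corresponding first-order rate constant, 1/h
K_THERMAL_PER_H = math.log(2.0) / T_HALF_THERMAL_H


@dataclass(frozen=True)
class RelaxationParams:
    """Mono-exponential trace ``A(t) = Ainf - (Ainf - A0) exp(-ln2 t/t_half)``."""

    A0: float
    Ainf: float
    t_half: float  # hours

    def __post_init__(self):
        if self.t_half <= 0:
            raise ParameterError(f"t_half must be > 0, got {self.t_half}")


@dataclass(frozen=True)
class PhotoPhase:
    """An illumination condition.

    ``pss`` is the isomer composition the light drives the population toward
    and ``k_photo`` (1/h) the first-order rate of approach; ``k_thermal``
    (1/h) is the cis->trans dark relaxation rate, active in every phase.
    ``k_photo = 0`` describes the dark.
    """

    label: str
    pss: IsomerFractions
    k_photo: float
    k_thermal: float = K_THERMAL_PER_H

    def __post_init__(self):
        if self.k_photo < 0 or self.k_thermal < 0:
            raise ParameterError("rate constants must be non-negative")


def standard_phases(
    x_cis_uv: float = 0.95,
    x_cis_visible: float = 0.225,
    k_led: float = 5.0e4,
    k_daylight: float = 0.1,
    k_thermal: float = K_THERMAL_PER_H,
) -> dict[str, PhotoPhase]:
    """The four canonical illumination phases.

    Defaults: 355 nm LED drives ~95 % cis; daylight or a 430 nm LED leaves
    70-80 % trans (22.5 % cis midpoint).  LED phases are fast (PSS reached
    within a fraction of a plate-transfer time at typical flow rates);
    daylight photoconversion is slow enough that a several-column-volume
    wash sees an essentially frozen composition.
    """
    return {
        "dark": PhotoPhase("dark", IsomerFractions.pure_trans(), 0.0, k_thermal),
        "daylight": PhotoPhase(
            "daylight", IsomerFractions.from_cis(x_cis_visible), k_daylight, k_thermal
        ),
        "uv355": PhotoPhase(
            "uv355", IsomerFractions.from_cis(x_cis_uv), k_led, k_thermal
        ),
        "blue430": PhotoPhase(
            "blue430", IsomerFractions.from_cis(x_cis_visible), k_led, k_thermal
        ),
    }


def pss_cis_fraction(eps_t: float, eps_c: float, phi_ratio: float = 1.0) -> float:
    """Cis fraction at the photostationary state.

    ``phi_ratio`` is the quantum-yield ratio Phi(trans->cis)/Phi(cis->trans).
    With the PSS balance x_cis/x_trans = eps_t*phi_ratio/eps_c this gives
    ``x_cis = eps_t*phi_ratio / (eps_t*phi_ratio + eps_c)``.
    """
    if eps_t < 0 or eps_c < 0:
        raise ParameterError("extinction coefficients must be non-negative")
    if eps_t == 0 and eps_c == 0:
        raise ParameterError("PSS undefined when both isomers are transparent")
    if phi_ratio <= 0:
        raise ParameterError("phi_ratio must be positive")
    return eps_t * phi_ratio / (eps_t * phi_ratio + eps_c)


def phi_ratio_for_pss(x_cis: float, eps_t: float, eps_c: float) -> float:
    """Quantum-yield ratio that yields a given PSS cis fraction (inverse)."""
    if not 0.0 < x_cis < 1.0:
        raise ParameterError("x_cis must lie strictly in (0, 1)")
    if eps_t <= 0 or eps_c <= 0:
        raise ParameterError("need positive extinction coefficients to invert")
    return x_cis / (1.0 - x_cis) * eps_c / eps_t


def evolve_fractions(
    start: IsomerFractions, phase: PhotoPhase, dt: float
) -> IsomerFractions:
    """Propagate an isomer composition through ``dt`` hours of one phase.

    The photo process pulls toward ``phase.pss`` at rate ``k_photo``; the
    thermal process pulls toward pure trans at rate ``k_thermal``.  Both are
    first order, so the combined dynamics is a single exponential toward the
    rate-weighted attractor.
    """
    if dt < 0:
        raise ParameterError("dt must be non-negative")
    k_tot = phase.k_photo + phase.k_thermal
    if k_tot == 0.0 or dt == 0.0:
        return start
    x_eq = phase.k_photo * phase.pss.x_cis / k_tot  # thermal attractor: x_cis = 0
    x_cis = x_eq + (start.x_cis - x_eq) * math.exp(-k_tot * dt)
    x_cis = min(max(x_cis, 0.0), 1.0)
    return IsomerFractions(1.0 - x_cis, x_cis)


def relaxation_curve(params: RelaxationParams, t) -> np.ndarray | float:
    """Evaluate the mono-exponential relaxation model at times ``t`` (hours)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("time must be non-negative")
    out = params.Ainf - (params.Ainf - params.A0) * np.exp(
        -math.log(2.0) * t_arr / params.t_half
    )
    return out if t_arr.ndim else float(out)


class RelaxationFit(RegressorMixin, BaseEstimator):
    """Least-squares fit of a mono-exponential absorbance trace.

    Parameters
    ----------
    fixed_Ainf : optional asymptote.  When provided, only ``A0`` and
        ``t_half`` are free — this mirrors the common practice of carrying
        the asymptote over from a companion experiment that actually reaches
        it, since a slow relaxation observed over a fraction of its
        half-life barely constrains its own plateau.

    Attributes
    ----------
    params_ : fitted :class:`RelaxationParams`
    stderr_ : dict of standard errors keyed ``A0 | Ainf | t_half``
        (``Ainf`` absent when fixed)
    """

    def __init__(self, fixed_Ainf: float | None = None):
        self.fixed_Ainf = fixed_Ainf

    def fit(self, t, absorbance):
        t_arr = np.asarray(t, dtype=float).ravel()
        A = np.asarray(absorbance, dtype=float).ravel()
        if t_arr.size != A.size:
            raise ParameterError("t and absorbance must have equal length")
        if t_arr.size < 4:
            raise ParameterError("need >= 4 points for a relaxation fit")
        if np.any(t_arr < 0):
            raise ParameterError("times must be non-negative")
        if np.ptp(A) == 0.0:
            raise UnidentifiableError(
                "constant absorbance trace: no relaxation detectable"
            )

        span = float(t_arr.max() - t_arr.min())
        a0_init = float(A[np.argmin(t_arr)])
        if self.fixed_Ainf is None:
            # extrapolate the plateau one observed-change beyond the last point
            ainf_init = float(A[np.argmax(t_arr)] + (A[np.argmax(t_arr)] - a0_init))
            theta0 = [a0_init, ainf_init, span]

            def resid(theta):
                a0, ainf, th = theta
                return ainf - (ainf - a0) * np.exp(-math.log(2.0) * t_arr / th) - A

            lb = [-np.inf, -np.inf, 1e-9]
            ub = [np.inf, np.inf, np.inf]
        else:
            theta0 = [a0_init, span]

            def resid(theta):
                a0, th = theta
                ainf = self.fixed_Ainf
                return ainf - (ainf - a0) * np.exp(-math.log(2.0) * t_arr / th) - A

            lb = [-np.inf, 1e-9]
            ub = [np.inf, np.inf]

        sol = least_squares(resid, theta0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15)
        if not sol.success:
            raise FitConvergenceError(
                f"relaxation fit did not converge: {sol.message}",
                diagnostics={"cost": sol.cost, "x": sol.x.tolist()},
            )
        stderr = _stderr_from_jac(sol.jac, sol.fun)
        if self.fixed_Ainf is None:
            a0, ainf, th = sol.x
            self.stderr_ = {"A0": stderr[0], "Ainf": stderr[1], "t_half": stderr[2]}
        else:
            a0, th = sol.x
            ainf = self.fixed_Ainf
            self.stderr_ = {"A0": stderr[0], "t_half": stderr[1]}
        self.params_ = RelaxationParams(float(a0), float(ainf), float(th))
        self.t_span_ratio_ = span / self.params_.t_half
        if self.t_span_ratio_ < 0.1:
            import warnings

            warnings.warn(
                f"trace spans only {self.t_span_ratio_:.2f} of the fitted "
                "half-life; t_half is weakly constrained",
                stacklevel=2,
            )
        return self

    def predict(self, t):
        return relaxation_curve(self.params_, np.asarray(t, dtype=float).ravel())


def _stderr_from_jac(jac: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    dof = max(resid.size - jac.shape[1], 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)


def fit_relaxation(series, fixed_Ainf: float | None = None) -> RelaxationFit:
    """Fit ``[(t_h, A), ...]``; returns the fitted :class:`RelaxationFit`."""
    arr = np.asarray(list(series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParameterError("series must be (time_h, absorbance) pairs")
    return RelaxationFit(fixed_Ainf=fixed_Ainf).fit(arr[:, 0], arr[:, 1])
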