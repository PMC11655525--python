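"""Beer-Lambert forward model and spectral estimation for an azobenzene switch.

The photoswitchable amino acid p-(phenylazo)-L-phenylalanine (Pap) exists as
a mixture of the planar *trans* ground state and the bulky metastable *cis*
state.  Each isomer has its own extinction-coefficient spectrum; a solution
of total concentration ``c`` with isomer fractions ``(x_t, x_c)`` absorbs

    A(lambda) = c * l * (x_t * eps_trans(lambda) + x_c * eps_cis(lambda))

with path length ``l`` in cm.  This module provides that forward model, the
inverse problem (estimating isomer fractions from absorbances at two or more
wavelengths), and zero-intercept extinction-coefficient regression from a
dilution series.

Band maxima for Pap (pH 8.0): trans 326 nm (eps = 21500 M-1 cm-1) and
423 nm (1380); cis 293 nm (6700) and 426 nm (2120).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ParameterError, SpectralRangeError, UnidentifiableError

__all__ = [
    "IsomerFractions",
    "IsomerSpectra",
    "UnmixResult",
    "absorbance",
    "unmix_fractions",
    "ExtinctionRegression",
    "fit_extinction",
    "EPS_TRANS_326",
    "EPS_TRANS_423",
    "EPS_CIS_293",
    "EPS_CIS_426",
]

# Band-maximum extinction coefficients of Pap, M-1 cm-1
EPS_TRANS_326 = 21500.0
EPS_TRANS_423 = 1380.0
EPS_CIS_293 = 6700.0
EPS_CIS_426 = 2120.0


@dataclass(frozen=True)
class IsomerFractions:
    """Composition of a cis/trans azobenzene population (must sum to 1)."""

    x_trans: float
    x_cis: float

    def __post_init__(self):
        if self.x_trans < -1e-12 or self.x_cis < -1e-12:
            raise ParameterError(
                f"isomer fractions must be non-negative, got "
                f"({self.x_trans}, {self.x_cis})"
            )
        if abs(self.x_trans + self.x_cis - 1.0) > 1e-9:
            raise ParameterError(
                f"isomer fractions must sum to 1, got "
                f"{self.x_trans + self.x_cis}"
            )

    @classmethod
    def pure_trans(cls) -> "IsomerFractions":
        return cls(1.0, 0.0)

    @classmethod
    def pure_cis(cls) -> "IsomerFractions":
        return cls(0.0, 1.0)

    @classmethod
    def from_cis(cls, x_cis: float) -> "IsomerFractions":
        return cls(1.0 - x_cis, x_cis)


@dataclass(frozen=True)
class IsomerSpectra:
    """Wavelength-tabulated extinction coefficients for both isomers.

    Wavelengths are in nm (strictly increasing); epsilon vectors in
    M-1 cm-1, one entry per wavelength.  Values between grid points are
    obtained by linear interpolation.
    """

    wavelengths: np.ndarray
    eps_trans: np.ndarray
    eps_cis: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        et = np.asarray(self.eps_trans, dtype=float)
        ec = np.asarray(self.eps_cis, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ParameterError("need a 1-D wavelength grid with >= 2 points")
        if not (et.shape == wl.shape and ec.shape == wl.shape):
            raise ParameterError("epsilon vectors must match the wavelength grid")
        if np.any(np.diff(wl) <= 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if np.any(et < 0) or np.any(ec < 0):
            raise ParameterError("extinction coefficients must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_trans", et)
        object.__setattr__(self, "eps_cis", ec)

    def _interp(self, eps: np.ndarray, wavelength: float) -> float:
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if wavelength < lo or wavelength > hi:
            raise SpectralRangeError(
                f"wavelength {wavelength} nm outside grid [{lo}, {hi}] nm"
            )
        return float(np.interp(wavelength, self.wavelengths, eps))

    def eps_trans_at(self, wavelength: float) -> float:
        return self._interp(self.eps_trans, wavelength)

    def eps_cis_at(self, wavelength: float) -> float:
        return self._interp(self.eps_cis, wavelength)

    @classmethod
    def default_pap(
        cls,
        wl_min: float = 250.0,
        wl_max: float = 550.0,
        step: float = 1.0,
        band_widths: dict[str, float] | None = None,
    ) -> "IsomerSpectra":
        """Synthetic Pap spectra built from Gaussian bands at the maxima.

        Only the band maxima and their extinction coefficients are
        experimentally anchored; the band shapes here are a parametric
        stand-in (Gaussian, widths in nm standard deviation) chosen to give
        smooth, plausible UV-Vis curves.  Use measured spectra via
        ``read_spectra`` whenever available.
        """
        widths = {"t1": 28.0, "t2": 40.0, "c1": 28.0, "c2": 45.0}
        if band_widths:
            widths.update(band_widths)
        wl = np.arange(wl_min, wl_max + 0.5 * step, step)

        def gauss(center, sigma, x):
            return np.exp(-((x - center) ** 2) / (2.0 * sigma**2))

        def two_band(c1, s1, e1, c2, s2, e2):
            # solve band amplitudes so the summed spectrum hits the printed
            # extinction coefficients exactly at both band maxima
            M = np.array([[1.0, gauss(c2, s2, c1)], [gauss(c1, s1, c2), 1.0]])
            a = np.linalg.solve(M, np.array([e1, e2]))
            return a[0] * gauss(c1, s1, wl) + a[1] * gauss(c2, s2, wl)

        eps_t = two_band(
            326.0, widths["t1"], EPS_TRANS_326, 423.0, widths["t2"], EPS_TRANS_423
        )
        eps_c = two_band(
            293.0, widths["c1"], EPS_CIS_293, 426.0, widths["c2"], EPS_CIS_426
        )
        return cls(wl, np.clip(eps_t, 0.0, None), np.clip(eps_c, 0.0, None))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "eps_trans": self.eps_trans,
                "eps_cis": self.eps_cis,
            }
        )


def absorbance(
    conc: float,
    fractions: IsomerFractions,
    spectra: IsomerSpectra,
    wavelength: float,
    path: float = 1.0,
) -> float:
    """Beer-Lambert absorbance of a cis/trans mixture.

    Parameters
    ----------
    conc : total chromophore concentration, M
    fractions : isomer composition
    spectra : extinction-coefficient table
    wavelength : nm, must lie within the spectral grid
    path : optical path length, cm
    """
    if conc < 0:
        raise ParameterError("concentration must be non-negative")
    if path <= 0:
        raise ParameterError("path length must be positive")
    eps_mix = (
        fractions.x_trans * spectra.eps_trans_at(wavelength)
        + fractions.x_cis * spectra.eps_cis_at(wavelength)
    )
    return conc * path * eps_mix


@dataclass(frozen=True)
class UnmixResult:
    """Outcome of a two-component spectral unmixing."""

    fractions: IsomerFractions
    residual: float  # RMS absorbance residual, AU
    clipped: bool  # True if the simplex projection moved the solution > 0.02


def unmix_fractions(
    absorbances: dict[float, float],
    conc: float,
    spectra: IsomerSpectra,
    path: float = 1.0,
) -> UnmixResult:
    """Estimate isomer fractions from absorbances at >= 2 wavelengths.

    Solves the unconstrained linear least-squares problem
    ``A(lambda_i) = c*l*(x_t eps_t(lambda_i) + x_c eps_c(lambda_i))`` and
    projects the solution onto the probability simplex.  If the projection
    moves the solution by more than 0.02 in either coordinate the result is
    flagged (``clipped=True``) and a warning is emitted.
    """
    if len(absorbances) < 2:
        raise ParameterError("need absorbances at >= 2 wavelengths")
    if conc <= 0:
        raise ParameterError("concentration must be positive")
    wls = sorted(absorbances)
    A = np.array([absorbances[w] for w in wls])
    M = np.array(
        [
            [conc * path * spectra.eps_trans_at(w) for w in wls],
            [conc * path * spectra.eps_cis_at(w) for w in wls],
        ]
    ).T  # (m, 2)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e8:
        raise UnidentifiableError(
            f"extinction matrix ill-conditioned (cond={cond:.3g}); choose "
            "wavelengths where the isomer spectra differ"
        )
    x, *_ = np.linalg.lstsq(M, A, rcond=None)
    x_proj = _project_simplex(x)
    moved = float(np.max(np.abs(x_proj - x)))
    clipped = moved > 0.02
    if clipped:
        warnings.warn(
            f"unmixing solution {x} lay off the simplex by {moved:.3f}; "
            "clipped — check concentration/path inputs",
            stacklevel=2,
        )
    resid = float(np.sqrt(np.mean((M @ x_proj - A) ** 2)))
    return UnmixResult(IsomerFractions(x_proj[0], x_proj[1]), resid, clipped)


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a 2-vector onto {x >= 0, sum x = 1}."""
    # shift onto the sum-1 hyperplane, then clip at the vertices
    u = v + (1.0 - v.sum()) / 2.0
    if u[0] < 0:
        return np.array([0.0, 1.0])
    if u[1] < 0:
        return np.array([1.0, 0.0])
    return u


class ExtinctionRegression(RegressorMixin, BaseEstimator):
    """Zero-intercept Beer-Lambert regression, ``A = eps * l * c``.

    Estimates a molar extinction coefficient from a dilution series by
    ordinary least squares through the origin (a blank-corrected photometer
    reads zero at zero concentration by construction).

    Parameters
    ----------
    path : optical path length in cm (default 1.0).

    Attributes
    ----------
    epsilon_ : fitted extinction coefficient, M-1 cm-1
    stderr_ : standard error of ``epsilon_``
    n_points_ : number of points used
    """

    def __init__(self, path: float = 1.0):
        self.path = path

    def fit(self, conc, absorbance):
        c = np.asarray(conc, dtype=float).ravel()
        A = np.asarray(absorbance, dtype=float).ravel()
        if c.size != A.size:
            raise ParameterError("conc and absorbance must have equal length")
        if c.size < 3:
            raise ParameterError("need >= 3 points for an extinction fit")
        if np.any(c < 0):
            raise ParameterError("concentrations must be non-negative")
        if np.ptp(c) == 0:
            raise ParameterError("concentrations are all equal; slope undefined")
        x = c * self.path
        sxx = float(x @ x)
        slope = float(x @ A) / sxx
        resid = A - slope * x
        # dof = n - 1 (one fitted parameter, no intercept)
        s2 = float(resid @ resid) / (c.size - 1)
        stderr = float(np.sqrt(s2 / sxx))
        self.epsilon_ = slope
        self.stderr_ = stderr
        self.n_points_ = int(c.size)
        if slope == 0.0 or (slope != 0 and abs(stderr / slope) > 0.5):
            warnings.warn(
                "extinction estimate poorly determined "
                f"(eps={slope:.4g} +/- {stderr:.4g})",
                stacklevel=2,
            )
        return self

    def predict(self, conc):
        c = np.asarray(conc, dtype=float).ravel()
        return self.epsilon_ * self.path * c


def fit_extinction(series, path: float = 1.0) -> tuple[float, float]:
    """Fit eps from ``[(conc_M, absorbance), ...]``; returns (eps, stderr)."""
    arr = np.asarray(list(series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParameterError("series must be (conc, absorbance) pairs")
    est = ExtinctionRegression(path=path).fit(arr[:, 0], arr[:, 1])
    return est.epsilon_, est.stderr_
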