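"""Exception hierarchy for azochrom."""


class AzochromError(Exception):
    """Base class for all azochrom errors."""


class ParameterError(AzochromError, ValueError):
    """A physical parameter is outside its admissible range."""


class SpectralRangeError(AzochromError, ValueError):
    """Requested wavelength lies outside the tabulated spectral grid."""


class UnidentifiableError(AzochromError, RuntimeError):
    """The data carry no information about the requested parameter.

    Raised e.g. for a flat titration series (no spectroscopic change on
    complex formation, so K_D has at best a lower bound) or an
    ill-conditioned unmixing system.
    """


class FitConvergenceError(AzochromError, RuntimeError):
    """Nonlinear least squares failed to converge; diagnostics attached."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ParseError(AzochromError, ValueError):
    """A CSV/config file failed validation; names the row/column at fault."""
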