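"""Exception hierarchy for ionfold.

Every domain error raised by the package derives from :class:`IonfoldError`,
so callers can catch one base class at pipeline boundaries while tests can
assert on the specific condition.
"""


class IonfoldError(Exception):
    """Base class for all ionfold errors."""


# --- spectra / FRET ---------------------------------------------------------

class IncompatibleSpectraError(IonfoldError):
    """Two spectra do not share the wavelength range required by an operation."""


class AcceptorSignalAbsentError(IonfoldError):
    """The directly excited acceptor band integrates to zero (or negative)."""


class GridMismatchError(IonfoldError):
    """Two series that must share a grid (concentrations, wavelengths) do not."""


class InvalidPhotophysicsError(IonfoldError):
    """Nonpositive extinction coefficient, quantum yield or overlap integral."""


class InvalidLabelingFractionError(InvalidPhotophysicsError):
    """Donor labeling fraction f_D outside (0, 1]."""


class EfficiencyRangeError(IonfoldError):
    """Conformer-corrected efficiency outside the invertible range (0, 1)."""


class GeometryError(IonfoldError):
    """Arm lengths and dye separation violate the triangle inequality."""


class NoPeakError(IonfoldError):
    """No peak above baseline in a spectrum passed to peak_metrics."""


# --- fitting ----------------------------------------------------------------

class FitConvergenceError(IonfoldError):
    """A nonlinear fit failed to converge.

    The best-so-far parameter values, when available, are attached as the
    ``best`` attribute (a plain dict).
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class NoTransitionError(IonfoldError):
    """Titration signal is flat; there is no transition to fit."""


class UnidentifiableModelError(FitConvergenceError):
    """The fit's Jacobian is singular; parameters are not identifiable."""


class NoDecayError(IonfoldError):
    """Luminescence trace contains no decaying component above the baseline."""


class NegativeTransferError(IonfoldError):
    """Quenched lifetime exceeds the donor-only lifetime."""


# --- I/O and configuration --------------------------------------------------

class ParseError(IonfoldError):
    """Structured CSV parse failure; carries the 1-based line number."""

    def __init__(self, message, line=None, path=None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.line = line
        self.path = path


class SchemaVersionError(ParseError):
    """File declares a schema version newer than this package supports."""


class ConfigError(IonfoldError):
    """Unknown or invalid run-configuration key or value."""
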