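"""Exception hierarchy for the nervelocate package.

All package-specific failures derive from :class:`NerveLocateError` so callers
can catch one base class at pipeline boundaries.
"""


class NerveLocateError(Exception):
    """Base class for all nervelocate errors."""


# --- pulse / impedance ------------------------------------------------------

class NoPulseDetected(NerveLocateError):
    """No rising edge in the waveform exceeds the noise threshold."""


class AmbiguousPulse(NerveLocateError):
    """More than one stimulus pulse detected in a single waveform."""


class FitNotConverged(NerveLocateError):
    """A nonlinear least-squares fit failed to converge.

    Carries the best candidate found (if any) in ``.diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedCapacitance(NerveLocateError):
    """Impedance at f > 0 requested for a circuit with undefined Cp."""


# --- CMAP features ----------------------------------------------------------

class IncompleteWindow(NerveLocateError):
    """A trigger's analysis window extends past the end of the recording."""


class ShapeMismatch(NerveLocateError):
    """Segments of unequal length passed to an aggregation."""


class NoResponse(NerveLocateError):
    """Peak-to-peak amplitude below the detection threshold."""


class DegenerateRange(NerveLocateError):
    """CMAP normalization impossible: top and bottom amplitudes equal."""


class SingularDesign(NerveLocateError):
    """Linear model design matrix is singular (e.g. all currents equal)."""


class ThresholdNotFound(NerveLocateError):
    """No motor response detected up to the maximum safe current."""


# --- regression model -------------------------------------------------------

class MissingFeature(NerveLocateError):
    """A feature required by the model variant is absent from the record."""


class InvalidRecord(NerveLocateError):
    """A record holds values that make a required feature undefined."""


class UnfittedModel(NerveLocateError):
    """Prediction requested from a model that has not been fitted."""


class RankDeficient(NerveLocateError):
    """Design matrix rank-deficient; coefficients not identifiable."""


# --- validation -------------------------------------------------------------

class ConstantTruth(NerveLocateError):
    """Correlation-based accuracy undefined: reference values constant."""


class LengthMismatch(NerveLocateError):
    """Paired vectors of unequal length."""


# --- phantom ----------------------------------------------------------------

class NoResponsePossible(NerveLocateError):
    """The simulated motor threshold exceeds the maximum allowed current."""


# --- I/O --------------------------------------------------------------------

class MalformedInput(NerveLocateError):
    """An input table fails validation; message names the offending row."""
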