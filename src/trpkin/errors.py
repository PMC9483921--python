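"""Exception and warning types shared across the package."""


class TrpkinError(Exception):
    """Base class for package errors."""


class InvalidInputError(TrpkinError, ValueError):
    """A physical quantity is outside its valid domain (e.g. negative area)."""


class UndefinedFractionError(TrpkinError, ZeroDivisionError):
    """A fractional quantity has an all-zero denominator."""


class UndefinedBranchingError(TrpkinError, ZeroDivisionError):
    """All channels out of an intermediate have zero rate."""


class InsufficientDataError(TrpkinError, ValueError):
    """A fit or correction window contains too few points."""


class FitFailureError(TrpkinError, RuntimeError):
    """An optimizer failed to converge or produced a singular system."""


class SolverFailureError(TrpkinError, RuntimeError):
    """The ODE integrator did not converge; carries solver diagnostics."""


class DegenerateGeometryError(TrpkinError, ValueError):
    """Point sets are collinear/coincident; superposition is ill-posed."""


class EmptyBandError(TrpkinError, ValueError):
    """An integration band does not overlap the spectrum support."""


class ParseError(TrpkinError, ValueError):
    """A data file violates the expected format; message names the line."""


class DataQualityWarning(UserWarning):
    """Physically suspect but tolerable data (e.g. fraction above 1)."""


class QSSValidityWarning(UserWarning):
    """Quasi-steady-state assumption is marginal for the given rates."""


class BoundaryWarning(UserWarning):
    """A fitted parameter sits on a bound; the estimate is not interior."""
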