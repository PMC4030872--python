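"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`McfoldError`,
so callers can catch one type at a pipeline boundary.
"""


class McfoldError(Exception):
    """Base class for all mcfold errors."""


class InvalidParameterError(McfoldError, ValueError):
    """A numeric parameter violates its precondition (e.g. k <= 0)."""


class IncompatibleModelsError(McfoldError, ValueError):
    """Two potentials cannot be combined (mismatched dimension or domain)."""


class OracleRangeError(McfoldError, ValueError):
    """A canonical oracle was queried outside its temperature validity range."""


class IntegrationFailureError(McfoldError, RuntimeError):
    """The integrator diverged; the message names the time step used."""


class WeightDerivativeError(McfoldError, RuntimeError):
    """dE_mc/dE evaluated to a non-finite value."""


class InsufficientDataError(McfoldError, ValueError):
    """Too few occupied histogram bins to fit a weight polynomial."""


class ConvergenceFailureError(McfoldError, RuntimeError):
    """Iterative weight estimation exceeded its iteration budget.

    Carries the per-iteration report accumulated so far in ``report``.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report if report is not None else []


class UndefinedFlatnessError(McfoldError, ValueError):
    """Flatness requested on an empty or nearly empty energy histogram."""


class PDBParseError(McfoldError, ValueError):
    """Malformed PDB text; the message carries a line number when known."""


class EmptyStructureError(McfoldError, ValueError):
    """A structure source contained no atoms."""


class MissingRegionError(McfoldError, KeyError):
    """A residue selection matched nothing; lists the absent residue numbers."""


class ConfigError(McfoldError, ValueError):
    """A run configuration violates the strict schema."""
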