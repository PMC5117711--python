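"""Exception hierarchy for epifold."""


class EpifoldError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EpifoldError, ValueError):
    """Arguments violate a documented precondition."""


class FormatError(EpifoldError, ValueError):
    """A file or table does not conform to its expected format."""


class DegenerateTableError(EpifoldError, ValueError):
    """Contact-energy table degenerates (zero normalisation)."""


class IntegrationError(EpifoldError, RuntimeError):
    """Langevin propagation produced non-finite coordinates."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite coordinates at step {step}")


class GenerationError(EpifoldError, RuntimeError):
    """Random-coil construction failed after bounded retries."""


class AlignmentDegenerateError(EpifoldError, ValueError):
    """Point sets are too degenerate (collinear) for superposition."""


class DockingError(EpifoldError, RuntimeError):
    """Shell sweep produced no candidate poses."""


class InvalidTargetError(EpifoldError, ValueError):
    """Target state does not cover every pair of the binding complex."""


class CannotBuildTargetError(EpifoldError, RuntimeError):
    """No replica is active under the provisional target."""


class NoMoveError(EpifoldError, RuntimeError):
    """Exchange matrix allows no substitution at the requested site."""


class SummaryError(EpifoldError, ValueError):
    """Too few records to summarise a distribution."""
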