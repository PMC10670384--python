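"""Exception hierarchy shared across the package."""


class SeegFuseError(Exception):
    """Base class for all package errors."""


class ContractError(SeegFuseError, ValueError):
    """An argument violates a documented precondition."""


class GeometryError(SeegFuseError, ValueError):
    """Two grids that must share geometry do not, or an affine is degenerate."""


class PlacementError(SeegFuseError, RuntimeError):
    """Electrode placement could not satisfy the requested configuration."""

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class ProviderError(SeegFuseError, RuntimeError):
    """An external brain-extraction provider failed or produced bad output."""


class RegistrationError(SeegFuseError, RuntimeError):
    """Registration failed to produce a usable transform."""
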