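"""Exception hierarchy shared across the package."""


class CerebsegError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CerebsegError):
    """Volumes/masks combined on incompatible grids (shape, spacing or affine)."""


class ContractError(CerebsegError, ValueError):
    """An operation precondition was violated by the caller."""


class ConfigurationError(CerebsegError, ValueError):
    """Invalid configuration values (phantom or pipeline)."""


class PipelineError(CerebsegError, RuntimeError):
    """A segmentation stage produced an unusable result.

    Carries the name of the stage that failed so batch callers can log it.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class RegistrationError(CerebsegError, RuntimeError):
    """Affine registration failed (non-finite cost or empty warped mask)."""


class DegenerateFitError(CerebsegError, ValueError):
    """A statistical fit cannot be performed on the given data."""
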