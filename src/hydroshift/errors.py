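"""Exception hierarchy for the hydroshift pipeline."""


class HydroshiftError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(HydroshiftError, ValueError):
    """An input configuration is internally inconsistent or infeasible."""


class ValidationError(HydroshiftError, ValueError):
    """An input table, grid, or argument violates a documented contract."""


class CollinearityError(HydroshiftError, ValueError):
    """An exposure is absorbed by the fixed effects and cannot be estimated."""

    def __init__(self, message: str, absorbed_by: str | None = None):
        super().__init__(message)
        self.absorbed_by = absorbed_by
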