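"""Exception hierarchy shared by all pipeline stages."""


class Nc886Error(Exception):
    """Base class for all package-specific errors."""


class ConfigError(Nc886Error, ValueError):
    """Invalid simulation or pipeline configuration."""


class InputError(Nc886Error, ValueError):
    """Malformed or out-of-contract input data."""


class CollinearityError(Nc886Error):
    """Rank-deficient regression design matrix; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; suspect columns: {self.columns}")


class ConvergenceError(Nc886Error):
    """Model fit failed to converge or the likelihood is degenerate (separation)."""


class InsufficientDataError(Nc886Error):
    """Too few usable observations (or cases) for the requested fit."""
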