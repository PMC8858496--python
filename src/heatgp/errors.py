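"""Exception types shared across the package."""


class HeatgpError(Exception):
    """Base class for package errors."""


class ConfigError(HeatgpError):
    """Invalid user-supplied configuration or arguments."""


class ConvergenceError(HeatgpError):
    """Iterative estimation failed to converge.

    Carries the per-iteration trajectory in ``trajectory`` (list of dicts
    with at least ``iter`` and ``loglik``) to aid diagnosis.
    """

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []


class DataError(HeatgpError):
    """Inconsistent or degenerate input data."""
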