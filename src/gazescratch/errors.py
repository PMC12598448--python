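"""Exception hierarchy for the gazescratch package."""


class GazeScratchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GazeScratchError):
    """A file does not conform to the expected tabular/structured format."""


class IntegrityError(GazeScratchError):
    """Data violate an invariant (e.g. non-monotone timestamps within a trial)."""


class ConfigError(GazeScratchError):
    """A run configuration contains unknown keys or ill-typed values."""


class ConvergenceWarning(UserWarning):
    """An MCMC-based estimate failed its convergence diagnostic."""
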