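"""Exception hierarchy used across the package."""


class PedscatterError(Exception):
    """Base class for all package errors."""


class FormatError(PedscatterError):
    """A file could not be parsed into the expected tabular layout."""


class ValidationError(PedscatterError):
    """Parsed data violates an invariant (e.g. non-monotone timestamps)."""


class ConfigurationError(PedscatterError):
    """A configuration value is out of its admissible range."""


class IntegrationError(PedscatterError):
    """The simulator produced a non-finite state."""


class SkipEncounter(PedscatterError):
    """Signal that a candidate group/encounter cannot be formed (e.g. no
    overlapping time support, group stationary throughout)."""


class NoEncounter(PedscatterError):
    """The individual never enters the observation window."""


class DegenerateVelocity(PedscatterError):
    """The averaged relative velocity at window entry has zero norm."""


class EmptyAnalysisError(PedscatterError):
    """No encounters survived filtering; refusing to emit empty results."""
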